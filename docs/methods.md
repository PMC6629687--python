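# Methods

This note documents the models and procedures implemented in `atoxfam`,
the parameter defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the package's known limitations.

## Topology screening

Transmembrane (TM) helices are called from a Kyte–Doolittle hydropathy
profile: per-residue windowed means (window 19, odd; edge windows
truncated so the profile has one value per residue; the unknown residue X
contributes 0). Maximal runs of positions with mean ≥ 1.6 are candidate
helices; runs separated by ≤ 3 positions are merged (a single buried polar
residue should not split a helix call) and merged runs shorter than 15
residues are discarded. These are the classic hydropathy-plot settings for
membrane-helix detection; all four are configurable. A sequence passes the
screen iff exactly seven segments are called.

The region map is then forced by the family's fixed orientation
(extracellular N-terminus, intracellular C-terminus): regions alternate
N-terminal, TMI, IC Loop 1, TMII, EC Loop 1, TMIII, IC Loop 2, …, TMVII,
C-terminal, giving exactly three intracellular and three extracellular
loops. No orientation inference is attempted — for this family it is not
in question. The detector is a deliberate simplification: it is a
hydropathy heuristic, not a hidden-Markov topology model, and it does not
handle signal peptides or re-entrant helices. A consequence of the
19-residue window is that a called segment is systematically ~6 residues
shorter than the underlying hydrophobic stretch (edge windows mix in
flanking hydrophilic residues), which is why the screen requires
hydrophobic stretches comfortably longer than the window to be robust.

All coordinates everywhere in the package are 0-based, half-open.

## Family-motif filter

The family motif is matched with the degenerate pattern `[DE]RW[YN]A[IV]`,
the union of the variants observed across the family (the Y/N slot admits
the single Hydra-type ERWNAI form). A match counts only when anchored at
the TMIII / IC Loop 2 interface: its start must lie in
`[TMIII.end − 6, IC Loop 2.end)`. The window extends six residues (one
motif length) into the helix so the motif may begin inside TMIII and
finish in the loop; the first match in the window wins (a deterministic
tie-break; multiple matches are not expected). Wider degeneracy is opt-in
via the pattern parameter.

The codon-change calculator brute-forces the standard genetic code: for
two amino acids it returns the minimum Hamming distance over all encoding
codon pairs, plus every minimizing pair with the differing codon
positions. This is the package's formal version of the parsimony argument
for the family's observed variants: D↔E is always a single change at codon
position 3, and Y→N a single change at position 1.

## Multiple alignment

Pairwise and profile–profile alignment use Gotoh's three-state affine-gap
global dynamic programme. Column pairs are scored by the average-of-pairs
rule: the sum of substitution scores over all residue pairs of the two
columns, divided by the (constant) number of row pairs. The normalization
keeps column scores on the single-sequence BLOSUM62 scale for which the
flat gap penalties (open −10, extend −1; a gap of length L costs
open + (L−1)·extend) are calibrated — with a raw sum-of-pairs score, gap
penalties would become negligible for large profiles. Gaps and X
contribute nothing to column scores. Traceback ties are fixed:
match/mismatch first, then gap in the second profile, then gap in the
first, making output deterministic.

Progressive alignment merges profiles bottom-up along a Neighbour-Joining
guide tree computed from p-distances of all pairwise alignments. There is
no iterative refinement and no attempt to reproduce any particular
external aligner column-for-column; the contract tested is structural
(ungapping any row recovers its input exactly; no all-gap columns;
consistently planted blocks align into single gap-free column runs).

Conserved blocks are maximal gap-free column runs in which every column's
majority-residue frequency reaches the threshold; the consensus is the
per-column majority residue (ties broken alphabetically).

## Distances, trees, support

The p-distance of two rows is differing sites / compared sites, where
compared sites exclude positions holding a gap or X in either row
(pairwise deletion, the default) or in any row (complete deletion). The
Poisson correction d = −ln(1 − p) converts the observed difference
fraction into expected substitutions per site; p at or above the
saturation cap (default 0.95) is an error rather than an infinite
distance, so saturated pairs must be pruned explicitly.

Neighbour-Joining follows Saitou & Nei: join the pair minimizing
Q(i,j) = (n−2)·d(i,j) − R_i − R_j, with ties broken on the smallest
(i, j) index pair; branch lengths use the standard rate-corrected
formulas, and a negative length is clamped to zero with the deficit moved
to the sibling edge (preserving the joined pair's path length). On
additive matrices the algorithm recovers topology and branch lengths
exactly, which the tests verify over all 15 five-leaf topologies.

Bootstrap replicates resample alignment columns with replacement (same
length), recompute Poisson-corrected distances and re-run NJ; a replicate
whose distances are saturated or undefined is dropped and counted with a
warning. The majority-rule consensus contains exactly the non-trivial
bipartitions occurring in strictly more than the cutoff percentage of
replicate trees (default 50%, which guarantees mutual compatibility),
each annotated with its exact frequency as support. Robinson–Foulds
distance is the size of the symmetric difference of non-trivial
bipartition sets; all tree comparisons treat trees as unrooted.

The likelihood scorer implements Felsenstein's pruning algorithm under
the equal-rates 20-state model (the amino-acid analogue of Jukes–Cantor):
uniform stationary frequencies, P(same) = 1/20 + (19/20)·exp(−(20/19)t).
Gap and X cells are missing data (all-ones partials). Under this
time-reversible model the likelihood is invariant under re-rooting, which
is tested (pulley principle). The scorer ranks candidate topologies; no
heuristic tree search (NNI/SPR), rate heterogeneity, or empirical
exchangeability matrix (JTT/WAG/LG) is implemented — tree *search* here
is NJ, and the likelihood is a scoring complement.

## Signature mining

For a labelled group, candidates are the maximal alignment-column runs in
which every in-group row holds the same definite residue (gaps and X break
runs). A candidate within the length bounds (default 6–25 residues,
bracketing the observed range of family and group signatures) is reported
iff its residue string passes the specificity check: no sequence outside
the group contains it as an exact substring. Specificity is checked
against the dataset only — an in-dataset replacement for a
database-identity search, and a deliberate semantic narrowing: a motif
"specific" within a small dataset may of course occur elsewhere in nature.
Groups with fewer than `min_group_size` (default 2) aligned members are
skipped with a warning, since with one member every substring is trivially
conserved. Degenerate signature positions (e.g. a two-way L/Q slot) are
not mined: conservation is strict identity.

A brute-force oracle (substring enumeration testing both conditions, then
maximality, then bounds) is kept in the package and the test suite
verifies the run-based miner equals it exactly on toy and simulated data.

## Synthetic data generator

The generator is the package's study-condition definition, not a test
convenience; its defaults are fixed:

- **Template**: 40-residue hydrophilic N-terminus, seven 30-residue
  hydrophobic stretches separated by 25-residue hydrophilic loops,
  40-residue C-terminus — 440 residues. Hydrophobic stretches draw from
  {I, L, V, F, A} with weights (.30, .30, .20, .10, .10);
  loops/termini draw uniformly from {R, K, D, E, N, Q, S, G}. Thirty
  residues is toward the long end for a membrane-spanning helix but well
  within the sequence span of tilted/kinked GPCR helices, and it is the
  geometry a 19-residue-window detector with a 15-residue minimum call
  needs: the called run is ~6 residues shorter than the stretch, so
  stretches must exceed window + margin for evolved sequences to keep
  passing the screen.
- **Family-invariant mask**: the DRWYAI motif written across the TMIII
  end / IC Loop 2 junction (start = TMIII.end − 2, so it spans helix and
  loop as in real receptors); an NPIIY block mid-TMVII echoing the
  rhodopsin-family NPxxY element; and the core of every TM stretch,
  leaving 2 residues per helix end free to evolve. Masked sites never
  substitute. The helix cores are masked for two structural reasons:
  they guarantee that every simulated leaf passes the hydropathy screen
  (the family's defining property, which the inclusion filter assumes),
  and, at 26 columns, a conserved run through a helix core always
  exceeds the 25-residue maximum signature length, so family-invariant
  cores can never masquerade as clade signatures.
- **Evolution**: along each branch of the (known) tree, every unmasked
  site receives a Poisson(b × rate) number of substitution events, each
  replacing the residue with a uniform draw from the other 19. This is
  exactly the equal-rates model assumed by the Poisson correction and the
  likelihood scorer, so the package's closed forms apply to its own
  simulations. No indels are simulated — alignment columns remain
  homologous by construction, which is what lets truth tables use
  template coordinates directly.
- **Default tree**: 12 leaves in three named 4-leaf clades (CladeA/B/C
  under Metazoa), every branch 0.05 substitutions/site. Group labels are
  the named internal nodes, giving nested taxonomy paths.
- **Planted clade signatures**: KFRAEFKA (C-terminal, CladeA), ADYDDEFI
  (N-terminal, CladeB), QRNWRTIQCS (IC Loop 3, CladeC) — written into
  the ancestral state at each clade's root and masked within that
  subtree only, so each is perfectly conserved inside its clade and
  diverges freely elsewhere. Positions must be pairwise disjoint
  (validated).

What the generator does **not** emulate about real data: indels and
alignment uncertainty, among-site rate variation, composition bias,
paralogy/gene duplication (every leaf is an ortholog of the template),
incomplete or fragmentary sequences, and database noise. Passing tests
therefore demonstrate the correctness of the machinery under the model's
own assumptions — not robustness to the full messiness of curated
database sets.

## Validation set-up and problem sizes

Validation runs use desk-scale sizes chosen to make the checks exact or
statistically decisive: alignment-score enumeration up to length 6 (200
random pairs); likelihood state-enumeration on four-leaf trees with
20-column alignments (50 trees); NJ additivity on all 15 five-leaf
topologies; divergence closed-form checks at sequence length 10,000 with
100 replicates (3-standard-error band for the difference fraction, 5%
band for the mean Poisson-corrected estimate at d ≤ 0.1); bootstrap
behaviour with 200 replicates on a constructed zero-homoplasy alignment
(two internal edges, 20 private columns each — the probability a
replicate misses an edge's columns is (180/200)^200 ≈ 7·10⁻¹⁰);
signature mining at 0.2 substitutions/site per branch with minimum
signature length 8. At that divergence a flanking column stays conserved
within a 4-leaf clade with probability ≈ e^(−1.2) ≈ 0.30, so mined
signatures may legitimately extend a planted motif by a residue or two;
recovery is therefore scored by span overlap plus containment of the
planted string, while miner-vs-oracle agreement is exact string-set
equality. A minimum mined length of 8 matches the planted-signature
length floor; at minimum length 6, chance clade-conserved 6-mers are
statistically expected at this divergence (0.30⁶ × ~160 evolving
positions ≈ 0.1 per clade) and would be genuine — but unplanted —
signatures.

## Numerical and design choices

- Strict 21-letter alphabet (20 amino acids + X); B/Z/J/U/O are rejected
  at parse time rather than silently recoded.
- BLOSUM62, genetic code and FASTA parsing come from Biopython; Newick
  parsing from dendropy. A numeric internal-node label in Newick is read
  as bootstrap support, any other label as a clade name.
- All stochastic steps (simulation, bootstrap) take explicit integer
  seeds; reruns with the same configuration are byte-identical, and the
  pipeline's run log records seed, parameters and an input digest.
- Bootstrap ties and NJ Q-ties resolve to the smallest index pair;
  consensus construction inserts bipartitions smallest-side-first.
- The consensus tree carries supports but no branch lengths (a
  frequency-based summary has no natural length estimate).
- The region vocabulary is fixed to the 15 labels of a 7-TM receptor
  (N-terminal, TMI–TMVII, IC/EC Loops 1–3, C-terminal). Group-signature
  reports never emit a fourth extracellular loop; a span crossing several
  regions is labelled by the ordered joined labels (e.g.
  "TMIII – IC Loop 2").

## Limitations

- The topology screen is a hydropathy heuristic; sequences with unusually
  polar helices or very short loops can be miscalled, and the screen's
  pass/fail boundary depends on the four detector parameters.
- The Poisson correction ignores repeated substitutions' composition
  structure (it is exact only under the equal-rates model) and the
  saturation cap simply refuses distances with p ≥ 0.95.
- Signature specificity is relative to the supplied dataset; it is not a
  database-wide uniqueness claim.
- The likelihood scorer evaluates fixed topologies only; there is no ML
  tree search.
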