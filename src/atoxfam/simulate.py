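"""Ground-truthed synthetic GPCR-like datasets.

The generator builds a 7-TM template sequence — hydrophilic N-terminus,
seven hydrophobic stretches separated by hydrophilic loops, hydrophilic
C-terminus — and evolves it along a known tree under the equal-rates
20-state model, leaving designated positions invariant.  Two family-wide
elements are written into the template and masked everywhere:

* the DRWYAI family motif spanning the TMIII end / IC Loop 2 junction
  (start = TMIII.end - 2), and
* an NPIIY block at the centre of TMVII, mirroring the rhodopsin-family
  NPxxY element, so that the family shows the canonical two conserved
  domains (TMIII/IC Loop 2 and TMVII).

Clade signatures are planted by overwriting the sequence state at the
named internal node of each labelled group and masking those positions
within that subtree only; outside the subtree the positions evolve freely,
so a planted signature is conserved in its group and (for realistic
lengths) absent elsewhere.

Hydrophobic stretches draw from {I, L, V, F, A} weighted toward the
strongly hydrophobic residues; loops and termini draw uniformly from
{R, K, D, E, N, Q, S, G}.  Unmasked TM residues evolve like any other
site, so the hydropathy screen is exercised on realistically noisy
helices.  Substitutions are a Poisson number of events per site per
branch with a uniform target among the other 19 residues — exactly the
model the distance correction and likelihood scorer assume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, GroupLabeling, ProteinSequence, fasta_string
from .topology import Topology
from .tree import PhyloTree, TreeError, TreeNode

log = logging.getLogger(__name__)

TM_RESIDUES = "ILVFA"
TM_WEIGHTS = (0.30, 0.30, 0.20, 0.10, 0.10)
LOOP_RESIDUES = "RKDENQSG"

FAMILY_MOTIF = "DRWYAI"
TM7_MOTIF = "NPIIY"


class SimulationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class PlantedMotif:
    group: str
    motif: str
    start: int  # template coordinate

    @property
    def end(self) -> int:
        return self.start + len(self.motif)


@dataclass
class SimulationConfig:
    n_tm: int = 7
    tm_len: int = 30
    loop_len: int = 25
    nterm_len: int = 40
    cterm_len: int = 40
    tree: PhyloTree | None = None
    rate: float = 1.0
    planted: list[PlantedMotif] = field(default_factory=list)
    extra_invariant: frozenset[int] = frozenset()
    #: residues masked at each end of every TM stretch stay evolvable;
    #: the stretch core in between is invariant, which is what guarantees
    #: that every simulated leaf still passes the hydropathy screen
    tm_core_margin: int = 2
    seed: int = 0

    @property
    def seq_len(self) -> int:
        return (
            self.nterm_len
            + self.n_tm * self.tm_len
            + (self.n_tm - 1) * self.loop_len
            + self.cterm_len
        )

    def tm_segments(self) -> list[tuple[int, int]]:
        segs = []
        pos = self.nterm_len
        for _ in range(self.n_tm):
            segs.append((pos, pos + self.tm_len))
            pos += self.tm_len + self.loop_len
        return segs


def default_tree() -> PhyloTree:
    """Balanced 12-leaf tree: three named 4-leaf clades, 0.05 subs/site
    on every branch."""
    b = 0.05
    root = TreeNode(name="Metazoa")
    for clade, prefix in (("CladeA", "a"), ("CladeB", "b"), ("CladeC", "c")):
        cnode = root.add_child(TreeNode(name=clade, length=b))
        for pair in ((1, 2), (3, 4)):
            inner = cnode.add_child(TreeNode(length=b))
            for k in pair:
                inner.add_child(TreeNode(name=f"{prefix}{k}", length=b))
    return PhyloTree(root)


def default_planted(cfg: SimulationConfig) -> list[PlantedMotif]:
    """One clade signature each in the N-terminal, IC Loop 3 and
    C-terminal regions (motif strings in the style of real group
    signatures)."""
    segs = cfg.tm_segments()
    icl3_start = segs[4][1]  # loop between TMV and TMVI is IC Loop 3
    cterm_start = segs[-1][1]
    return [
        PlantedMotif("CladeA", "KFRAEFKA", cterm_start + 10),
        PlantedMotif("CladeB", "ADYDDEFI", 10),
        PlantedMotif("CladeC", "QRNWRTIQCS", icl3_start + 7),
    ]


def default_config(seed: int = 0, rate: float = 1.0) -> SimulationConfig:
    cfg = SimulationConfig(tree=default_tree(), rate=rate, seed=seed)
    cfg.planted = default_planted(cfg)
    return cfg


def _validate(cfg: SimulationConfig) -> None:
    if cfg.n_tm != 7:
        raise SimulationError("the family topology has exactly 7 TM domains")
    if min(cfg.tm_len, cfg.loop_len, cfg.nterm_len, cfg.cterm_len) < 8:
        raise SimulationError("segment lengths too short for a 7-TM layout")
    spans = [(p.start, p.end, p.group) for p in cfg.planted]
    for start, end, group in spans:
        if not (0 <= start < end <= cfg.seq_len):
            raise SimulationError(f"planted motif for {group!r} out of bounds")
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            a, b = spans[i], spans[j]
            if a[0] < b[1] and b[0] < a[1]:
                raise SimulationError(
                    f"planted motifs for {a[2]!r} and {b[2]!r} overlap"
                )
    if cfg.tree is not None:
        names = {n.name for n in cfg.tree.root.preorder() if n.name}
        for p in cfg.planted:
            if p.group not in names:
                raise SimulationError(f"planted group {p.group!r} not in tree")


def make_template(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ProteinSequence, Topology, set[int]]:
    """Template sequence, its true topology and the family-invariant mask."""
    _validate(cfg)
    rng = rng or np.random.default_rng(cfg.seed)
    segs = cfg.tm_segments()
    chars = list(
        rng.choice(list(LOOP_RESIDUES), size=cfg.seq_len)
    )
    for a, b in segs:
        tm = rng.choice(list(TM_RESIDUES), size=b - a, p=TM_WEIGHTS)
        chars[a:b] = list(tm)
    mask: set[int] = set()
    # invariant helix cores (flanks of width tm_core_margin keep evolving)
    if cfg.tm_core_margin >= 0:
        for a, b in segs:
            mask.update(range(a + cfg.tm_core_margin, b - cfg.tm_core_margin))
    # family motif across the TMIII end / IC Loop 2 junction
    fam_start = segs[2][1] - 2
    chars[fam_start:fam_start + len(FAMILY_MOTIF)] = list(FAMILY_MOTIF)
    mask.update(range(fam_start, fam_start + len(FAMILY_MOTIF)))
    # NPxxY-like block at the centre of TMVII
    tm7_mid = (segs[6][0] + segs[6][1]) // 2 - len(TM7_MOTIF) // 2
    chars[tm7_mid:tm7_mid + len(TM7_MOTIF)] = list(TM7_MOTIF)
    mask.update(range(tm7_mid, tm7_mid + len(TM7_MOTIF)))
    mask.update(cfg.extra_invariant)
    seq = ProteinSequence(id="template", residues="".join(chars))
    topo = Topology(tm_segments=segs, seq_len=cfg.seq_len)
    return seq, topo, mask


_AA_INDEX = {c: i for i, c in enumerate(AMINO_ACIDS)}


def _evolve_branch(
    state: np.ndarray, t: float, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Equal-rates evolution of *state* (int codes) over branch length t."""
    out = state.copy()
    if t <= 0:
        return out
    events = rng.poisson(t, size=state.shape[0])
    events[mask] = 0
    for pos in np.nonzero(events)[0]:
        cur = out[pos]
        for _ in range(events[pos]):
            step = rng.integers(0, 19)
            cur = step if step < cur else step + 1
        out[pos] = cur
    return out


def simulate_on_tree(
    template: ProteinSequence,
    cfg: SimulationConfig,
    mask: set[int] | None = None,
) -> dict[str, ProteinSequence]:
    """Evolve the template along cfg.tree; returns leaf id -> sequence.

    Root state = template.  Masked sites never substitute.  A planted
    group motif is written into the state at that group's subtree root and
    masked within the subtree.  Deterministic given cfg.seed.
    """
    if cfg.tree is None:
        raise SimulationError("config has no tree")
    _validate(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    root_state = np.array([_AA_INDEX[c] for c in template.residues])
    base_mask = np.zeros(len(root_state), dtype=bool)
    for i in mask or set():
        base_mask[i] = True
    planted_by_group = {p.group: p for p in cfg.planted}
    leaves: dict[str, ProteinSequence] = {}

    def walk(node: TreeNode, state: np.ndarray, m: np.ndarray) -> None:
        state = state.copy()
        m = m.copy()
        if node.name in planted_by_group:
            p = planted_by_group[node.name]
            state[p.start:p.end] = [_AA_INDEX[c] for c in p.motif]
            m[p.start:p.end] = True
        if node.length:
            state = _evolve_branch(state, node.length * cfg.rate, m, rng)
        if node.is_leaf:
            if node.name is None:
                raise TreeError("unnamed leaf in simulation tree")
            leaves[node.name] = ProteinSequence(
                id=node.name,
                residues="".join(AMINO_ACIDS[k] for k in state),
            )
            return
        for child in node.children:
            walk(child, state, m)

    walk(cfg.tree.root, root_state, base_mask)
    return leaves


@dataclass
class SyntheticDataset:
    """Sequences plus every piece of ground truth needed downstream."""

    config: SimulationConfig
    template: ProteinSequence
    true_topology: Topology
    family_mask: set[int]
    sequences: list[ProteinSequence]
    labels: GroupLabeling
    tree: PhyloTree
    truth_signatures: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "sequences.fasta",
            "labels": outdir / "groups.tsv",
            "tree": outdir / "true_tree.nwk",
            "signatures": outdir / "true_signatures.tsv",
            "segments": outdir / "true_segments.tsv",
        }
        paths["fasta"].write_text(fasta_string(self.sequences))
        with open(paths["labels"], "w") as fh:
            from .seqio import write_group_table

            write_group_table(self.labels, fh)
        paths["tree"].write_text(self.tree.to_newick() + "\n")
        self.truth_signatures.to_csv(paths["signatures"], sep="\t", index=False)
        seg_rows = [
            {"tm": f"TM{k + 1}", "start": a, "end": b}
            for k, (a, b) in enumerate(self.true_topology.tm_segments)
        ]
        pd.DataFrame(seg_rows).to_csv(paths["segments"], sep="\t", index=False)
        return paths


def generate_dataset(
    cfg: SimulationConfig | None = None, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Generate sequences, labels, true tree and truth tables."""
    cfg = cfg or default_config()
    if cfg.tree is None:
        cfg.tree = default_tree()
    if not cfg.planted:
        cfg.planted = default_planted(cfg)
    _validate(cfg)
    template, topo, mask = make_template(cfg)
    leaves = simulate_on_tree(template, cfg, mask)
    order = cfg.tree.leaf_names()
    sequences = [leaves[name] for name in order]
    # taxonomy path = named ancestors, most inclusive first
    paths: dict[str, tuple[str, ...]] = {}

    def collect(node: TreeNode, trail: tuple[str, ...]) -> None:
        trail = trail + ((node.name,) if node.name and not node.is_leaf else ())
        if node.is_leaf:
            paths[node.name] = trail if trail else ("Unassigned",)
            return
        for child in node.children:
            collect(child, trail)

    collect(cfg.tree.root, ())
    labels = GroupLabeling(paths)
    truth = pd.DataFrame(
        [
            {
                "group": p.group,
                "motif": p.motif,
                "template_start": p.start,
                "template_end": p.end,
                "region": " – ".join(topo.span_regions(p.start, p.end)),
            }
            for p in cfg.planted
        ],
        columns=["group", "motif", "template_start", "template_end", "region"],
    )
    ds = SyntheticDataset(
        config=cfg,
        template=template,
        true_topology=topo,
        family_mask=mask,
        sequences=sequences,
        labels=labels,
        tree=cfg.tree,
        truth_signatures=truth,
    )
    if outdir is not None:
        ds.write(outdir)
    return ds
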