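import numpy as np
import pytest

from atoxfam.alignment import Alignment, SequenceError
from atoxfam.bruteforce import enumerate_alignment_score, random_protein
from atoxfam.msa import (
    AlignmentError,
    ScoringScheme,
    blosum62_scheme,
    build_guide_tree,
    conserved_blocks,
    pairwise_align,
    progressive_align,
    sum_of_pairs_score,
)
from atoxfam.seqio import ProteinSequence
from atoxfam.simulate import SimulationConfig, default_config, default_tree, generate_dataset
from atoxfam.tree import robinson_foulds


class TestScoringScheme:
    def test_asymmetric_matrix_rejected(self):
        mat = np.zeros((21, 21))
        mat[0, 1] = 5.0
        with pytest.raises(AlignmentError):
            ScoringScheme(matrix=mat)

    def test_gap_penalty_ordering_enforced(self):
        with pytest.raises(AlignmentError):
            blosum62_scheme(gap_open=-1, gap_extend=-10)


class TestPairwiseAlign:
    def test_family_motif_self_alignment_scores_37(self, scheme):
        # BLOSUM62 diagonal: D6 + R5 + W11 + Y7 + A4 + I4
        a = ProteinSequence(id="a", residues="DRWYAI")
        b = ProteinSequence(id="b", residues="DRWYAI")
        ra, rb, score = pairwise_align(a, b, scheme)
        assert (ra, rb) == ("DRWYAI", "DRWYAI")
        assert score == 37

    def test_identical_sequences_align_gap_free(self, scheme):
        rng = np.random.default_rng(0)
        res = random_protein(rng, 80)
        ra, rb, score = pairwise_align(
            ProteinSequence(id="a", residues=res),
            ProteinSequence(id="b", residues=res),
            scheme,
        )
        assert ra == rb == res
        assert score == sum(scheme.score(c, c) for c in res)

    def test_score_matches_enumeration_oracle_on_short_pairs(self, scheme):
        rng = np.random.default_rng(7)
        for _ in range(60):
            a = random_protein(rng, int(rng.integers(1, 7)))
            b = random_protein(rng, int(rng.integers(1, 7)))
            _, _, score = pairwise_align(
                ProteinSequence(id="a", residues=a),
                ProteinSequence(id="b", residues=b),
                scheme,
            )
            oracle = enumerate_alignment_score(a, b, scheme)
            assert score == pytest.approx(oracle, abs=1e-9), (a, b)

    def test_score_matches_biopython_on_longer_pairs(self, scheme):
        aligner = pytest.importorskip("Bio.Align").PairwiseAligner()
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
        aligner.mode = "global"
        rng = np.random.default_rng(21)
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(10, 40)))
            b = random_protein(rng, int(rng.integers(10, 40)))
            _, _, score = pairwise_align(
                ProteinSequence(id="a", residues=a),
                ProteinSequence(id="b", residues=b),
                scheme,
            )
            assert score == pytest.approx(aligner.score(a, b))

    def test_ungapping_recovers_inputs(self, scheme):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(5, 50)))
            b = random_protein(rng, int(rng.integers(5, 50)))
            ra, rb, _ = pairwise_align(
                ProteinSequence(id="a", residues=a),
                ProteinSequence(id="b", residues=b),
                scheme,
            )
            assert ra.replace("-", "") == a
            assert rb.replace("-", "") == b
            assert len(ra) == len(rb)


class TestGuideTree:
    def test_two_sequences_single_edge(self, scheme):
        seqs = [
            ProteinSequence(id="a", residues="ACDEFGHIKL"),
            ProteinSequence(id="b", residues="ACDEFGHIKW"),
        ]
        tree = build_guide_tree(seqs, scheme)
        assert set(tree.leaf_names()) == {"a", "b"}
        total = sum(c.length for c in tree.root.children)
        assert total == pytest.approx(0.1)

    def test_three_identical_sequences_star_with_zero_lengths(self, scheme):
        seqs = [
            ProteinSequence(id=i, residues="ACDEFGHIKL") for i in ("a", "b", "c")
        ]
        tree = build_guide_tree(seqs, scheme)
        assert all(c.length == pytest.approx(0.0) for c in tree.root.children)

    def test_fewer_than_two_sequences_rejected(self, scheme):
        from atoxfam.tree import TreeError

        with pytest.raises(TreeError):
            build_guide_tree([ProteinSequence(id="a", residues="ACD")], scheme)

    def test_recovers_generating_topology(self, scheme, dataset):
        tree = build_guide_tree(dataset.sequences, scheme)
        assert robinson_foulds(tree, dataset.tree) == 0


class TestProgressiveAlign:
    def test_single_sequence_returned_unchanged(self, scheme):
        seq = ProteinSequence(id="a", residues="ACDEFG")
        aln = progressive_align([seq], scheme=scheme)
        assert aln.rows == ["ACDEFG"]

    def test_identical_sequences_gap_free(self, scheme):
        rng = np.random.default_rng(5)
        res = random_protein(rng, 60)
        seqs = [ProteinSequence(id=f"s{k}", residues=res) for k in range(4)]
        aln = progressive_align(seqs, scheme=scheme)
        assert all(row == res for row in aln.rows)

    def test_ungapping_invariant_after_merges(self, scheme):
        rng = np.random.default_rng(9)
        seqs = [
            ProteinSequence(id=f"s{k}", residues=random_protein(rng, int(rng.integers(40, 60))))
            for k in range(5)
        ]
        aln = progressive_align(seqs, scheme=scheme)
        for seq in seqs:
            assert aln.ungapped(seq.id) == seq.residues

    def test_planted_block_aligned_in_single_gap_free_run(self, scheme):
        # divergent hydrophilic flanks of unequal length around DRWYAI
        rng = np.random.default_rng(13)
        seqs = []
        for k in range(4):
            left = random_protein(rng, 8 + 3 * k)
            right = random_protein(rng, 20 - 3 * k)
            seqs.append(
                ProteinSequence(id=f"s{k}", residues=left + "DRWYAI" + right)
            )
        aln = progressive_align(seqs, scheme=scheme)
        starts = set()
        for seq in seqs:
            row = aln.row(seq.id)
            col = 0
            # locate motif columns in the gapped row
            res_start = seq.residues.index("DRWYAI")
            seen = 0
            for col, c in enumerate(row):
                if c != "-":
                    if seen == res_start:
                        break
                    seen += 1
            assert row[col:col + 6] == "DRWYAI"
            starts.add(col)
        assert len(starts) == 1

    def test_alignment_score_invariant_under_input_order(self, scheme, dataset):
        seqs = dataset.sequences[:6]
        guide = build_guide_tree(seqs, scheme)
        aln1 = progressive_align(seqs, guide, scheme)
        aln2 = progressive_align(list(reversed(seqs)), guide, scheme)
        assert sum_of_pairs_score(aln1, scheme) == pytest.approx(
            sum_of_pairs_score(aln2, scheme)
        )

    def test_guide_leaf_mismatch_rejected(self, scheme):
        from atoxfam.tree import TreeError

        seqs = [
            ProteinSequence(id="a", residues="ACD"),
            ProteinSequence(id="b", residues="ACD"),
        ]
        guide = build_guide_tree(
            [ProteinSequence(id="x", residues="ACD"), seqs[1]], scheme
        )
        with pytest.raises(TreeError):
            progressive_align(seqs, guide, scheme)


class TestAlignmentContainer:
    def test_unequal_rows_rejected(self):
        with pytest.raises(SequenceError):
            Alignment(["a", "b"], ["AC-", "AC"])

    def test_all_gap_column_rejected(self):
        with pytest.raises(SequenceError):
            Alignment(["a", "b"], ["A-C", "A-C"])


class TestConservedBlocks:
    def test_identical_rows_single_full_length_block(self):
        aln = Alignment(["a", "b", "c"], ["DRWYAI"] * 3)
        assert conserved_blocks(aln, min_identity=1.0, min_len=3) == [
            (0, 6, "DRWYAI")
        ]

    def test_min_len_longer_than_alignment_gives_nothing(self):
        aln = Alignment(["a", "b"], ["DRWYAI"] * 2)
        assert conserved_blocks(aln, min_identity=1.0, min_len=7) == []

    def test_two_planted_invariant_domains_recovered(self):
        # high divergence, helix cores free to evolve: the only conserved
        # blocks left are the two family-invariant domains
        cfg = default_config(seed=4, rate=6.0)
        cfg.tm_core_margin = -1  # helix cores evolve
        ds = generate_dataset(cfg)
        aln = Alignment.from_sequences(ds.sequences)
        blocks = conserved_blocks(aln, min_identity=1.0, min_len=5)
        assert len(blocks) == 2
        (s1, e1, cons1), (s2, e2, cons2) = blocks
        segs = ds.true_topology.tm_segments
        fam_start = segs[2][1] - 2
        tm7_mid = (segs[6][0] + segs[6][1]) // 2 - 2
        assert s1 <= fam_start and e1 >= fam_start + 6
        assert "DRWYAI" in cons1
        assert s2 <= tm7_mid and e2 >= tm7_mid + 5
        assert "NPIIY" in cons2
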