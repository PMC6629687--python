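import logging

import numpy as np
import pytest

from atoxfam.alignment import Alignment
from atoxfam.phylo import (
    DistanceError,
    DistanceMatrix,
    bootstrap_trees,
    majority_consensus,
    nj_tree,
    p_distance_matrix,
    poisson_correct,
    poisson_distance_matrix,
)
from atoxfam.tree import (
    PhyloTree,
    TreeError,
    TreeNode,
    all_unrooted_topologies,
    assign_random_branch_lengths,
    newick_parse,
    newick_write,
    path_distance_matrix,
    robinson_foulds,
)


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["ACDE", "ACDE"])
        assert p_distance_matrix(aln).values[0, 1] == 0.0

    def test_direct_count(self):
        aln = Alignment(["a", "b"], ["AAAA", "AATT"])
        assert p_distance_matrix(aln).values[0, 1] == pytest.approx(0.5)

    def test_pairwise_deletion_excludes_gap_sites(self):
        aln = Alignment(["a", "b"], ["AA-A", "AATA"])
        assert p_distance_matrix(aln, "pairwise").values[0, 1] == 0.0

    def test_x_sites_excluded(self):
        aln = Alignment(["a", "b"], ["AXAA", "ATAA"])
        assert p_distance_matrix(aln).values[0, 1] == 0.0

    def test_complete_deletion_drops_column_for_all_pairs(self):
        aln = Alignment(["a", "b", "c"], ["ACDE", "AC-E", "TCDE"])
        pw = p_distance_matrix(aln, "pairwise")
        cd = p_distance_matrix(aln, "complete")
        assert pw.values[0, 2] == pytest.approx(1 / 4)
        assert cd.values[0, 2] == pytest.approx(1 / 3)

    def test_no_comparable_sites_is_an_error(self):
        aln = Alignment(["a", "b", "c"], ["A-", "-A", "AA"])
        with pytest.raises(DistanceError, match="'a' and 'b'"):
            p_distance_matrix(aln)


class TestPoissonCorrection:
    def test_zero(self):
        assert poisson_correct(0.0) == 0.0

    def test_closed_form_at_half(self):
        assert poisson_correct(0.5) == pytest.approx(0.693147, abs=1e-6)

    def test_saturation_guard(self):
        with pytest.raises(DistanceError, match="saturated"):
            poisson_correct(0.99)

    def test_monotone(self):
        ps = np.linspace(0, 0.9, 10)
        ds = [poisson_correct(p) for p in ps]
        assert all(x < y for x, y in zip(ds, ds[1:]))


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(DistanceError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(DistanceError):
            DistanceMatrix(["a", "b"], np.array([[0.1, 1.0], [1.0, 0.0]]))


class TestNeighbourJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        tree = nj_tree(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.3], [0.3, 0]]))
        tree = nj_tree(dm)
        assert sum(c.length for c in tree.root.children) == pytest.approx(0.3)

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(17)
        for true in all_unrooted_topologies(["A", "B", "C", "D", "E"]):
            assign_random_branch_lengths(true, lambda: rng.uniform(0.05, 1.0))
            names, d = path_distance_matrix(true)
            inferred = nj_tree(DistanceMatrix(names, np.array(d)))
            assert robinson_foulds(inferred, true) == 0
            e_true, e_inf = true.edge_lengths(), inferred.edge_lengths()
            assert set(e_true) == set(e_inf)
            for key, val in e_true.items():
                assert e_inf[key] == pytest.approx(val, abs=1e-9)

    def test_equidistant_matrix_gives_minimum_evolution_length(self):
        # all pairwise distances 0.5: any resolution is valid; the total
        # length must equal the star-tree optimum n * d / 2
        n, d = 5, 0.5
        vals = np.full((n, n), d)
        np.fill_diagonal(vals, 0.0)
        tree = nj_tree(DistanceMatrix(list("ABCDE"), vals))
        total = sum(
            node.length for node in tree.root.preorder() if node.length
        )
        assert total == pytest.approx(n * d / 2)

    def test_agrees_with_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(23)
        true = all_unrooted_topologies(["A", "B", "C", "D", "E", "F"])[7]
        assign_random_branch_lengths(true, lambda: rng.uniform(0.1, 0.6))
        names, d = path_distance_matrix(true)
        mine = nj_tree(DistanceMatrix(names, np.array(d)))
        sk = skbio.tree.nj(skbio.DistanceMatrix(np.array(d), ids=names))
        theirs = newick_parse(str(sk).strip())
        assert robinson_foulds(mine, theirs) == 0


def _perfect_phylogeny_alignment() -> tuple[Alignment, PhyloTree]:
    """Five taxa, two internal edges, each supported by 20 private
    columns; remaining 160 columns constant (zero homoplasy)."""
    taxa = ["A", "B", "C", "D", "E"]
    cols = []
    for _ in range(20):  # split AB | CDE
        cols.append({"A": "C", "B": "C", "C": "S", "D": "S", "E": "S"})
    for _ in range(20):  # split AB C | DE
        cols.append({"A": "W", "B": "W", "C": "W", "D": "H", "E": "H"})
    for _ in range(160):
        cols.append({t: "G" for t in taxa})
    rows = ["".join(c[t] for c in cols) for t in taxa]
    true = newick_parse("((A:1,B:1):1,C:1,(D:1,E:1):1);")
    return Alignment(taxa, rows), true


class TestBootstrap:
    def test_zero_replicates(self, dataset):
        aln = Alignment.from_sequences(dataset.sequences)
        assert bootstrap_trees(aln, 0, seed=1) == []

    def test_same_seed_reproducible(self):
        aln, _ = _perfect_phylogeny_alignment()
        t1 = bootstrap_trees(aln, 10, seed=42)
        t2 = bootstrap_trees(aln, 10, seed=42)
        assert [newick_write(t) for t in t1] == [newick_write(t) for t in t2]

    def test_zero_homoplasy_gives_identical_topologies(self):
        aln, true = _perfect_phylogeny_alignment()
        trees = bootstrap_trees(aln, 50, seed=3)
        assert len(trees) == 50
        assert all(robinson_foulds(t, true) == 0 for t in trees)

    def test_saturated_replicates_dropped_with_warning(self, caplog):
        # every column differs: p = 1 >= cap in every replicate
        aln = Alignment(["a", "b"], ["ACDEFGHIKL", "CDEFGHIKLM"])
        with caplog.at_level(logging.WARNING, logger="atoxfam.phylo"):
            trees = bootstrap_trees(aln, 5, seed=1)
        assert trees == []
        assert "dropped" in caplog.text


class TestMajorityConsensus:
    def test_identical_trees_full_support(self):
        trees = [newick_parse("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);") for _ in range(10)]
        cons = majority_consensus(trees, 50.0)
        assert robinson_foulds(cons, trees[0]) == 0
        supports = [
            n.support for n in cons.root.preorder() if n.support is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_sixty_forty_split(self):
        majority = [newick_parse("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")] * 6
        minority = [newick_parse("((A:1,C:1):1,(B:1,(D:1,E:1):1):1);")] * 4
        cons = majority_consensus(majority + minority, 50.0)
        bips = cons.bipartition_nodes()
        ab = frozenset(["C", "D", "E"])  # side not containing leaf A
        assert ab in bips and bips[ab].support == pytest.approx(60.0)
        ac = frozenset(["B", "D", "E"])
        assert ac not in bips

    def test_total_disagreement_at_full_cutoff_gives_star(self):
        trees = [
            newick_parse("((A:1,B:1):1,C:1,D:1);"),
            newick_parse("((A:1,C:1):1,B:1,D:1);"),
        ]
        cons = majority_consensus(trees, 100.0)
        assert cons.bipartitions() == set()

    def test_differing_leaf_sets_rejected(self):
        t1 = newick_parse("((A:1,B:1):1,C:1,D:1);")
        t2 = newick_parse("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(TreeError):
            majority_consensus([t1, t2])

    def test_every_reported_support_exceeds_cutoff(self):
        aln, _ = _perfect_phylogeny_alignment()
        trees = bootstrap_trees(aln, 40, seed=9)
        cons = majority_consensus(trees, 50.0)
        for node in cons.root.preorder():
            if node.support is not None:
                assert node.support > 50.0


class TestRobinsonFoulds:
    def test_self_distance_zero(self):
        t = newick_parse("((A:1,B:1):1,C:1,D:1);")
        assert robinson_foulds(t, t) == 0

    def test_distinct_quartets_distance_two(self):
        t1 = newick_parse("((A:1,B:1):1,C:1,D:1);")
        t2 = newick_parse("((A:1,C:1):1,B:1,D:1);")
        assert robinson_foulds(t1, t2) == 2

    def test_binary_versus_star(self):
        binary = newick_parse("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        star = newick_parse("(A:1,B:1,C:1,D:1,E:1);")
        assert robinson_foulds(binary, star) == len(binary.bipartitions())

    def test_differing_leaf_sets_rejected(self):
        t1 = newick_parse("(A:1,B:1,C:1);")
        t2 = newick_parse("(A:1,B:1,D:1);")
        with pytest.raises(TreeError):
            robinson_foulds(t1, t2)

    def test_agrees_with_dendropy(self):
        import dendropy

        rng = np.random.default_rng(31)
        labels = list("ABCDEFG")
        tops = all_unrooted_topologies(labels)
        idx = rng.integers(0, len(tops), size=6)
        for i, j in zip(idx[::2], idx[1::2]):
            t1, t2 = tops[int(i)].copy(), tops[int(j)].copy()
            assign_random_branch_lengths(t1, lambda: 1.0)
            assign_random_branch_lengths(t2, lambda: 1.0)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=newick_write(t1), schema="newick", taxon_namespace=tns
            )
            d2 = dendropy.Tree.get(
                data=newick_write(t2), schema="newick", taxon_namespace=tns
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert robinson_foulds(t1, t2) == expected


class TestNewick:
    def test_single_edge_round_trip(self):
        t = newick_parse("(A:0.1,B:0.1);")
        assert newick_write(t) == "(A:0.1,B:0.1);"

    def test_support_label_round_trip(self):
        t = newick_parse("((A:0.1,B:0.2)75:0.3,C:0.4,D:0.5);")
        internal = [n for n in t.root.preorder() if n.support is not None]
        assert len(internal) == 1 and internal[0].support == 75.0
        assert newick_write(t) == "((A:0.1,B:0.2)75:0.3,C:0.4,D:0.5);"

    def test_malformed_input_rejected(self):
        with pytest.raises(TreeError, match="Newick"):
            newick_parse("((A:0.1,B:0.2;")

    def test_random_tree_round_trip_preserves_structure(self):
        rng = np.random.default_rng(19)
        for top in all_unrooted_topologies(list("ABCDE"))[::3]:
            assign_random_branch_lengths(top, lambda: float(rng.uniform(0.01, 2)))
            back = newick_parse(newick_write(top))
            assert robinson_foulds(back, top) == 0
            e1, e2 = top.edge_lengths(), back.edge_lengths()
            for key in e1:
                assert e2[key] == pytest.approx(e1[key], abs=1e-9)


class TestPoissonDistanceMatrix:
    def test_saturated_pair_named(self):
        aln = Alignment(["a", "b"], ["ACDEFGHIKL", "CDEFGHIKLM"])
        with pytest.raises(DistanceError, match="saturated"):
            poisson_distance_matrix(aln)

    def test_matches_scalar_correction(self):
        aln = Alignment(["a", "b"], ["AAAA", "AATT"])
        dm = poisson_distance_matrix(aln)
        assert dm.values[0, 1] == pytest.approx(poisson_correct(0.5))
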