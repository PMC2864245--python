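"""Alignment, distances, neighbor joining, bootstrap, rooting, clades."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromomine import phylo
from chromomine.io import SequenceRecord, AMINO_ACID, NUCLEOTIDE
from chromomine import _domains as lib


def aa_records(pairs):
    return [SequenceRecord(name, seq, AMINO_ACID) for name, seq in pairs]


def random_additive_tree(rng, n):
    names = [f"t{i}" for i in range(n)]
    nodes = [phylo.Node(name=nm, length=float(rng.uniform(0.1, 2.0)))
             for nm in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(phylo.Node(children=[a, b],
                                length=float(rng.uniform(0.1, 2.0))))
    tree = phylo.Tree(phylo.Node(children=nodes))
    pd = tree.path_distances()
    m = np.zeros((n, n))
    for (x, y), d in pd.items():
        xi, yi = names.index(x), names.index(y)
        m[xi, yi] = m[yi, xi] = d
    return names, m, tree


class TestProgressiveMsa:
    def test_identical_sequences_align_gap_free(self):
        aln = phylo.progressive_msa(aa_records(
            [("a", "MKVLD"), ("b", "MKVLD")]))
        assert [r.residues for r in aln] == ["MKVLD", "MKVLD"]

    def test_two_nucleotide_sequences_single_gap(self):
        aln = phylo.progressive_msa([
            SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACT")])
        rows = {r.id: r.residues for r in aln}
        assert len(rows["a"]) == len(rows["b"]) == 4
        assert rows["a"] == "ACGT"
        assert rows["b"].count("-") == 1

    def test_column_count_invariant_under_input_order(self, rng):
        base = lib.random_protein(rng, 120)
        seqs = []
        for famidx in range(3):
            master = lib.mutate_protein(base, 0.25, rng)
            for copy in range(2):
                seqs.append((f"f{famidx}c{copy}",
                             lib.mutate_protein(master, 0.05, rng)))
        cols_ref = len(phylo.progressive_msa(aa_records(seqs))[0].residues)
        for order_seed in range(3):
            perm = np.random.default_rng(order_seed).permutation(len(seqs))
            shuffled = [seqs[i] for i in perm]
            cols = len(phylo.progressive_msa(aa_records(shuffled))[0].residues)
            assert cols == cols_ref
        assert cols_ref >= 120

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            phylo.progressive_msa([
                SequenceRecord("a", "ACGT"),
                SequenceRecord("b", "MKV", AMINO_ACID)])


class TestDistanceMatrix:
    def test_identical_pair_zero_under_both_models(self):
        aln = aa_records([("a", "MKVL"), ("b", "MKVL"), ("c", "MKVV")])
        for model in ("p", "poisson"):
            dm = phylo.distance_matrix(aln, model=model)
            assert dm.matrix[0, 1] == 0.0

    def test_poisson_correction_value(self):
        # p = 0.48 over 100 columns -> d = -ln(0.52) = 0.6539...
        a = "A" * 100
        b = "A" * 52 + "C" * 48
        dm = phylo.distance_matrix(aa_records([("a", a), ("b", b)]),
                                   model="poisson")
        assert dm.matrix[0, 1] == pytest.approx(0.65393, abs=1e-5)

    def test_saturated_pair_rejected(self):
        a, b = "ACDEF" * 4, "GHIKL" * 4
        with pytest.raises(ValueError):
            phylo.distance_matrix(aa_records([("a", a), ("b", b)]),
                                  model="poisson")

    def test_gapped_columns_excluded(self):
        aln = aa_records([("a", "MK-L"), ("b", "MKVL")])
        dm = phylo.distance_matrix(aln, model="p")
        assert dm.matrix[0, 1] == 0.0

    def test_poisson_dominates_p_distance(self, rng):
        a = lib.random_protein(rng, 200)
        b = lib.mutate_protein(a, 0.3, rng)
        aln = aa_records([("a", a), ("b", b)])
        dp = phylo.distance_matrix(aln, model="p").matrix[0, 1]
        dpois = phylo.distance_matrix(aln, model="poisson").matrix[0, 1]
        assert dpois > dp > 0


class TestNeighborJoining:
    def test_exact_on_worked_additive_example(self):
        # tree A-u:1, B-u:2, u-v:1, C-v:3, D-v:4
        ids = ["A", "B", "C", "D"]
        m = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(ids, m))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        pd = tree.path_distances()
        for (x, y), expect in {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
                               ("B", "C"): 6, ("B", "D"): 7,
                               ("C", "D"): 7}.items():
            assert pd[(x, y)] == pytest.approx(expect)

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(["a", "b", "c"], m))
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths == {"a": 0.0, "b": 2.0, "c": 3.0}

    def test_additive_matrices_recovered(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            names, m, source = random_additive_tree(rng, n)
            out = phylo.nj_tree(phylo.DistanceMatrix(names, m))
            out_pd = out.path_distances()
            for key, value in source.path_distances().items():
                assert math.isclose(out_pd[key], value, abs_tol=1e-8)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.nj_tree(phylo.DistanceMatrix(
                ["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_deterministic_on_tied_matrix(self):
        m = np.ones((4, 4)) - np.eye(4)
        ids = ["d", "c", "b", "a"]
        t1 = phylo.nj_tree(phylo.DistanceMatrix(ids, m.copy()))
        t2 = phylo.nj_tree(phylo.DistanceMatrix(ids, m.copy()))
        assert t1.to_newick() == t2.to_newick()


class TestBootstrap:
    def _alignment(self, rng, n=5, length=200, divergence=0.2):
        base = lib.random_protein(rng, length)
        recs = []
        for i in range(n):
            recs.append(SequenceRecord(
                f"s{i}", lib.mutate_protein(base, divergence * (i + 1) / n,
                                            rng), AMINO_ACID))
        return recs

    def test_identical_sequences_full_support(self):
        aln = aa_records([(f"s{i}", "MKVLDEAG") for i in range(4)])
        tree = phylo.bootstrap(aln, n=50, seed=1, model="p")
        for side, support in tree.bipartitions(with_support=True).items():
            assert support == 100.0

    def test_zero_replicates_point_tree_without_support(self, rng):
        aln = self._alignment(rng)
        tree = phylo.bootstrap(aln, n=0, seed=1)
        assert all(s is None for s in
                   tree.bipartitions(with_support=True).values())

    def test_supports_reproducible_under_seed(self, rng):
        aln = self._alignment(rng)
        t1 = phylo.bootstrap(aln, n=200, seed=9)
        t2 = phylo.bootstrap(aln, n=200, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_within_bounds(self, rng):
        aln = self._alignment(rng)
        tree = phylo.bootstrap(aln, n=100, seed=2)
        for support in tree.bipartitions(with_support=True).values():
            assert support is None or 0.0 <= support <= 100.0


class TestCladeAssignment:
    def _tree(self, support):
        return phylo.Tree.from_newick(
            f"((query:1,(ref1:1,ref2:1)95:1){support}:1,"
            "(other1:1,other2:1)99:1,out:3);")

    def test_query_inside_supported_uniform_clade(self):
        tree = self._tree(100)
        labels = {"ref1": "Tcn1", "ref2": "Tcn1", "other1": "Maggy",
                  "other2": "Maggy", "out": "outgroup"}
        out = {a.query_id: a.clade
               for a in phylo.assign_clades(tree, labels)}
        assert out["query"] == "Tcn1"

    def test_mixed_label_clade_unclassified(self):
        tree = self._tree(100)
        labels = {"ref1": "Tcn1", "ref2": "Maggy", "other1": "Maggy",
                  "other2": "Maggy", "out": "outgroup"}
        out = {a.query_id: a.clade
               for a in phylo.assign_clades(tree, labels)}
        assert out["query"] == "unclassified"

    def test_support_threshold_honored(self):
        labels = {"ref1": "Tcn1", "ref2": "Tcn1", "other1": "Maggy",
                  "other2": "Maggy", "out": "outgroup"}
        at_49 = phylo.assign_clades(self._tree(49), labels)
        at_50 = phylo.assign_clades(self._tree(50), labels)
        assert {a.query_id: a.clade for a in at_49}["query"] == "unclassified"
        assert {a.query_id: a.clade for a in at_50}["query"] == "Tcn1"


class TestRooting:
    def test_single_leaf_outgroup(self):
        tree = phylo.Tree.from_newick("((A:1,B:2):1,C:3,D:4);")
        rooted = phylo.root_with_outgroup(tree, ["A"])
        assert rooted.rooted
        sides = [frozenset(l.name for l in c.leaves())
                 for c in rooted.root.children]
        assert frozenset({"A"}) in sides

    def test_all_leaves_outgroup_rejected(self):
        tree = phylo.Tree.from_newick("((A:1,B:2):1,C:3,D:4);")
        with pytest.raises(ValueError):
            phylo.root_with_outgroup(tree, ["A", "B", "C", "D"])

    def test_non_monophyletic_outgroup_rejected(self):
        tree = phylo.Tree.from_newick("((A:1,B:2):1,C:3,D:4);")
        with pytest.raises(ValueError, match="monophyletic"):
            phylo.root_with_outgroup(tree, ["A", "C"])

    def test_rooting_preserves_bipartitions(self):
        tree = phylo.Tree.from_newick("(((A:1,B:1):1,C:2):1,D:1,E:2);")
        rooted = phylo.root_with_outgroup(tree, ["E"])
        assert rooted.bipartitions() == tree.bipartitions()


@settings(max_examples=100, derandomize=True)
@given(st.floats(0.0, 0.9), st.floats(0.0, 0.9))
def test_poisson_correction_monotone_and_dominant(p1, p2):
    d1, d2 = phylo.poisson_correct(p1), phylo.poisson_correct(p2)
    if p1 < p2:
        assert d1 < d2
    assert d1 >= p1
    if p1 == 0:
        assert d1 == 0
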