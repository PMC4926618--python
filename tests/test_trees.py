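import itertools

import numpy as np
import pytest

from barcodiv.errors import DataError
from barcodiv.phylo import _path_lengths, parse_newick
from barcodiv.records import DistanceMatrix, SequenceRecord
from barcodiv.trees import (bootstrap_support, build_tree, check_ultrametric,
                            polarise, upgma_from_alignment)

ADDITIVE = DistanceMatrix(
    ids=("A", "B", "C", "D"),
    values=np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                     [5, 6, 0, 7], [6, 7, 7, 0]], float))


class TestBuildTree:
    def test_nj_recovers_additive_tree_exactly(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4))
        tree = build_tree(ADDITIVE, "nj")
        paths = _path_lengths(tree)
        for (a, b) in itertools.combinations("ABCD", 2):
            assert paths[(a, b)] == pytest.approx(ADDITIVE[(a, b)], abs=1e-9)
        splits = set(tree.bipartitions())
        assert frozenset({"C", "D"}) in splits or \
            frozenset({"A", "B"}) in splits

    def test_nj_consistent_on_random_additive_quartets(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            # quartet ab|cd with internal edge e and pendants p[i]
            p = rng.uniform(0.5, 3.0, 4)
            e = rng.uniform(0.5, 2.0)
            d = np.zeros((4, 4))
            pair = {(0, 1): p[0] + p[1], (2, 3): p[2] + p[3]}
            for i, j in itertools.combinations(range(4), 2):
                d[i, j] = d[j, i] = pair.get((i, j), p[i] + p[j] + e)
            dm = DistanceMatrix(ids=("a", "b", "c", "d"), values=d)
            tree = build_tree(dm, "nj")
            assert frozenset({"c", "d"}) in tree.bipartitions() or \
                frozenset({"a", "b"}) in tree.bipartitions()

    def test_upgma_reproduces_ultrametric_ages(self):
        vals = np.array([[0, 2, 8, 8], [2, 0, 8, 8],
                         [8, 8, 0, 4], [8, 8, 4, 0]], float)
        tree = build_tree(DistanceMatrix(ids=("A", "B", "C", "D"),
                                         values=vals), "upgma")
        ages = sorted(a for n, a in tree.node_ages().items()
                      if not n.is_leaf())
        assert ages == pytest.approx([1.0, 2.0, 4.0])
        ok, dev = check_ultrametric(tree)
        assert ok and dev == pytest.approx(0.0)

    def test_two_taxon_boundary(self):
        dm = DistanceMatrix(ids=("x", "y"),
                            values=np.array([[0, 0.3], [0.3, 0]]))
        nj = build_tree(dm, "nj")
        assert _path_lengths(nj)[("x", "y")] == pytest.approx(0.3)
        up = build_tree(dm, "upgma")
        assert up.tip_depths() == pytest.approx({"x": 0.15, "y": 0.15})

    def test_saturated_distances_rejected(self):
        vals = np.array([[0, np.inf], [np.inf, 0]])
        dm = DistanceMatrix(ids=("x", "y"), values=vals)
        with pytest.raises(DataError, match="saturated"):
            build_tree(dm, "nj")


def _clean_split_alignment(n_noise=0, seed=0, length=200):
    """Two 2-taxon clades differing at half the sites."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), length)
    other = base.copy()
    flip = rng.choice(length, length // 2, replace=False)
    for i in flip:
        other[i] = rng.choice([b for b in "ACGT" if b != other[i]])
    seqs = []
    for name, template in [("a1", base), ("a2", base),
                           ("b1", other), ("b2", other)]:
        t = template.copy()
        noise = rng.choice(length, n_noise, replace=False)
        for i in noise:
            t[i] = rng.choice(list("ACGT"))
        seqs.append(SequenceRecord(id=name, bases="".join(t)))
    return seqs


class TestBootstrap:
    def test_deterministic_given_seed(self):
        aln = _clean_split_alignment(n_noise=10)
        t1 = bootstrap_support(aln, B=25, seed=5)
        t2 = bootstrap_support(aln, B=25, seed=5)
        assert t1.support_map() == t2.support_map()

    def test_clean_split_gets_high_support(self):
        hits = 0
        for seed in range(5):
            aln = _clean_split_alignment(n_noise=4, seed=seed)
            tree = bootstrap_support(aln, B=100, seed=seed)
            support = tree.support_map().get(frozenset({"b1", "b2"}), 0.0)
            hits += support >= 0.95
        assert hits >= 4

    def test_single_replicate_supports_binary(self):
        aln = _clean_split_alignment(n_noise=10)
        tree = bootstrap_support(aln, B=1, seed=0)
        assert set(tree.support_map().values()) <= {0.0, 1.0}

    def test_too_few_sequences_error(self):
        aln = _clean_split_alignment()[:3]
        with pytest.raises(DataError):
            bootstrap_support(aln, B=10, seed=0)


class TestPolarise:
    def test_midpoint_on_symmetric_path(self):
        tree = parse_newick("((A:2,B:2):0,C:1,D:1);")
        tree.rooted = False
        rooted = polarise(tree, "midpoint")
        # longest path A-B (length 4): root halves it
        depths = rooted.tip_depths()
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_outgroup_roots_on_pendant_edge(self):
        tree = parse_newick("((A:1,B:1):1,C:3,D:1);")
        tree.rooted = False
        rooted = polarise(tree, "outgroup", outgroup_ids=["C"])
        (og,) = [c for c in rooted.root.child_nodes() if c.is_leaf()]
        assert og.taxon.label == "C"

    @pytest.mark.parametrize("mode,og", [("midpoint", None),
                                         ("outgroup", ["C"]),
                                         ("outgroup", ["A", "B"])])
    def test_rooting_preserves_tip_paths_and_supports(self, mode, og):
        tree = parse_newick("((A:1,B:1)0.9:1,C:2,(D:3,E:1)0.8:1);")
        tree.rooted = False
        before = _path_lengths(tree)
        sup_before = tree.support_map()
        rooted = polarise(tree, mode, outgroup_ids=og)
        after = _path_lengths(rooted)
        for pair in before:
            assert after[pair] == pytest.approx(before[pair], abs=1e-9)
        assert rooted.support_map() == sup_before


class TestUltrametricity:
    def test_nonclocklike_tree_fails(self):
        tree = parse_newick("((A:2,B:1):1,C:2);")
        ok, dev = check_ultrametric(tree, tol=1e-6)
        assert not ok and dev > 0.1

    def test_infinite_tolerance_always_passes(self):
        tree = parse_newick("((A:2,B:1):1,C:2);")
        ok, _ = check_ultrametric(tree, tol=np.inf)
        assert ok

    def test_resolution_snap_collapses_tiny_ages(self, small_survey):
        tree = upgma_from_alignment(small_survey.aligned_records)
        L = len(small_survey.aligned_records[0].bases)
        tiny = [a for n, a in tree.node_ages().items()
                if not n.is_leaf() and 1e-9 < a < 0.5 / L]
        assert tiny == []
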