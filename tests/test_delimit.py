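import math

import numpy as np
import pytest
from scipy import stats

from barcodiv.delimit import (GmycParams, candidate_thresholds,
                              _profile_lambdas, gmyc_fit, gmyc_intervals,
                              gmyc_loglik, gmyc_lr_test, null_loglik,
                              ptp_fit, _delimitation_loglik,
                              _enumerate_antichains)
from barcodiv.errors import DataError
from barcodiv.phylo import parse_newick
from tests.conftest import random_tree_newick


def brute_force_gmyc(tree, grid=26):
    """Independent threshold-scan oracle: dense exponent grid + profiled
    rates at every candidate threshold."""
    best = (-np.inf, None)
    ps = np.linspace(0.0, 10.0, grid)
    for T in candidate_thresholds(tree):
        iv = gmyc_intervals(tree, T)
        logL = max(_profile_lambdas(iv, p1, p2)[2]
                   for p1 in ps for p2 in ps)
        # local polish around the best grid point
        from scipy.optimize import minimize
        coarse = max(((p1, p2) for p1 in ps for p2 in ps),
                     key=lambda p: _profile_lambdas(iv, *p)[2])
        res = minimize(lambda p: -_profile_lambdas(
            iv, min(max(p[0], 0), 10), min(max(p[1], 0), 10))[2],
            coarse, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10})
        logL = max(logL, -res.fun)
        if logL > best[0]:
            best = (logL, T)
    return best


class TestIntervals:
    def test_two_tip_tree_single_interval(self):
        tree = parse_newick("(A:1,B:1);")
        iv = gmyc_intervals(tree, np.inf)
        assert iv.x.tolist() == [1.0]
        assert iv.n_total.tolist() == [2]

    def test_four_tip_hand_enumeration(self, two_cluster_tree):
        iv = gmyc_intervals(two_cluster_tree, 0.5)
        assert iv.n_entities == 2
        assert sorted(iv.partition.values()) == ["ent1", "ent1",
                                                 "ent2", "ent2"]
        # intervals: (1.0 -> 0.01) with 2 entity stems, then the tie at 0.01
        # collapses, leaving (0.01 -> 0) with both pairs coalescing
        assert iv.x == pytest.approx([0.99, 0.01])
        assert iv.n_div.tolist() == [2, 2]
        assert iv.coal[0].tolist() == pytest.approx([0.0, 0.0])
        assert sorted(iv.coal[1].tolist()) == pytest.approx([2.0, 2.0])

    def test_threshold_below_all_nodes_pure_yule(self, two_cluster_tree):
        iv = gmyc_intervals(two_cluster_tree, 0.005)
        assert iv.n_entities == 4
        assert (iv.coal == 0).all()

    def test_interval_count_and_age_sum(self, two_cluster_tree):
        iv = gmyc_intervals(two_cluster_tree, 0.5)
        assert iv.x.sum() == pytest.approx(1.0)  # root age


class TestLoglik:
    def test_two_tip_null_closed_form(self):
        tree = parse_newick("(A:1,B:1);")
        iv = gmyc_intervals(tree, np.inf)
        assert null_loglik(iv, 1.0, 1.0) == pytest.approx(math.log(2) - 2)

    def test_zero_exponents_reduce_to_constant_rates(self, two_cluster_tree):
        iv = gmyc_intervals(two_cluster_tree, 0.5)
        params = GmycParams(1.3, 0.0, 2.0, 0.0, 0.5)
        # brute-force sum: b_i = lam1 + lam2 * (#entities with >= 2 lineages)
        expected = 0.0
        for i in range(len(iv.x)):
            k = int((iv.coal[i] > 0).sum())
            b = 1.3 + 2.0 * k
            expected += math.log(b) - b * iv.x[i]
        assert gmyc_loglik(iv, params) == pytest.approx(expected)

    def test_exponential_scale_equivariance(self):
        a = parse_newick("((A:0.2,B:0.2):0.8,(C:0.4,D:0.4):0.6);")
        b = parse_newick("((A:0.6,B:0.6):2.4,(C:1.2,D:1.2):1.8);")
        c = 3.0
        iva, ivb = gmyc_intervals(a, 0.5), gmyc_intervals(b, 1.5)
        pa = GmycParams(1.2, 0.7, 30.0, 0.3, 0.5)
        pb = GmycParams(1.2 / c, 0.7, 30.0 / c, 0.3, 1.5)
        assert gmyc_loglik(ivb, pb) - gmyc_loglik(iva, pa) == pytest.approx(
            -len(iva.x) * math.log(c))


class TestGmycFit:
    def test_two_cluster_tree_delimited(self, two_cluster_tree):
        fit = gmyc_fit(two_cluster_tree)
        assert 0.01 < fit.params.threshold < 0.99
        assert fit.n_entities == 2 and fit.n_clusters == 2
        assert set(fit.partition.values()) == {"ent1", "ent2"}
        assert fit.partition["A"] == fit.partition["B"]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_threshold_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = parse_newick(random_tree_newick(rng, int(rng.integers(5, 10)),
                                               ultrametric=True))
        fit = gmyc_fit(tree, seed=seed)
        oracle_logL, _ = brute_force_gmyc(tree)
        assert fit.logL == pytest.approx(oracle_logL, abs=1e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_nested_null_never_beats_mixed(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = parse_newick(random_tree_newick(rng, 8, ultrametric=True))
        fit = gmyc_fit(tree, seed=seed)
        assert fit.logL >= fit.logL_null - 1e-6
        assert fit.LR >= 0.0

    def test_ci_contains_point_estimate(self, small_survey):
        from barcodiv.trees import upgma_from_alignment
        fit = gmyc_fit(upgma_from_alignment(small_survey.aligned_records))
        lo, hi = fit.ci_entities
        assert lo <= fit.n_entities <= hi
        assert 1 <= lo and hi <= 18

    def test_threshold_extremes_entity_counts(self, two_cluster_tree):
        below = gmyc_intervals(two_cluster_tree, 1e-6)
        assert below.n_entities == two_cluster_tree.n_tips
        above = gmyc_intervals(two_cluster_tree, 10.0)
        assert above.n_entities == 1

    def test_non_ultrametric_rejected(self):
        tree = parse_newick("((A:2,B:1):1,C:2);")
        with pytest.raises(DataError, match="ultrametric"):
            gmyc_fit(tree)


class TestLrTest:
    def test_equal_likelihoods_give_p_one(self, two_cluster_tree):
        fit = gmyc_fit(two_cluster_tree)
        fit.logL = fit.logL_null
        lr, p = gmyc_lr_test(fit)
        assert lr == 0.0 and p == 1.0

    def test_chi2_three_df_quantile(self, two_cluster_tree):
        fit = gmyc_fit(two_cluster_tree)
        fit.logL = fit.logL_null + 7.815 / 2.0
        _, p = gmyc_lr_test(fit)
        assert p == pytest.approx(0.05, abs=0.001)

    def test_p_monotone_in_lr(self):
        ps = [float(stats.chi2.sf(lr, 3)) for lr in (0.5, 2.0, 8.0, 20.0)]
        assert ps == sorted(ps, reverse=True)


class TestPtp:
    def test_two_cluster_tree_exact_and_greedy_agree(self):
        tree = parse_newick(
            "(((a1:0.01,a2:0.01):0.012,(a3:0.01,a4:0.015):0.01):0.5,"
            "((b1:0.012,b2:0.01):0.01,(b3:0.01,b4:0.01):0.013):0.5);")
        exact = ptp_fit(tree, "exact")
        greedy = ptp_fit(tree, "greedy")
        assert exact.n_species == 2
        assert greedy.n_species == 2
        assert exact.partition == greedy.partition
        assert exact.partition["a1"] == exact.partition["a4"]
        assert exact.partition["a1"] != exact.partition["b1"]

    def test_equal_edges_prefer_single_species(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert ptp_fit(tree, "exact").n_species == 1
        assert ptp_fit(tree, "greedy").n_species == 1

    def test_two_tip_boundary(self):
        fit = ptp_fit(parse_newick("(a:0.1,b:0.1);"), "greedy")
        assert fit.n_species in (1, 2)

    def test_exact_mode_tip_limit(self):
        rng = np.random.default_rng(0)
        tree = parse_newick(random_tree_newick(rng, 14))
        with pytest.raises(DataError):
            ptp_fit(tree, "exact")

    def test_antichain_enumeration_counts(self):
        # balanced 4-tip tree: cuts = {root}, {child x cuts(child)} ...
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        cuts = _enumerate_antichains(tree)
        # {root}; {L,R}; {L,{c,d}}; {{a,b},R}; {{a,b},{c,d}}
        assert len(cuts) == 5
        for roots in cuts:
            covered = sorted(
                lab for r in roots for lab in
                [lf.taxon.label for lf in r.leaf_iter()])
            assert covered == ["a", "b", "c", "d"]

    @pytest.mark.parametrize("seed", range(20))
    def test_greedy_matches_exact_on_random_trees(self, seed):
        rng = np.random.default_rng(2000 + seed)
        tree = parse_newick(random_tree_newick(rng, 8))
        exact = ptp_fit(tree, "exact")
        greedy = ptp_fit(tree, "greedy")
        assert greedy.logL <= exact.logL + 1e-9
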