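import itertools
import shutil
import subprocess
from math import comb

import numpy as np
import pandas as pd
import pytest

from barcodiv.errors import DataError
from barcodiv.records import IncidenceMatrix
from barcodiv.richness import (accumulation_curve, completeness,
                               richness_estimate, richness_report)


def make_incidence(m, Q_counts, seed=0):
    """Incidence matrix with a prescribed number of events m and species
    occupancy counts (list of Y_i values)."""
    rng = np.random.default_rng(seed)
    rows = {}
    for i, y in enumerate(Q_counts):
        events = rng.choice(m, size=y, replace=False)
        row = np.zeros(m, int)
        row[events] = 1
        rows[f"sp{i}"] = row
    return IncidenceMatrix(pd.DataFrame(
        rows, index=[f"e{j}" for j in range(m)]).T)


@pytest.fixture
def printed_example():
    """m=10 events, S_obs=25, Q1=5 singletons, Q2=2 doubletons."""
    Y = [1] * 5 + [2] * 2 + [4] * 10 + [7] * 8
    return make_incidence(10, Y)


class TestEstimators:
    def test_chao2_closed_form(self, printed_example):
        est = richness_estimate(printed_example, "chao2")
        assert est.inputs == {"m": 10, "Q1": 5, "Q2": 2}
        assert est.S_hat == pytest.approx(25 + (9 / 10) * 25 / 4)  # 30.625

    def test_jackknife1_closed_form(self, printed_example):
        est = richness_estimate(printed_example, "jackknife1")
        assert est.S_hat == pytest.approx(29.5)

    def test_jackknife2_exceeds_jackknife1_with_singletons(self,
                                                           printed_example):
        j1 = richness_estimate(printed_example, "jackknife1").S_hat
        j2 = richness_estimate(printed_example, "jackknife2").S_hat
        assert j2 >= j1

    def test_no_singletons_means_no_unseen_signal(self):
        inc = make_incidence(10, [3] * 20)
        assert richness_estimate(inc, "chao2").S_hat == pytest.approx(20.0)

    def test_bias_corrected_form_when_no_doubletons(self):
        inc = make_incidence(10, [1] * 4 + [5] * 6)
        est = richness_estimate(inc, "chao2")
        assert est.S_hat == pytest.approx(10 + (9 / 10) * 4 * 3 / 2)

    def test_chao1_on_abundances(self):
        counts = np.array([1, 1, 1, 2, 2, 5, 9, 14])
        est = richness_estimate(counts, "chao1")
        assert est.inputs == {"f1": 3, "f2": 2}
        assert est.S_hat == pytest.approx(8 + 9 / 4)

    def test_single_event_rejected(self):
        inc = make_incidence(1, [1, 1])
        with pytest.raises(DataError):
            richness_estimate(inc, "chao2")

    def test_relabelling_invariance(self, printed_example):
        shuffled = IncidenceMatrix(
            printed_example.counts.sample(frac=1.0, random_state=1)
            [list(np.random.default_rng(2).permutation(
                printed_example.events))])
        for name in ("chao2", "jackknife1", "jackknife2"):
            assert richness_estimate(shuffled, name).S_hat == pytest.approx(
                richness_estimate(printed_example, name).S_hat)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_against_vegan_specpool(self, printed_example, tmp_path):
        """Independent oracle: vegan::specpool on the same incidence."""
        csv = tmp_path / "inc.csv"
        pd.DataFrame(printed_example.incidence.T,
                     columns=printed_example.species).to_csv(csv, index=False)
        script = tmp_path / "pool.R"
        script.write_text(
            'x <- read.csv("%s"); suppressMessages(library(vegan));\n'
            'p <- specpool(x); cat(p$chao, p$jack1, p$jack2, sep="\\n")\n'
            % csv)
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        chao, j1, j2 = map(float, out)
        assert richness_estimate(printed_example,
                                 "chao2").S_hat == pytest.approx(chao, abs=1e-4)
        assert richness_estimate(printed_example,
                                 "jackknife1").S_hat == pytest.approx(
            j1, abs=1e-4)
        assert richness_estimate(printed_example,
                                 "jackknife2").S_hat == pytest.approx(
            j2, abs=1e-4)


class TestAccumulation:
    def test_full_effort_returns_observed_richness(self, printed_example):
        curve = accumulation_curve(printed_example, "analytic")
        assert curve[-1] == pytest.approx(printed_example.n_species)
        assert (np.diff(curve) >= -1e-12).all()

    def test_ubiquitous_species_constant_curve(self):
        inc = make_incidence(6, [6])
        assert accumulation_curve(inc, "analytic") == pytest.approx(
            np.ones(6))

    def test_analytic_equals_exhaustive_subset_average(self):
        inc = make_incidence(6, [1, 2, 2, 4, 6], seed=3)
        curve = accumulation_curve(inc, "analytic")
        binary = inc.incidence
        m = inc.n_events
        for t in range(1, m + 1):
            total = 0.0
            for subset in itertools.combinations(range(m), t):
                total += (binary[:, list(subset)].sum(axis=1) > 0).sum()
            assert curve[t - 1] == pytest.approx(total / comb(m, t))

    def test_permutation_mode_matches_analytic(self, printed_example):
        analytic = accumulation_curve(printed_example, "analytic")
        perm = accumulation_curve(printed_example, "permutation", R=1000,
                                  seed=4)
        assert perm == pytest.approx(analytic, abs=0.35)

    def test_permutation_deterministic_given_seed(self, printed_example):
        a = accumulation_curve(printed_example, "permutation", R=50, seed=9)
        b = accumulation_curve(printed_example, "permutation", R=50, seed=9)
        assert a == pytest.approx(b)


class TestCompleteness:
    def test_division(self, printed_example):
        est = richness_estimate(printed_example, "chao2")
        assert completeness(25, est) == pytest.approx(25 / 30.625)

    def test_complete_inventory(self):
        inc = make_incidence(10, [3] * 12)
        est = richness_estimate(inc, "chao2")
        assert completeness(12, est) == pytest.approx(1.0)

    def test_report_spans_interval(self, printed_example):
        report = richness_report(printed_example)
        fracs = [completeness(est.S_obs, est) for est in report.values()]
        assert min(fracs) < max(fracs)
        assert all(0 < f <= 1 for f in fracs)

    def test_exhaustive_sampling_converges(self):
        # sampling a closed 20-species community at 3 depths: the estimate
        # approaches truth and completeness approaches 1
        rng = np.random.default_rng(5)
        S_true = 20
        gaps = []
        for m in (4, 12, 40):
            obs_sp, obs_ev = [], []
            for e in range(m):
                for sp in rng.choice(S_true, size=6, replace=False):
                    obs_sp.append(f"sp{sp}")
                    obs_ev.append(f"e{e}")
            inc = IncidenceMatrix.from_observations(obs_sp, obs_ev)
            est = richness_estimate(inc, "chao2")
            gaps.append(abs(est.S_hat - S_true)
                        + (S_true - inc.n_species))
        assert gaps[-1] <= gaps[0]
        assert gaps[-1] < 1.0
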