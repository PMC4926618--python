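"""Rarefaction/accumulation curves and nonparametric species-richness
extrapolation over sampling events.

Incidence-based estimators (Chao2, first- and second-order jackknife) act on
a species-by-event incidence matrix; the abundance-based Chao1 acts on a
vector of per-species individual counts.  Observed richness divided by an
extrapolated total gives an inventory-completeness fraction, and reporting
the completeness over several estimators yields the usual min-max interval.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .errors import DataError
from .records import IncidenceMatrix

ESTIMATORS = ("chao2", "chao1", "jackknife1", "jackknife2")


@dataclass(frozen=True)
class RichnessEstimate:
    estimator: str
    S_obs: int
    S_hat: float
    se: float | None
    inputs: dict

    def __post_init__(self):
        if self.estimator not in ESTIMATORS:
            raise DataError(f"unknown estimator {self.estimator!r}")
        if self.S_hat < self.S_obs - 1e-9:
            raise DataError("extrapolated richness below observed richness")


def accumulation_curve(inc: IncidenceMatrix, mode: str = "analytic",
                       R: int = 1000, seed: int = 0) -> np.ndarray:
    """Expected species count after t = 1..m sampling events.

    Analytic mode uses the hypergeometric rarefaction formula
    ``E[S_t] = sum_i [1 - C(m - Y_i, t) / C(m, t)]`` with ``Y_i`` the number
    of events containing species i; permutation mode averages accumulation
    over ``R`` seeded random event orderings.  Both are nondecreasing and end
    at the observed richness.
    """
    m = inc.n_events
    Y = inc.incidence_frequencies()
    if mode == "analytic":
        out = np.empty(m)
        for t in range(1, m + 1):
            out[t - 1] = sum(1.0 - comb(m - y, t) / comb(m, t) for y in Y)
        return out
    if mode == "permutation":
        if R < 1:
            raise ValueError("R must be >= 1 for permutation mode")
        rng = np.random.default_rng(seed)
        binary = inc.incidence
        total = np.zeros(m)
        for _ in range(R):
            order = rng.permutation(m)
            seen = np.cumsum(binary[:, order], axis=1) > 0
            total += seen.sum(axis=0)
        return total / R
    raise ValueError(f"unknown accumulation mode {mode!r}")


def richness_estimate(data: IncidenceMatrix | np.ndarray,
                      estimator: str = "chao2") -> RichnessEstimate:
    """Extrapolate total species richness.

    Incidence estimators (chao2, jackknife1, jackknife2) take an
    :class:`IncidenceMatrix` with at least two events; chao1 takes a
    per-species abundance vector.  Chao estimators switch to the
    bias-corrected form when the doubleton count is zero.
    """
    if estimator == "chao1":
        counts = np.asarray(data.counts.to_numpy().sum(axis=1)
                            if isinstance(data, IncidenceMatrix) else data)
        counts = counts[counts > 0]
        S_obs = len(counts)
        f1 = int((counts == 1).sum())
        f2 = int((counts == 2).sum())
        S_hat, se = _chao(S_obs, f1, f2, correction=1.0)
        return RichnessEstimate("chao1", S_obs, S_hat, se,
                                {"f1": f1, "f2": f2})
    if not isinstance(data, IncidenceMatrix):
        raise DataError(f"{estimator} requires an incidence matrix")
    m = data.n_events
    if m < 2:
        raise DataError("incidence estimators require >= 2 sampling events")
    Y = data.incidence_frequencies()
    S_obs = data.n_species
    Q1 = int((Y == 1).sum())
    Q2 = int((Y == 2).sum())
    inputs = {"m": m, "Q1": Q1, "Q2": Q2}
    if estimator == "chao2":
        S_hat, se = _chao(S_obs, Q1, Q2, correction=(m - 1) / m)
        return RichnessEstimate("chao2", S_obs, S_hat, se, inputs)
    if estimator == "jackknife1":
        S_hat = S_obs + Q1 * (m - 1) / m
        return RichnessEstimate("jackknife1", S_obs, S_hat, None, inputs)
    if estimator == "jackknife2":
        S_hat = (S_obs + Q1 * (2 * m - 3) / m
                 - Q2 * (m - 2) ** 2 / (m * (m - 1)))
        return RichnessEstimate("jackknife2", S_obs, max(S_hat, float(S_obs)),
                                None, inputs)
    raise DataError(f"unknown estimator {estimator!r}")


def _chao(S_obs: int, q1: int, q2: int, correction: float
          ) -> tuple[float, float | None]:
    """Chao-type estimate with the classic or (at q2=0) bias-corrected form,
    plus the standard asymptotic variance."""
    if q2 > 0:
        extra = correction * q1 * q1 / (2.0 * q2)
        r = q1 / q2
        var = q2 * correction * (0.5 * r ** 2 + correction * r ** 3
                                 + 0.25 * correction * r ** 4)
    else:
        extra = correction * q1 * (q1 - 1) / 2.0
        var = (correction * q1 * (q1 - 1) / 2.0
               + correction ** 2 * q1 * (2 * q1 - 1) ** 2 / 4.0)
        if extra > 0:
            var -= correction ** 2 * q1 ** 4 / max(4.0 * (S_obs + extra),
                                                   1e-300)
    return S_obs + extra, float(np.sqrt(max(var, 0.0)))


def completeness(S_obs: int, est: RichnessEstimate) -> float:
    """Fraction of the extrapolated total richness already observed."""
    if est.S_hat < S_obs:
        raise DataError("S_hat below S_obs")
    return S_obs / est.S_hat if est.S_hat > 0 else 1.0


def richness_report(inc: IncidenceMatrix) -> dict[str, RichnessEstimate]:
    """All incidence estimators (plus chao1 on pooled abundances) at once;
    the span of the estimates gives the richness and completeness intervals."""
    out = {name: richness_estimate(inc, name)
           for name in ("chao2", "jackknife1", "jackknife2")}
    out["chao1"] = richness_estimate(inc, "chao1")
    return out
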