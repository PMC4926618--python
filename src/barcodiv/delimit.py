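"""Single-locus species delimitation.

Two tree-based methods that need no prior species hypotheses:

* The single-threshold general mixed Yule-coalescent model (GMYC).  On an
  ultrametric gene tree, branching events older than a threshold age T are
  treated as speciation (Yule) events and events younger than T as neutral
  within-species coalescences.  Between successive branching events the
  combined event rate is

      b_i = lambda1 * n_d,i**p1  +  lambda2 * sum_j [n_j,i (n_j,i - 1)]**p2

  where ``n_d,i`` counts species-level lineages in interval i and ``n_j,i``
  the within-entity lineages of entity j (entities with a single lineage
  contribute nothing).  Waiting times are exponential with rate b_i, giving
  log L = sum_i [ln b_i - b_i x_i].  The null model is a single process with
  ``b_i = lambda [n_i (n_i-1)]**p`` over the whole tree; the likelihood-ratio
  statistic is referred to a chi-square with 3 degrees of freedom.  The
  profile over all candidate thresholds also yields a confidence range of
  entity counts (thresholds within 2 log-likelihood units of the optimum).

* The Poisson tree processes model (PTP) in its maximum-likelihood form,
  which classifies branch lengths (substitutions/site, no ultrametricity
  required) into speciation and coalescent exponential classes over an
  antichain of species roots.

"Entities" include singletons; "clusters" are entities with at least two
sampled tips.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DataError, NumericalError
from .phylo import PhyloTree, tip_label
from .trees import check_ultrametric

logger = logging.getLogger(__name__)

LOG_LAMBDA_BOUNDS = (np.log(1e-8), np.log(1e6))
P_BOUNDS = (0.0, 10.0)
CI_DELTA_LOGL = 2.0
LR_DOF = 3


# ====================================================================== GMYC
@dataclass(frozen=True)
class GmycParams:
    """Mixed-model parameters: branching rates, scaling exponents, threshold."""

    lambda1: float
    p1: float
    lambda2: float
    p2: float
    threshold: float

    def __post_init__(self):
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise DataError("rates must be strictly positive")
        if not (P_BOUNDS[0] <= self.p1 <= P_BOUNDS[1]
                and P_BOUNDS[0] <= self.p2 <= P_BOUNDS[1]):
            raise DataError("scaling exponents out of bounds")


@dataclass
class IntervalTable:
    """Inter-branching-event intervals of an ultrametric tree at threshold T.

    ``x`` holds the n-1 waiting times oldest-first, ``n_div`` the
    species-level lineage count per interval, ``n_total`` the total lineage
    count (for the null model), and ``coal`` a zero-padded matrix whose row i
    lists ``n_j(n_j - 1)`` for every entity j with >= 2 lineages in
    interval i.
    """

    threshold: float
    x: np.ndarray
    n_div: np.ndarray
    n_total: np.ndarray
    coal: np.ndarray
    partition: dict[str, str]

    @property
    def n_entities(self) -> int:
        return len(set(self.partition.values()))

    @property
    def n_clusters(self) -> int:
        sizes: dict[str, int] = {}
        for ent in self.partition.values():
            sizes[ent] = sizes.get(ent, 0) + 1
        return sum(1 for v in sizes.values() if v >= 2)


@dataclass
class GmycFit:
    params: GmycParams
    logL: float
    logL_null: float
    null_params: tuple[float, float]
    partition: dict[str, str]
    n_entities: int
    n_clusters: int
    ci_entities: tuple[int, int]
    threshold_profile: list[tuple[float, float, int]]  # (T, logL, n_entities)

    @property
    def LR(self) -> float:
        return max(2.0 * (self.logL - self.logL_null), 0.0)

    @property
    def p_value(self) -> float:
        return float(stats.chi2.sf(self.LR, LR_DOF))


def candidate_thresholds(tree: PhyloTree) -> list[float]:
    """Midpoints between consecutive distinct node ages, plus one above the
    root and one below the shallowest branching event."""
    ages = sorted({round(a, 12) for n, a in tree.node_ages().items()
                   if not n.is_leaf()})
    if not ages:
        raise DataError("tree has no internal nodes")
    cands = [ages[0] / 2.0]
    for lo, hi in zip(ages, ages[1:]):
        cands.append((lo + hi) / 2.0)
    cands.append(ages[-1] * 1.5 if ages[-1] > 0 else 1.0)
    return cands


def gmyc_intervals(tree: PhyloTree, T: float) -> IntervalTable:
    """Interval table at threshold age ``T``.

    Nodes older than T are diversification events; edges crossing T subtend
    the entities.  Ties in node ages (non-binary resolutions) produce
    zero-length intervals, which is logged and harmless to the likelihood
    only if removed, so coincident ages are collapsed into single intervals.
    """
    ages = tree.node_ages()
    internal_ages = sorted((a for n, a in ages.items() if not n.is_leaf()),
                           reverse=True)
    n_tips = tree.n_tips
    if n_tips < 2:
        raise DataError("interval table requires >= 2 tips")

    # entity assignment: highest edge crossing T roots an entity
    entity_of: dict = {}
    entities: list = []
    for node in tree.dt.preorder_node_iter():
        parent = node.parent_node
        if parent is not None and entity_of.get(parent) is not None:
            entity_of[node] = entity_of[parent]
            continue
        parent_age = ages[parent] if parent is not None else np.inf
        if ages[node] < T <= parent_age:
            entity_of[node] = len(entities)
            entities.append(node)
        else:
            entity_of[node] = None
    partition = {}
    for lf in tree.leaves():
        ent = entity_of[lf]
        partition[tip_label(lf)] = f"ent{(ent if ent is not None else 0) + 1}"
    n_entities = max(len(entities), 1)

    bounds = internal_ages + [0.0]
    x, n_div, n_total, coal_rows = [], [], [], []
    k = 1  # lineages before the first (root) event
    for hi, lo in zip(bounds, bounds[1:]):
        k += 1  # each event adds one lineage (ties handled by zero x)
        if hi - lo <= 0:
            continue
        x.append(hi - lo)
        n_total.append(k)
        if lo >= T:
            n_div.append(k)
            coal_rows.append([])
        else:
            n_div.append(n_entities)
            counts: dict[int, int] = {}
            for node, ent in entity_of.items():
                if ent is None or node.parent_node is None:
                    continue
                # edge alive during (lo, hi)?
                if ages[node] <= lo and ages[node.parent_node] >= hi:
                    counts[ent] = counts.get(ent, 0) + 1
            coal_rows.append(sorted(c * (c - 1) for c in counts.values()
                                    if c >= 2))
    width = max((len(r) for r in coal_rows), default=0)
    coal = np.zeros((len(x), max(width, 1)))
    for i, row in enumerate(coal_rows):
        coal[i, :len(row)] = row
    return IntervalTable(threshold=T, x=np.array(x), n_div=np.array(n_div),
                         n_total=np.array(n_total), coal=coal,
                         partition=partition)


def gmyc_loglik(iv: IntervalTable, params: GmycParams) -> float:
    """Mixed-model log-likelihood of an interval table."""
    b = _mixed_rates(iv, params.lambda1, params.p1, params.lambda2, params.p2)
    if (b <= 0).any():
        raise DataError("nonpositive event rate; parameter bounds violated")
    return float(np.sum(np.log(b) - b * iv.x))


def _mixed_rates(iv, lam1, p1, lam2, p2):
    with np.errstate(over="ignore"):
        div = lam1 * np.power(iv.n_div.astype(float), p1)
        safe = np.where(iv.coal > 0, iv.coal, 1.0)
        coal = lam2 * (np.power(safe, p2) * (iv.coal > 0)).sum(axis=1)
    return div + coal


def null_loglik(iv: IntervalTable, lam: float, p: float) -> float:
    """Single-process null: b_i = lam * [n_i (n_i - 1)]**p."""
    base = (iv.n_total * (iv.n_total - 1)).astype(float)
    with np.errstate(over="ignore"):
        b = lam * np.power(base, p)
    if (b <= 0).any() or not np.isfinite(b).all():
        return -np.inf
    return float(np.sum(np.log(b) - b * iv.x))


_LAM_MIN, _LAM_MAX = np.exp(LOG_LAMBDA_BOUNDS[0]), np.exp(LOG_LAMBDA_BOUNDS[1])


def _profile_lambdas(iv: IntervalTable, p1: float, p2: float
                     ) -> tuple[float, float, float]:
    """Best (lambda1, lambda2) and log-likelihood at fixed exponents.

    At fixed (p1, p2) the log-likelihood is concave in the rates, so the
    two-rate inner problem is solved reliably by a gradient quasi-Newton
    search in log-rate space (with closed forms when one class is absent).
    """
    with np.errstate(over="ignore"):
        A = np.power(iv.n_div.astype(float), p1)
        safe = np.where(iv.coal > 0, iv.coal, 1.0)
        B = (np.power(safe, p2) * (iv.coal > 0)).sum(axis=1)
    SAx = float(A @ iv.x)
    SBx = float(B @ iv.x)
    n_int = len(iv.x)
    if SBx == 0.0:  # no within-entity branching anywhere: pure Yule part
        lam1 = np.clip(n_int / SAx, _LAM_MIN, _LAM_MAX)
        logL = float(np.sum(np.log(lam1 * A)) - lam1 * SAx)
        return float(lam1), _LAM_MIN, logL

    warm = getattr(iv, "_warm", None)
    lam1, lam2, logL = _newton_rates(A, B, iv.x, SAx, SBx, n_int, warm)
    iv._warm = (lam1, lam2)
    return lam1, lam2, logL


def _newton_rates(A, B, x, SAx, SBx, n_int, warm=None):
    """Projected Newton ascent for the concave two-rate inner problem."""

    def value(l1, l2):
        return float(np.sum(np.log(l1 * A + l2 * B)) - l1 * SAx - l2 * SBx)

    l = np.clip(warm if warm is not None
                else [n_int / (2.0 * SAx), n_int / (2.0 * SBx)],
                _LAM_MIN, _LAM_MAX)
    l = np.asarray(l, dtype=float)
    cur = value(*l)
    for _ in range(100):
        b = l[0] * A + l[1] * B
        Ab, Bb = A / b, B / b
        G = np.array([Ab.sum() - SAx, Bb.sum() - SBx])
        # active-set projection at the box bounds
        fixed = ((l <= _LAM_MIN) & (G < 0)) | ((l >= _LAM_MAX) & (G > 0))
        if fixed.all():
            break
        H = np.array([[np.sum(Ab * Ab), np.sum(Ab * Bb)],
                      [np.sum(Ab * Bb), np.sum(Bb * Bb)]])
        if fixed.any():
            free = ~fixed
            step = np.zeros(2)
            idx = int(np.flatnonzero(free)[0])
            step[idx] = G[idx] / max(H[idx, idx], 1e-300)
        else:
            det = H[0, 0] * H[1, 1] - H[0, 1] ** 2
            if det <= 1e-300:
                step = G / np.maximum(np.diag(H), 1e-300)
            else:
                step = np.array([
                    (H[1, 1] * G[0] - H[0, 1] * G[1]) / det,
                    (H[0, 0] * G[1] - H[0, 1] * G[0]) / det,
                ])
        t = 1.0
        improved = False
        for _ in range(40):
            trial = np.clip(l + t * step, _LAM_MIN, _LAM_MAX)
            v = value(*trial)
            if v >= cur:
                improved = v > cur + 1e-14
                l, cur = trial, v
                break
            t *= 0.5
        if not improved:
            break
    return float(l[0]), float(l[1]), cur


_P_GRID = np.array([0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 10.0])


def _batch_profile(iv: IntervalTable, pairs: np.ndarray) -> np.ndarray:
    """Profiled log-likelihood for many (p1, p2) exponent pairs at once.

    The concave two-rate inner problems are solved simultaneously by a
    vectorised projected-Newton ascent with per-problem backtracking.
    """
    x = iv.x
    n_int = len(x)
    P1, P2 = pairs[:, 0], pairs[:, 1]
    nd = iv.n_div.astype(float)
    A = np.power(nd[None, :], P1[:, None])
    B = np.empty((len(pairs), n_int))
    safe = np.where(iv.coal > 0, iv.coal, 1.0)
    nonzero = iv.coal > 0
    for p2 in np.unique(P2):
        rows = P2 == p2
        B[rows] = (np.power(safe, p2) * nonzero).sum(axis=1)[None, :]
    SAx = A @ x
    SBx = B @ x
    no_coal = SBx == 0.0
    l1 = np.clip(n_int / (2.0 * SAx), _LAM_MIN, _LAM_MAX)
    l2 = np.clip(np.where(no_coal, _LAM_MIN, n_int / (2.0 * np.maximum(SBx, 1e-300))),
                 _LAM_MIN, _LAM_MAX)
    l1 = np.where(no_coal, np.clip(n_int / SAx, _LAM_MIN, _LAM_MAX), l1)

    def values(v1, v2):
        b = v1[:, None] * A + v2[:, None] * B
        return np.log(b).sum(axis=1) - v1 * SAx - v2 * SBx

    cur = values(l1, l2)
    active = ~no_coal
    for _ in range(80):
        if not active.any():
            break
        b = l1[:, None] * A + l2[:, None] * B
        Ab, Bb = A / b, B / b
        G1 = Ab.sum(axis=1) - SAx
        G2 = Bb.sum(axis=1) - SBx
        H11 = (Ab * Ab).sum(axis=1)
        H22 = np.maximum((Bb * Bb).sum(axis=1), 1e-300)
        H12 = (Ab * Bb).sum(axis=1)
        det = H11 * H22 - H12 ** 2
        ok = det > 1e-300
        s1 = np.where(ok, (H22 * G1 - H12 * G2) / np.where(ok, det, 1.0),
                      G1 / H11)
        s2 = np.where(ok, (H11 * G2 - H12 * G1) / np.where(ok, det, 1.0),
                      G2 / H22)
        s1 = np.where(active, s1, 0.0)
        s2 = np.where(active, s2, 0.0)
        t = np.ones(len(pairs))
        improved = np.zeros(len(pairs), dtype=bool)
        n1, n2 = l1.copy(), l2.copy()
        for _ in range(35):
            todo = active & ~improved
            if not todo.any():
                break
            t1 = np.clip(l1 + t * s1, _LAM_MIN, _LAM_MAX)
            t2 = np.clip(l2 + t * s2, _LAM_MIN, _LAM_MAX)
            v = values(t1, t2)
            good = todo & (v >= cur)
            n1[good], n2[good] = t1[good], t2[good]
            improved |= good & (v > cur + 1e-13)
            cur = np.where(good, v, cur)
            t = np.where(todo & ~good, t * 0.5, t)
        l1, l2 = n1, n2
        active &= improved
    return cur


def _zoom_exponents(iv: IntervalTable, levels: int = 3) -> tuple[float, float,
                                                                 float]:
    """Hierarchical grid search over the exponents on the profiled surface."""
    g1 = g2 = _P_GRID
    best = None
    for _ in range(levels):
        pairs = np.array([(a, b) for a in g1 for b in g2])
        vals = _batch_profile(iv, pairs)
        k = int(np.argmax(vals))
        best = (pairs[k, 0], pairs[k, 1], float(vals[k]))
        step1 = np.diff(g1).max() if len(g1) > 1 else 1.0
        step2 = np.diff(g2).max() if len(g2) > 1 else 1.0
        g1 = np.clip(np.linspace(best[0] - step1, best[0] + step1, 7),
                     *P_BOUNDS)
        g2 = np.clip(np.linspace(best[1] - step2, best[1] + step2, 7),
                     *P_BOUNDS)
    return best


def _optimise_mixed(iv: IntervalTable, n_starts: int = 1, seed: int = 0
                    ) -> tuple[GmycParams, float]:
    """Maximise the mixed-model likelihood at one threshold.

    The rates are profiled out (the inner two-rate problem is concave), so
    the search runs over the two scaling exponents only: a hierarchical
    121-start grid, then a Nelder-Mead polish from its optimum plus
    ``n_starts - 1`` extra seeded random polishes.
    """
    rng = np.random.default_rng(seed)

    def neg_outer(p):
        if not (P_BOUNDS[0] <= p[0] <= P_BOUNDS[1]
                and P_BOUNDS[0] <= p[1] <= P_BOUNDS[1]):
            return 1e12
        return -_profile_lambdas(iv, p[0], p[1])[2]

    zp1, zp2, zval = _zoom_exponents(iv)
    starts = [np.array([zp1, zp2])]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(0.0, 3.0, size=2))
    best_x, best_val = np.array([zp1, zp2]), -zval
    for x0 in starts:
        res = optimize.minimize(neg_outer, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9,
                                         "maxfev": 120})
        if res.fun < best_val:
            best_x, best_val = np.clip(res.x, *P_BOUNDS), res.fun
    if not np.isfinite(best_val):
        raise NumericalError(
            f"mixed-model optimisation non-finite at threshold "
            f"{iv.threshold}")
    p1, p2 = float(best_x[0]), float(best_x[1])
    lam1, lam2, logL = _profile_lambdas(iv, p1, p2)
    logL = max(logL, zval)
    params = GmycParams(lambda1=max(lam1, _LAM_MIN), p1=p1,
                        lambda2=max(lam2, _LAM_MIN), p2=p2,
                        threshold=iv.threshold)
    return params, logL


def _null_profile(iv: IntervalTable, p: float) -> tuple[float, float]:
    """Closed-form best rate and log-likelihood of the null at exponent p."""
    base = (iv.n_total * (iv.n_total - 1)).astype(float)
    with np.errstate(over="ignore"):
        f = np.power(base, p)
    Sfx = float(f @ iv.x)
    lam = np.clip(len(iv.x) / Sfx, _LAM_MIN, _LAM_MAX)
    return float(lam), float(np.sum(np.log(lam * f)) - lam * Sfx)


def _optimise_null(iv: IntervalTable, n_starts: int = 5, seed: int = 0
                   ) -> tuple[tuple[float, float], float]:
    grid = [( _null_profile(iv, p)[1], p) for p in np.linspace(*P_BOUNDS, 41)]
    _, p0 = max(grid)
    res = optimize.minimize_scalar(
        lambda p: -_null_profile(iv, p)[1],
        bounds=(max(p0 - 0.3, P_BOUNDS[0]), min(p0 + 0.3, P_BOUNDS[1])),
        method="bounded", options={"xatol": 1e-10})
    p_hat = float(res.x)
    lam_hat, logL = _null_profile(iv, p_hat)
    return (lam_hat, p_hat), logL


def gmyc_fit(tree: PhyloTree, n_starts: int = 1, seed: int = 0,
             ultrametric_tol: float | None = None) -> GmycFit:
    """Profile the mixed Yule-coalescent likelihood over all candidate
    thresholds of an ultrametric tree."""
    if tree.n_tips < 3:
        raise DataError("GMYC requires >= 3 tips")
    ok, dev = check_ultrametric(tree, ultrametric_tol)
    if not ok:
        raise DataError(
            f"tree is not ultrametric (max deviation {dev:g}); rebuild with "
            f"UPGMA or supply a chronogram")
    null_iv = gmyc_intervals(tree, np.inf)
    null_params, logL_null = _optimise_null(null_iv, n_starts, seed)

    profile: list[tuple[float, float, int]] = []
    fits = []
    for idx, T in enumerate(candidate_thresholds(tree)):
        iv = gmyc_intervals(tree, T)
        try:
            params, logL = _optimise_mixed(iv, n_starts, seed + idx)
        except NumericalError:
            raise
        profile.append((T, logL, iv.n_entities))
        fits.append((logL, T, params, iv))
    logL, T_best, params, iv_best = max(fits, key=lambda f: f[0])

    if logL < logL_null - 1e-6:
        # the null is a boundary case of the mixed model; tiny optimisation
        # shortfalls are absorbed by reporting the null value
        logger.debug("mixed optimum %.6f below null %.6f; clamping",
                     logL, logL_null)
        logL = logL_null
    lr = 2.0 * (logL - logL_null)
    if lr < -1e-6:
        raise NumericalError("negative likelihood ratio; null must be nested")

    ents = [n for (_, l, n) in profile if l >= logL - CI_DELTA_LOGL]
    ci = (min(ents + [iv_best.n_entities]), max(ents + [iv_best.n_entities]))
    return GmycFit(params=params, logL=logL, logL_null=logL_null,
                   null_params=null_params, partition=iv_best.partition,
                   n_entities=iv_best.n_entities,
                   n_clusters=iv_best.n_clusters,
                   ci_entities=ci, threshold_profile=profile)


def gmyc_lr_test(fit: GmycFit) -> tuple[float, float]:
    """Likelihood-ratio test of the mixed model against the single-process
    null (chi-square, 3 df)."""
    return fit.LR, fit.p_value


# ======================================================================= PTP
@dataclass
class PtpFit:
    species_roots: list
    rate_spec: float | None
    rate_coal: float | None
    logL: float
    n_species: int
    partition: dict[str, str]


EPS_EDGE = 1e-9
PTP_EXACT_MAX_TIPS = 12


def _delimitation_loglik(tree: PhyloTree, roots: frozenset) -> float:
    """Two-class exponential likelihood of an antichain of species roots.

    Edges strictly inside a species (below its root node) are
    coalescent-class; all others — including the stem edge subtending each
    species root, which ends at the speciation-to-coalescence transition —
    are speciation-class.  An empty class collapses to the single-class
    model.  Zero-length edges count as EPS_EDGE.
    """
    spec_lengths, coal_lengths = [], []
    inside: dict = {}
    for node in tree.dt.preorder_node_iter():
        parent = node.parent_node
        inside[node] = parent is not None and (parent in roots
                                               or inside[parent])
        if parent is None:
            continue
        length = max(node.edge.length, EPS_EDGE)
        (coal_lengths if inside[node] else spec_lengths).append(length)
    classes = [c for c in (spec_lengths, coal_lengths) if c]
    if len(classes) == 1:
        lengths = np.array(classes[0])
        n, tot = len(lengths), lengths.sum()
        return float(n * np.log(n / tot) - n)
    out = 0.0
    for lengths in classes:
        arr = np.array(lengths)
        n, tot = len(arr), arr.sum()
        out += n * np.log(n / tot) - n
    return float(out)


def _rates(tree: PhyloTree, roots: frozenset) -> tuple[float | None,
                                                       float | None]:
    spec, coal = [], []
    inside: dict = {}
    for node in tree.dt.preorder_node_iter():
        parent = node.parent_node
        inside[node] = parent is not None and (parent in roots
                                               or inside[parent])
        if parent is None:
            continue
        (coal if inside[node] else spec).append(max(node.edge.length,
                                                    EPS_EDGE))
    r_spec = len(spec) / sum(spec) if spec else None
    r_coal = len(coal) / sum(coal) if coal else None
    return r_spec, r_coal


def _partition_from_roots(roots) -> dict[str, str]:
    part = {}
    for k, root in enumerate(sorted(roots,
                                    key=lambda n: min(tip_label(lf)
                                                      for lf in n.leaf_iter()))):
        for lf in root.leaf_iter():
            part[tip_label(lf)] = f"ptp{k + 1}"
    return part


def _enumerate_antichains(tree: PhyloTree):
    """All antichains of nodes covering every tip (subtree cuts)."""
    def cuts(node):
        options = [[node]]
        if not node.is_leaf():
            child_cuts = [cuts(c) for c in node.child_nodes()]
            for combo in itertools.product(*child_cuts):
                options.append([n for part in combo for n in part])
        return options

    return [frozenset(c) for c in cuts(tree.root)]


def _better(cand: tuple[float, int], best: tuple[float, int],
            tol: float = 1e-9) -> bool:
    """Higher logL wins; at equal logL, fewer species win."""
    if cand[0] > best[0] + tol:
        return True
    if abs(cand[0] - best[0]) <= tol and cand[1] < best[1]:
        return True
    return False


def _greedy_climb(tree: PhyloTree, roots0) -> tuple[frozenset, tuple]:
    """Hill-climb over delimitations, one node per step.

    Moves: collapse any internal node into a single species (absorbing every
    species root beneath it) or split a species root into its children.
    """
    roots = frozenset(roots0)
    key = (_delimitation_loglik(tree, roots), len(roots))
    while True:
        moves = []
        inside: dict = {}
        for node in tree.dt.preorder_node_iter():
            parent = node.parent_node
            inside[node] = parent is not None and (parent in roots
                                                   or inside[parent])
        for node in tree.internal_nodes():
            if node in roots or inside[node]:
                continue
            absorbed = {r for r in roots if r in set(node.preorder_iter())}
            moves.append(roots - absorbed | {node})
        for node in list(roots):
            if not node.is_leaf():
                moves.append(roots - {node} | set(node.child_nodes()))
        best_move, best_move_key = None, key
        for cand in moves:
            cand_key = (_delimitation_loglik(tree, cand), len(cand))
            if _better(cand_key, best_move_key):
                best_move, best_move_key = cand, cand_key
        if best_move is None:
            break
        roots, key = frozenset(best_move), best_move_key
    return roots, key


def ptp_fit(tree: PhyloTree, mode: str = "greedy") -> PtpFit:
    """Maximum-likelihood Poisson-tree-processes delimitation.

    ``exact`` enumerates every antichain of species roots (trees up to
    12 tips); ``greedy`` takes the better of two deterministic hill climbs —
    from the all-singletons and from the single-species delimitations —
    merging or splitting one node per step.  Ties are broken towards fewer
    species.
    """
    if tree.n_tips < 2:
        raise DataError("PTP requires >= 2 tips")
    if mode == "exact":
        if tree.n_tips > PTP_EXACT_MAX_TIPS:
            raise DataError(
                f"exact mode limited to {PTP_EXACT_MAX_TIPS} tips")
        best_roots, best_key = None, (-np.inf, 0)
        for roots in _enumerate_antichains(tree):
            key = (_delimitation_loglik(tree, roots), len(roots))
            if best_roots is None or _better(key, best_key):
                best_roots, best_key = roots, key
    elif mode == "greedy":
        r1, k1 = _greedy_climb(tree, tree.leaves())
        r2, k2 = _greedy_climb(tree, [tree.root])
        if _better(k2, k1):
            best_roots, best_key = r2, k2
        else:
            best_roots, best_key = r1, k1
    else:
        raise ValueError(f"unknown PTP mode {mode!r}")

    r_spec, r_coal = _rates(tree, best_roots)
    return PtpFit(species_roots=sorted(best_roots,
                                       key=lambda n: min(tip_label(lf)
                                                         for lf in n.leaf_iter())),
                  rate_spec=r_spec, rate_coal=r_coal, logL=best_key[0],
                  n_species=len(best_roots),
                  partition=_partition_from_roots(best_roots))
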