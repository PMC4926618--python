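"""Pre-tree sequence conditioning for barcode surveys.

This is the front half of the tree-based identification pipeline: pairwise
evolutionary distances (p, Jukes-Cantor, Kimura 2-parameter), strand
re-orientation against a reference panel, end-trimming to a marker exemplar,
exact-duplicate dereplication, single-linkage threshold clustering of queries,
similarity-based recruitment of taxonomically tagged references into each
query group, and progressive multiple sequence alignment.

Reference recruitment realises "local plus global similarity search" as a
shared k-mer screen (local) followed by a global-alignment p-distance
threshold, so the whole procedure runs against a local reference library with
no network dependency.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .align import (DEFAULT_SCORING, Scoring, align_pair,
                    align_pair_conservative, kmer_distance, kmer_set,
                    merge_alignments, shared_kmer_fraction)
from .errors import DataError
from .records import DistanceMatrix, ReferenceLibrary, SequenceRecord

logger = logging.getLogger(__name__)

SATURATED = np.inf
#: distance recorded for pairs rejected by the k-mer screen (never clusters
#: at any plausible divergence threshold)
SCREEN_FAIL_DISTANCE = 1.0

_VALID = frozenset(b"ACGT")
_PURINES = frozenset(b"AG")


@dataclass(frozen=True)
class QueryGroup:
    """A similarity group of query sequences plus its recruited references."""

    group_id: str
    members: tuple[str, ...]
    refs: tuple[str, ...] = ()
    flagged: str | None = None  # e.g. "unidentifiable"


# --------------------------------------------------------------- distances
def _site_comparison(a: str, b: str) -> tuple[int, int, int]:
    """(compared sites, mismatches, transitions) over definite, ungapped sites."""
    if len(a) != len(b):
        raise DataError("aligned sequences must have equal length")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    valid_a = np.isin(xa, np.frombuffer(b"ACGT", dtype=np.uint8))
    valid_b = np.isin(xb, np.frombuffer(b"ACGT", dtype=np.uint8))
    use = valid_a & valid_b
    n = int(use.sum())
    diff = use & (xa != xb)
    mismatches = int(diff.sum())
    pur = np.frombuffer(b"AG", dtype=np.uint8)
    is_pur_a = np.isin(xa, pur)
    is_pur_b = np.isin(xb, pur)
    transitions = int((diff & (is_pur_a == is_pur_b)).sum())
    return n, mismatches, transitions


def _distance_from_counts(n: int, mismatches: int, transitions: int,
                          model: str) -> float:
    if n == 0:
        raise DataError("zero comparable sites between sequences")
    p = mismatches / n
    if model == "p":
        return p
    if model == "jc":
        if p >= 0.75:
            return SATURATED
        return -0.75 * np.log1p(-4.0 * p / 3.0)
    if model == "k2p":
        P = transitions / n
        Q = (mismatches - transitions) / n
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if w1 <= 0.0 or w2 <= 0.0:
            return SATURATED
        return -0.5 * np.log(w1) - 0.25 * np.log(w2)
    raise ValueError(f"unknown distance model {model!r}")


def pairwise_distance(a: SequenceRecord | str, b: SequenceRecord | str,
                      model: str = "p",
                      gap_policy: str = "pairwise-deletion",
                      aligned: bool | None = None,
                      scoring: Scoring = DEFAULT_SCORING) -> float:
    """Evolutionary distance between two sequences.

    Unaligned inputs (unequal lengths, unless ``aligned`` is forced) are
    globally aligned first.  Sites where either sequence carries a gap, N or
    an ambiguity code are excluded from the comparison.  Jukes-Cantor and
    Kimura distances return the saturation sentinel ``numpy.inf`` when the
    correction is undefined.
    """
    if gap_policy not in ("pairwise-deletion", "complete-deletion"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    sa = a.bases if isinstance(a, SequenceRecord) else a
    sb = b.bases if isinstance(b, SequenceRecord) else b
    if aligned is None:
        aligned = len(sa) == len(sb)
    if not aligned:
        sa, sb, _ = align_pair(sa.replace("-", ""), sb.replace("-", ""),
                               scoring)
    return _distance_from_counts(*_site_comparison(sa, sb), model)


def distance_matrix(seqs: list[SequenceRecord], model: str = "p",
                    gap_policy: str = "pairwise-deletion",
                    screen_k: int | None = None,
                    screen_min_frac: float = 0.2,
                    scoring: Scoring = DEFAULT_SCORING) -> DistanceMatrix:
    """All-pairs distance matrix.

    With ``gap_policy="complete-deletion"`` on an aligned collection, columns
    containing a gap in any sequence are removed before any comparison.  With
    ``screen_k`` set, pairs sharing fewer than ``screen_min_frac`` distinct
    k-mers skip alignment and receive :data:`SCREEN_FAIL_DISTANCE`; this only
    makes sense when the downstream consumer is threshold clustering.
    """
    ids = tuple(r.id for r in seqs)
    rows = [r.bases for r in seqs]
    lengths = {len(r) for r in rows}
    aligned = len(lengths) == 1
    if aligned and gap_policy == "complete-deletion":
        arr = np.array([list(r) for r in rows])
        keep = ~(arr == "-").any(axis=0)
        rows = ["".join(row) for row in arr[:, keep]]
    n = len(seqs)
    if aligned and screen_k is None:
        d = _aligned_pdist(rows, model)
        return DistanceMatrix(ids=ids, values=d, model=model,
                              gap_policy=gap_policy)
    d = np.zeros((n, n))
    ksets = [kmer_set(r.replace("-", ""), screen_k) for r in rows] \
        if screen_k else None
    for i in range(n):
        for j in range(i + 1, n):
            if ksets is not None and \
                    shared_kmer_fraction(ksets[i], ksets[j]) < screen_min_frac:
                d[i, j] = d[j, i] = SCREEN_FAIL_DISTANCE
                continue
            d[i, j] = d[j, i] = pairwise_distance(
                rows[i], rows[j], model=model, gap_policy=gap_policy,
                aligned=aligned or None, scoring=scoring)
    return DistanceMatrix(ids=ids, values=d, model=model,
                          gap_policy=gap_policy)


def _aligned_pdist(rows: list[str], model: str) -> np.ndarray:
    """Vectorised all-pairs distances for an aligned collection."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
    arr = arr.reshape(len(rows), -1)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    purine = np.isin(arr, np.frombuffer(b"AG", dtype=np.uint8))
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        use = valid[i] & valid[i + 1:]
        diff = use & (arr[i] != arr[i + 1:])
        comp = use.sum(axis=1)
        mism = diff.sum(axis=1)
        trans = (diff & (purine[i] == purine[i + 1:])).sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            d[i, j] = d[j, i] = _distance_from_counts(
                int(comp[k]), int(mism[k]), int(trans[k]), model)
    return d


# ------------------------------------------------------------- orientation
def orient_sequences(queries: list[SequenceRecord],
                     refs: list[SequenceRecord],
                     tol: float = 1e-9,
                     max_candidates: int = 5,
                     scoring: Scoring = DEFAULT_SCORING
                     ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Put every query on the reference strand.

    Each query is kept or reverse-complemented, whichever strand has the
    smaller best p-distance (after pairwise alignment) to any reference.
    Alignment is only attempted against the ``max_candidates`` references
    sharing the most k-mers with either strand, and is skipped entirely when
    a positional comparison of equal-length sequences already separates the
    strands by more than ``fast_margin`` (the decision is then the same, a
    homologous strand always being far closer than a reversed one).  Strand
    scores equal within ``tol`` flag the query as ambiguous and leave it
    unchanged.
    """
    if not refs:
        raise DataError("orientation requires a non-empty reference panel")
    fast_margin = 0.10
    ref_ksets = [kmer_set(r.bases) for r in refs]
    oriented: list[SequenceRecord] = []
    report_rows = []
    for q in queries:
        rc = q.reverse_complement()
        kf, kr = kmer_set(q.bases), kmer_set(rc.bases)
        affinity = [max(shared_kmer_fraction(kf, ks),
                        shared_kmer_fraction(kr, ks)) for ks in ref_ksets]
        order = np.argsort(affinity)[::-1][:max_candidates]
        d_fwd = d_rev = None
        same_len = [i for i in order if len(refs[i]) == len(q)]
        if same_len:
            quick_f = min(pairwise_distance(q, refs[i], aligned=True)
                          for i in same_len)
            quick_r = min(pairwise_distance(rc, refs[i], aligned=True)
                          for i in same_len)
            if abs(quick_f - quick_r) > fast_margin:
                d_fwd, d_rev = quick_f, quick_r
        if d_fwd is None:
            d_fwd = min(pairwise_distance(q, refs[i], aligned=False,
                                          scoring=scoring) for i in order)
            d_rev = min(pairwise_distance(rc, refs[i], aligned=False,
                                          scoring=scoring) for i in order)
        ambiguous = abs(d_fwd - d_rev) <= tol
        flipped = (not ambiguous) and d_rev < d_fwd
        oriented.append(rc if flipped else q)
        report_rows.append({"query": q.id, "flipped": flipped,
                            "d_forward": d_fwd, "d_reverse": d_rev,
                            "ambiguous": ambiguous})
        if flipped:
            logger.info("orient: flipped %s (fwd %.4f, rev %.4f)",
                        q.id, d_fwd, d_rev)
        if ambiguous:
            logger.warning("orient: %s is strand-ambiguous, left unchanged",
                           q.id)
    return oriented, pd.DataFrame(report_rows)


# ---------------------------------------------------------------- trimming
def trim_to_marker(queries: list[SequenceRecord], anchor: SequenceRecord,
                   l_min: int = 100,
                   scoring: Scoring = DEFAULT_SCORING
                   ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Trim query ends projecting outside a full-length marker exemplar.

    Each query is pairwise-aligned to the anchor; query residues in alignment
    columns outside the anchor's span are removed.  Queries shorter than
    ``l_min`` after trimming are dropped with a warning.
    """
    trimmed: list[SequenceRecord] = []
    report_rows = []
    for q in queries:
        aq, aa, _ = align_pair_conservative(q.bases.replace("-", ""),
                                            anchor.bases, scoring)
        anchor_cols = [i for i, ch in enumerate(aa) if ch != "-"]
        lo, hi = anchor_cols[0], anchor_cols[-1]
        kept = aq[lo:hi + 1].replace("-", "")
        dropped = len(q.degapped()) - len(kept)
        if len(kept) < l_min:
            logger.warning("trim: dropping %s (%d bp < %d after trim)",
                           q.id, len(kept), l_min)
            report_rows.append({"query": q.id, "trimmed_bases": dropped,
                                "final_length": len(kept), "kept": False})
            continue
        trimmed.append(q.replace_bases(kept))
        report_rows.append({"query": q.id, "trimmed_bases": dropped,
                            "final_length": len(kept), "kept": True})
    return trimmed, pd.DataFrame(report_rows)


# ------------------------------------------------------------ dereplication
def dereplicate(seqs: list[SequenceRecord]
                ) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Collapse exact-duplicate sequences (identical haplotypes).

    The representative of each duplicate set is the lexicographically
    smallest id.  Returns representatives (input order of first occurrence,
    re-sorted so reps replace members in place) and a total mapping
    ``id -> representative id``.
    """
    by_seq: dict[str, list[SequenceRecord]] = {}
    for rec in seqs:
        by_seq.setdefault(rec.bases, []).append(rec)
    mapping: dict[str, str] = {}
    reps: list[SequenceRecord] = []
    for group in by_seq.values():
        rep = min(group, key=lambda r: r.id)
        reps.append(rep)
        for rec in group:
            mapping[rec.id] = rep.id
    reps.sort(key=lambda r: r.id)
    return reps, mapping


# ---------------------------------------------------------------- clustering
def cluster_by_threshold(dm: DistanceMatrix, d_max: float) -> list[QueryGroup]:
    """Single-linkage connected components with edges d(i,j) <= d_max.

    Groups are numbered deterministically in order of their smallest member
    id.  Saturated (non-finite) distances never form edges.
    """
    if d_max < 0:
        raise ValueError("d_max must be nonnegative")
    n = dm.n
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            dij = dm.values[i, j]
            if np.isfinite(dij) and dij <= d_max:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(dm.ids[i])
    ordered = sorted(comps.values(), key=lambda mem: min(mem))
    width = max(3, len(str(len(ordered))))
    return [
        QueryGroup(group_id=f"g{k + 1:0{width}d}",
                   members=tuple(sorted(members)))
        for k, members in enumerate(ordered)
    ]


# ---------------------------------------------------------------- recruitment
def recruit_references(group: QueryGroup,
                       queries: list[SequenceRecord],
                       lib: ReferenceLibrary,
                       d_max: float = 0.10,
                       k: int = 8,
                       kappa_min: float = 0.2,
                       scoring: Scoring = DEFAULT_SCORING
                       ) -> tuple[QueryGroup, pd.DataFrame]:
    """Recruit library references similar to a query group.

    A reference joins the group iff it shares at least ``kappa_min`` of its
    distinct k-mers with some member (fast local screen) AND its global
    p-distance to at least one member is <= ``d_max``.  Groups recruiting no
    reference are flagged "unidentifiable".
    """
    by_id = {q.id: q for q in queries}
    members = [by_id[m] for m in group.members]
    member_ksets = [kmer_set(m.bases, k) for m in members]
    recruited = []
    log_rows = []
    for ref in lib.records:
        rk = kmer_set(ref.bases, k)
        frac = max(shared_kmer_fraction(rk, mk) for mk in member_ksets)
        passed_screen = frac >= kappa_min
        dist = np.nan
        passed_dist = False
        if passed_screen:
            dist = min(pairwise_distance(ref, m, aligned=False,
                                         scoring=scoring) for m in members)
            passed_dist = dist <= d_max
        if passed_screen and passed_dist:
            recruited.append(ref.id)
        log_rows.append({"group": group.group_id, "reference": ref.id,
                         "kmer_fraction": frac, "screen_pass": passed_screen,
                         "p_distance": dist, "distance_pass": passed_dist})
    flag = None
    if not recruited:
        flag = "unidentifiable"
        logger.warning("group %s recruited no references; flagged "
                       "unidentifiable", group.group_id)
    new_group = replace(group, refs=tuple(sorted(recruited)), flagged=flag)
    return new_group, pd.DataFrame(log_rows)


# ----------------------------------------------------------------- alignment
def anchor_align(seqs: list[SequenceRecord], anchor: SequenceRecord,
                 scoring: Scoring = DEFAULT_SCORING
                 ) -> list[SequenceRecord]:
    """Reference-guided multiple alignment onto a marker exemplar.

    Each sequence is pairwise-aligned to the anchor and projected into the
    anchor's coordinate system; insertions relative to the anchor open shared
    padding columns (one block per anchor position, wide enough for the
    longest insertion there).  Unlike de-novo progressive alignment, the
    column homology is pinned to one trusted coordinate system, so deeply
    divergent collections cannot drift apart; removing gap columns recovers
    every input exactly.
    """
    ref = anchor.bases.replace("-", "")
    L = len(ref)
    projections = []  # per seq: (residue per anchor pos, insertions dict)
    ins_width = np.zeros(L + 1, dtype=int)  # insertions BEFORE position j
    for rec in seqs:
        qa, aa, _ = align_pair_conservative(rec.bases.replace("-", ""), ref,
                                            scoring)
        at_pos: list[str] = ["-"] * L
        inserts: dict[int, str] = {}
        j = 0  # next anchor position
        pending = []
        for qc, ac in zip(qa, aa):
            if ac == "-":
                if qc != "-":
                    pending.append(qc)
                continue
            if pending:
                inserts[j] = "".join(pending)
                pending = []
            if qc != "-":
                at_pos[j] = qc
            j += 1
        if pending:
            inserts[L] = "".join(pending)
        for pos, block in inserts.items():
            ins_width[pos] = max(ins_width[pos], len(block))
        projections.append((at_pos, inserts))
    out = []
    for rec, (at_pos, inserts) in zip(seqs, projections):
        parts = []
        for j in range(L + 1):
            if ins_width[j]:
                block = inserts.get(j, "")
                parts.append(block.ljust(ins_width[j], "-"))
            if j < L:
                parts.append(at_pos[j])
        out.append(rec.replace_bases("".join(parts)))
    return out


def progressive_align(seqs: list[SequenceRecord],
                      scoring: Scoring = DEFAULT_SCORING,
                      guide_k: int = 8) -> list[SequenceRecord]:
    """Progressive multiple sequence alignment.

    Pairwise steps use the affine-gap global aligner; the guide tree is UPGMA
    on k-mer distances; profiles are merged progressively.  Removing the gap
    columns of any output row recovers the corresponding input exactly.
    """
    if len(seqs) == 0:
        return []
    if len(seqs) == 1:
        logger.warning("progressive_align: single sequence, returned unchanged")
        return list(seqs)
    bases = [s.bases.replace("-", "") for s in seqs]
    if len(seqs) == 2:
        a, b, _ = align_pair(bases[0], bases[1], scoring)
        merged_rows = [a, b]
        order = [0, 1]
    else:
        dvec = [kmer_distance(bases[i], bases[j], guide_k)
                for i in range(len(seqs)) for j in range(i + 1, len(seqs))]
        z = linkage(np.array(dvec), method="average")
        clusters: dict[int, tuple[list[int], list[str]]] = {
            i: ([i], [bases[i]]) for i in range(len(seqs))
        }
        nxt = len(seqs)
        for left, right, _, _ in z:
            ia, rows_a = clusters.pop(int(left))
            ib, rows_b = clusters.pop(int(right))
            new_a, new_b = merge_alignments(rows_a, rows_b, scoring)
            clusters[nxt] = (ia + ib, new_a + new_b)
            nxt += 1
        order, merged_rows = clusters.popitem()[1]
    out: list[SequenceRecord | None] = [None] * len(seqs)
    for idx, row in zip(order, merged_rows):
        out[idx] = seqs[idx].replace_bases(row)
    return [r for r in out if r is not None]
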