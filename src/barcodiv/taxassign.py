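"""Tree-based taxonomic assignment of query barcodes.

Given a polarised, support-annotated tree containing query tips and
taxonomically tagged reference tips, each query receives a taxonomy parsed
from the reference lineages of its clade context, under two criteria:

* STRICT — walk the query's ancestors tip-to-root and take the least
  inclusive clade that (a) has support at or above a threshold, (b) contains
  at least two reference tips, and (c) brackets the query (references on at
  least two child subtrees, so the query is nested among references rather
  than merely sister to them); the assignment is the rank-by-rank unanimous
  prefix of the clade's reference lineages.  Phylogenetic bracketing protects
  against false positives when the query's own taxon is absent from the
  reference library, at the cost of resolution.

* LIBERAL — the majority lineage (strictly more than half, rank by rank) of
  the references in the nearest reference-bearing ancestor, regardless of
  support; a single sister reference contributes its full lineage.

The strict assignment is always a prefix of the liberal one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import DataError
from .phylo import PhyloTree, tip_label
from .records import Lineage

logger = logging.getLogger(__name__)

DEFAULT_SUPPORT_MIN = 0.70


@dataclass(frozen=True)
class Assignment:
    """Per-query taxonomic assignment under both criteria."""

    query: str
    strict: Lineage
    liberal: Lineage
    clade_support: float
    n_refs: int
    clade_size: int
    flag: str | None = None

    def __post_init__(self):
        if not self.strict.is_prefix_of(self.liberal):
            raise DataError(
                f"{self.query}: strict assignment more specific than liberal")


def common_prefix(lineages: list[Lineage]) -> Lineage:
    """Longest rank-by-rank unanimous prefix of the given lineages."""
    if not lineages:
        raise DataError("common_prefix of an empty collection")
    out = []
    for depth in range(min(len(l) for l in lineages)):
        ranks = {l.ranks[depth] for l in lineages}
        if len(ranks) != 1:
            break
        out.append(next(iter(ranks)))
    return Lineage(tuple(out))


def majority_lineage(lineages: list[Lineage], frac: float = 0.5) -> Lineage:
    """Descend rank by rank keeping the taxon held by strictly more than
    ``frac`` of the lineages; lineages lacking a rank abstain.  ``frac`` = 1
    degenerates to unanimity (equivalent to :func:`common_prefix` restricted
    to equal-depth input)."""
    if not lineages:
        raise DataError("majority_lineage of an empty collection")
    if not 0.5 <= frac <= 1.0:
        raise ValueError("frac must be in [0.5, 1]")
    out = []
    pool = list(lineages)
    depth = 0
    while True:
        votes: dict[tuple[str, str], int] = {}
        voters = 0
        for l in pool:
            if len(l) > depth:
                votes[l.ranks[depth]] = votes.get(l.ranks[depth], 0) + 1
                voters += 1
        if not voters:
            break
        taxon, count = max(votes.items(), key=lambda kv: kv[1])
        if frac >= 1.0:
            if count < voters or len(votes) != 1:
                break
        elif count <= frac * voters:
            break
        out.append(taxon)
        pool = [l for l in pool if len(l) > depth and l.ranks[depth] == taxon]
        depth += 1
    return Lineage(tuple(out))


def _ref_tips_below(node, is_ref) -> list[str]:
    return [tip_label(lf) for lf in node.leaf_iter() if is_ref(tip_label(lf))]


def assign_query(tree: PhyloTree, lineages: dict[str, Lineage], query: str,
                 s_min: float = DEFAULT_SUPPORT_MIN) -> Assignment:
    """Assign one query tip from its clade context (see module docstring)."""
    if not 0.0 <= s_min <= 1.0 + 1e-12:
        # a bar above 1 is allowed and simply disables STRICT
        pass
    is_ref = lambda label: label in lineages  # noqa: E731
    tip = tree.find_tip(query)
    if is_ref(query):
        raise DataError(f"query {query!r} is itself a reference")

    strict = Lineage()
    clade_support = 0.0
    n_refs = 0
    clade_size = 0
    liberal = Lineage()
    liberal_found = False

    node = tip.parent_node
    while node is not None:
        refs = _ref_tips_below(node, is_ref)
        if refs and not liberal_found:
            liberal_found = True
            liberal = majority_lineage([lineages[r] for r in refs], 0.5)
        if refs and not strict:
            support = getattr(node, "support", None)
            support = 1.0 if node.parent_node is None and support is None \
                else (support if support is not None else 0.0)
            children_with_refs = sum(
                1 for c in node.child_nodes() if _ref_tips_below(c, is_ref))
            if (support >= s_min and len(refs) >= 2
                    and children_with_refs >= 2):
                strict = common_prefix([lineages[r] for r in refs])
                clade_support = support
                n_refs = len(refs)
                clade_size = sum(1 for _ in node.leaf_iter())
                break
        node = node.parent_node

    flag = None
    if not liberal_found:
        flag = "no reference context"
        logger.warning("query %s has no reference in its tree", query)
    if strict and not strict.is_prefix_of(liberal):
        # unanimity over a superset can only be shorter than the majority
        # lineage of the subset; guard against pathological rank tables
        strict = common_prefix([strict, liberal])
    return Assignment(query=query, strict=strict, liberal=liberal,
                      clade_support=clade_support, n_refs=n_refs,
                      clade_size=clade_size, flag=flag)


def assign_all(group_trees: dict[str, PhyloTree],
               group_queries: dict[str, list[str]],
               lineages: dict[str, Lineage],
               s_min: float = DEFAULT_SUPPORT_MIN
               ) -> tuple[list[Assignment], pd.DataFrame]:
    """Assign every query of every group tree.

    Returns the assignments plus a per-rank resolution summary (how many
    queries resolved at least to each rank, under each criterion).
    """
    assignments: list[Assignment] = []
    for group_id in sorted(group_trees):
        tree = group_trees[group_id]
        tips = set(tree.tip_labels)
        for query in sorted(group_queries[group_id]):
            if query not in tips:
                raise DataError(
                    f"query {query!r} missing from tree of group {group_id}")
            assignments.append(assign_query(tree, lineages, query, s_min))
    rank_names: list[str] = []
    for a in assignments:
        for r in a.liberal.rank_names:
            if r not in rank_names:
                rank_names.append(r)
    rows = []
    for rank in rank_names:
        rows.append({
            "rank": rank,
            "strict_resolved": sum(rank in a.strict.rank_names
                                   for a in assignments),
            "liberal_resolved": sum(rank in a.liberal.rank_names
                                    for a in assignments),
            "n_queries": len(assignments),
        })
    return assignments, pd.DataFrame(rows)


def assignments_table(assignments: list[Assignment]) -> pd.DataFrame:
    return pd.DataFrame([
        {"query": a.query,
         "strict": a.strict.joined(),
         "liberal": a.liberal.joined(),
         "support": a.clade_support,
         "n_refs": a.n_refs,
         "clade_size": a.clade_size,
         "flag": a.flag or ""}
        for a in assignments
    ])
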