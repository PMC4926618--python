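"""Distance-based tree inference, bootstrap supports, rooting, ultrametricity.

Group trees are inferred by neighbor joining (unrooted) or UPGMA (rooted,
ultrametric); node supports come from nonparametric bootstrap over alignment
columns.  Unrooted trees are secondarily polarised by midpoint or outgroup
rooting before taxonomic parsing.  Support-annotated trees computed by
external likelihood software can be imported through the ordinary Newick
reader and used interchangeably.

Neighbor joining is delegated to scikit-bio; UPGMA to scipy's average-linkage
clustering (node age = cluster distance / 2).
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .errors import DataError
from .phylo import PhyloTree, parse_newick, tip_label
from .records import DistanceMatrix, SequenceRecord
from .seqprep import distance_matrix

logger = logging.getLogger(__name__)

#: default ultrametricity tolerance, as a fraction of tree height
ULTRAMETRIC_REL_TOL = 1e-6


def build_tree(dm: DistanceMatrix, method: str = "nj",
               resolution: float = 0.0) -> PhyloTree:
    """Infer a tree from a distance matrix.

    ``nj`` gives an unrooted tree (negative NJ branch-length estimates are
    clamped to zero); ``upgma`` gives a rooted ultrametric tree with node age
    equal to half the cluster distance.  ``resolution`` (upgma only) snaps
    node ages below the stated value to zero: ages smaller than the distance
    resolution of the marker cannot be measured, and leaving them positive
    lets downstream threshold models over-fit quantisation noise.
    """
    saturated = dm.saturated_pairs()
    if saturated:
        raise DataError(
            f"saturated distances for pairs {saturated}; use the p model or "
            f"remove the offending sequences"
        )
    if dm.n < 2:
        raise DataError("tree inference requires >= 2 taxa")
    if method == "nj":
        return _nj_tree(dm)
    if method == "upgma":
        return _upgma_tree(dm, resolution)
    raise ValueError(f"unknown tree method {method!r}")


def _nj_tree(dm: DistanceMatrix) -> PhyloTree:
    if dm.n == 2:
        a, b = dm.ids
        tree = parse_newick(f"({a}:{dm.values[0, 1]:.10g},{b}:0);")
        tree.rooted = False
        return tree
    sk = _SkbioDM(dm.values, ids=list(dm.ids))
    newick = str(_skbio_nj(sk))
    tree = parse_newick(newick)
    tree.rooted = False
    return tree


def _upgma_tree(dm: DistanceMatrix, resolution: float = 0.0) -> PhyloTree:
    ids = list(dm.ids)
    if dm.n == 2:
        h = dm.values[0, 1] / 2.0
        return parse_newick(f"({ids[0]}:{h:.10g},{ids[1]}:{h:.10g});")
    condensed = dm.values[np.triu_indices(dm.n, k=1)]
    z = linkage(condensed, method="average")
    ages = {i: 0.0 for i in range(dm.n)}
    reps = {i: ids[i] for i in range(dm.n)}
    nxt = dm.n
    for left, right, dist, _ in z:
        left, right = int(left), int(right)
        age = dist / 2.0
        if age < resolution:
            age = 0.0
        age = max(age, ages[left], ages[right])  # keep ages monotone
        reps[nxt] = (f"({reps[left]}:{age - ages[left]:.10g},"
                     f"{reps[right]}:{age - ages[right]:.10g})")
        ages[nxt] = age
        nxt += 1
    return parse_newick(reps[nxt - 1] + ";")


def bootstrap_support(aln: list[SequenceRecord], method: str = "nj",
                      B: int = 100, seed: int = 0,
                      model: str = "p") -> PhyloTree:
    """Point-estimate tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``B`` times; each
    internal edge's support is the fraction of replicate trees containing its
    bipartition.  Fully reproducible for a given seed.
    """
    if len(aln) < 4:
        raise DataError("bootstrap supports require >= 4 sequences")
    if B < 1:
        raise ValueError("B must be >= 1")
    lengths = {len(r) for r in aln}
    if len(lengths) != 1:
        raise DataError("bootstrap requires an aligned (equal-length) input")
    length = lengths.pop()
    point = build_tree(distance_matrix(aln, model=model), method=method)
    splits = point.bipartitions()
    counts = {split: 0 for split in splits}
    rng = np.random.default_rng(seed)
    arr = np.array([list(r.bases) for r in aln])
    for _ in range(B):
        cols = rng.integers(0, length, size=length)
        rep = [r.replace_bases("".join(row))
               for r, row in zip(aln, arr[:, cols])]
        rep_tree = build_tree(distance_matrix(rep, model=model),
                              method=method)
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in splits.items():
        node.support = counts[split] / B
    return point


def polarise(tree: PhyloTree, mode: str = "midpoint",
             outgroup_ids: list[str] | None = None) -> PhyloTree:
    """Root an unrooted tree ("secondary polarisation").

    ``midpoint`` roots at the midpoint of the longest tip-to-tip path;
    ``outgroup`` roots on the edge subtending the smallest clade containing
    all outgroup ids (with a warning if that clade also contains ingroup
    tips, i.e. the outgroup is not monophyletic in the unrooted sense).
    Supports are re-attached to the same bipartitions; no tip-to-tip path
    length changes.
    """
    work = tree.copy()
    supports = work.support_map()
    if mode == "midpoint":
        _midpoint_root(work)
    elif mode == "outgroup":
        if not outgroup_ids:
            raise ValueError("outgroup mode requires outgroup_ids")
        missing = set(outgroup_ids) - set(work.tip_labels)
        if missing:
            raise DataError(f"outgroup tips not in tree: {sorted(missing)}")
        _root_at_outgroup(work, set(outgroup_ids))
    else:
        raise ValueError(f"unknown polarise mode {mode!r}")
    work.dt.suppress_unifurcations()
    for node in work.dt.preorder_node_iter():
        if node.edge.length is None or node.edge.length < 0:
            # None on the new root edge; sub-epsilon negatives from the
            # midpoint arithmetic
            node.edge.length = max(node.edge.length or 0.0, 0.0)
        node.support = None  # re-attached below by bipartition identity
    out = PhyloTree(work.dt, rooted=True)
    out.attach_supports(supports)
    return out


def _midpoint_root(tree: PhyloTree) -> None:
    """Root at the midpoint of the longest tip-to-tip path.

    Implemented directly (longest pair with lexicographic tie-break, then a
    walk to the halfway point) because the library rerooting routine
    mishandles midpoints that coincide with internal nodes.
    """
    depths = tree.node_depths()
    leaves = sorted(tree.leaves(), key=tip_label)
    if len(leaves) < 2:
        return
    anc: dict = {}
    for lf in leaves:
        chain = []
        node = lf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[lf] = chain
    best = None  # (-pathlen, label_u, label_v, u, v, lca)
    for i, u in enumerate(leaves):
        up = set(anc[u])
        for v in leaves[i + 1:]:
            lca = next(n for n in anc[v] if n in up)
            plen = depths[u] + depths[v] - 2 * depths[lca]
            key = (-plen, tip_label(u), tip_label(v))
            if best is None or key < best[0]:
                best = (key, u, v, lca)
    (_, u, v, lca) = best
    half = (depths[u] + depths[v] - 2 * depths[lca]) / 2.0
    if half <= 0:
        logger.warning("midpoint undefined (all path lengths zero); keeping "
                       "the existing basal node as root")
        return
    for start in (u, v):
        cum = 0.0
        node = start
        while node is not lca:
            length = node.edge.length
            if cum + length >= half - 1e-15:
                below = half - cum  # root sits this far above `node`
                tree.dt.reroot_at_edge(node.edge, length1=length - below,
                                       length2=below,
                                       update_bipartitions=False)
                return
            cum += length
            node = node.parent_node
        half = (depths[u] + depths[v] - 2 * depths[lca]) - half


def _root_at_outgroup(tree: PhyloTree, outgroup: set[str]) -> None:
    ingroup_tip = next(lf for lf in tree.leaves()
                       if tip_label(lf) not in outgroup)
    # view the tree from an ingroup tip so "smallest clade containing the
    # outgroup" is well defined in the unrooted sense
    edge = ingroup_tip.edge
    half = (edge.length or 0.0) / 2.0
    tree.dt.reroot_at_edge(edge, length1=(edge.length or 0.0) - half,
                           length2=half, update_bipartitions=False)
    below: dict = {}
    best = None
    for node in tree.dt.postorder_node_iter():
        if node.is_leaf():
            below[node] = {tip_label(node)}
        else:
            below[node] = set().union(*[below[c] for c in node.child_nodes()])
        if node.parent_node is not None and outgroup <= below[node]:
            if best is None or len(below[node]) < len(below[best]):
                best = node
    if best is None:
        best = tree.root
    if len(below[best]) > len(outgroup):
        logger.warning(
            "outgroup is not monophyletic; rooting on the smallest edge "
            "containing all %d outgroup tips (%d tips total)",
            len(outgroup), len(below[best]))
    half = best.edge.length / 2.0 if best.edge.length else 0.0
    tree.dt.reroot_at_edge(best.edge, length1=best.edge.length - half,
                           length2=half, update_bipartitions=False)


def check_ultrametric(tree: PhyloTree, tol: float | None = None
                      ) -> tuple[bool, float]:
    """Test equal root-to-tip path lengths.

    ``tol`` defaults to :data:`ULTRAMETRIC_REL_TOL` times the tree height.
    Returns (pass, max absolute deviation from the mean root-to-tip depth).
    """
    dev = tree.max_ultrametric_deviation()
    if tol is None:
        tol = ULTRAMETRIC_REL_TOL * max(tree.height(), 1e-300)
    return dev <= tol, dev


def upgma_from_alignment(aln: list[SequenceRecord], model: str = "p",
                         snap_resolution: float | None = None) -> PhyloTree:
    """Ultrametric tree directly from an alignment (the standard input to
    threshold delimitation).

    Node ages below the marker's distance resolution — half of one
    substitution per site, ``1/(2L)`` for an alignment of length L — default
    to being snapped to zero; they are not measurable and would otherwise
    seed spurious shallow waiting intervals.
    """
    if snap_resolution is None:
        L = max(len(r.bases) for r in aln)
        snap_resolution = 0.5 / L + 1e-12
    return build_tree(distance_matrix(aln, model=model), method="upgma",
                      resolution=snap_resolution)
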