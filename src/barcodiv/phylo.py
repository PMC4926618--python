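"""Phylogenetic tree container and Newick round-tripping.

The :class:`PhyloTree` wraps a :mod:`dendropy` tree and adds the survey-toolkit
conventions: per-node support values normalised to the unit interval (Newick
files in the wild carry supports either as fractions or as percentages;
any value above 1 triggers a whole-tree division by 100), nonnegative branch
lengths defaulting to zero, node-age accessors for ultrametric trees, and
canonical bipartition encoding used to re-attach supports after re-rooting.
"""
from __future__ import annotations

import math
from typing import Iterator

import dendropy
import numpy as np

from .errors import DataError, ParseError


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except (TypeError, ValueError):
        return False


class PhyloTree:
    """Rooted or unrooted tree with branch lengths and node supports."""

    def __init__(self, dtree: dendropy.Tree, rooted: bool = True):
        self.dt = dtree
        self.rooted = rooted
        for node in self.dt.preorder_node_iter():
            if node.edge.length is None:
                node.edge.length = 0.0
            if node.edge.length < 0:
                raise DataError(
                    f"negative branch length {node.edge.length} in tree"
                )
            if not hasattr(node, "support"):
                node.support = None
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise DataError("tip labels are not unique")

    # ------------------------------------------------------------------ basics
    @property
    def root(self) -> dendropy.Node:
        return self.dt.seed_node

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label if lf.taxon else lf.label
                for lf in self.dt.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dt.leaf_node_iter())

    def leaves(self) -> Iterator[dendropy.Node]:
        return self.dt.leaf_node_iter()

    def nodes(self) -> Iterator[dendropy.Node]:
        return self.dt.preorder_node_iter()

    def internal_nodes(self, exclude_root: bool = False) -> list[dendropy.Node]:
        out = []
        for node in self.dt.preorder_internal_node_iter():
            if exclude_root and node is self.root:
                continue
            out.append(node)
        return out

    def find_tip(self, label: str) -> dendropy.Node:
        for lf in self.dt.leaf_node_iter():
            if tip_label(lf) == label:
                return lf
        raise DataError(f"tip {label!r} not found in tree")

    def copy(self) -> "PhyloTree":
        clone = dendropy.Tree(self.dt)
        # dendropy's copy constructor does not carry ad-hoc attributes
        for src, dst in zip(self.dt.preorder_node_iter(),
                            clone.preorder_node_iter()):
            dst.support = getattr(src, "support", None)
        return PhyloTree(clone, rooted=self.rooted)

    # ------------------------------------------------------------------ depths
    def node_depths(self) -> dict[dendropy.Node, float]:
        """Root-to-node path lengths."""
        depths: dict[dendropy.Node, float] = {}
        for node in self.dt.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {tip_label(lf): depths[lf] for lf in self.dt.leaf_node_iter()}

    def height(self) -> float:
        """Mean root-to-tip path length."""
        return float(np.mean(list(self.tip_depths().values())))

    def max_ultrametric_deviation(self) -> float:
        d = np.array(list(self.tip_depths().values()))
        return float(np.max(np.abs(d - d.mean()))) if len(d) else 0.0

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Ages (time before present) on an ultrametric tree.

        Age = mean root-to-tip depth minus the node's own depth, clipped at 0
        so that tips of a numerically ultrametric tree sit exactly at the
        present.
        """
        depths = self.node_depths()
        h = self.height()
        return {n: max(h - d, 0.0) for n, d in depths.items()}

    # ------------------------------------------------------------- bipartitions
    def bipartitions(self) -> dict[frozenset[str], dendropy.Node]:
        """Canonical unrooted split of every internal edge.

        Each split is represented by the side NOT containing the
        lexicographically smallest tip label, making the encoding invariant to
        re-rooting.  Pendant edges and the root are excluded.
        """
        all_tips = frozenset(self.tip_labels)
        anchor = min(all_tips)
        out: dict[frozenset[str], dendropy.Node] = {}
        below: dict[dendropy.Node, frozenset[str]] = {}
        for node in self.dt.postorder_node_iter():
            if node.is_leaf():
                below[node] = frozenset([tip_label(node)])
            else:
                below[node] = frozenset().union(
                    *[below[c] for c in node.child_nodes()]
                )
            if node.parent_node is None or node.is_leaf():
                continue
            side = below[node]
            if len(side) <= 1 or len(all_tips - side) <= 1:
                continue  # trivial split
            canon = side if anchor not in side else all_tips - side
            out[canon] = node
        return out

    def support_map(self) -> dict[frozenset[str], float]:
        return {
            split: node.support
            for split, node in self.bipartitions().items()
            if getattr(node, "support", None) is not None
        }

    def attach_supports(self, supports: dict[frozenset[str], float]) -> None:
        """Write supports onto the internal nodes matching the given splits."""
        for split, node in self.bipartitions().items():
            if split in supports:
                node.support = supports[split]

    # ------------------------------------------------------------------ newick
    def to_newick(self, support_scale: str = "unit") -> str:
        """Serialise to a one-line Newick statement.

        ``support_scale`` is ``"unit"`` (default, supports written on [0,1])
        or ``"percent"`` (multiplied by 100, the other common dialect).
        """
        if support_scale not in ("unit", "percent"):
            raise ValueError(f"unknown support scale {support_scale!r}")
        mult = 100.0 if support_scale == "percent" else 1.0

        def fmt(node: dendropy.Node) -> str:
            if node.is_leaf():
                core = tip_label(node)
            else:
                inner = ",".join(fmt(c) for c in node.child_nodes())
                label = ""
                if getattr(node, "support", None) is not None:
                    label = f"{node.support * mult:g}"
                elif node.label:
                    label = node.label
                core = f"({inner}){label}"
            if node.parent_node is not None:
                core += f":{node.edge.length:.10g}"
            return core

        return fmt(self.root) + ";"

    def write_newick(self, path, support_scale: str = "unit") -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(support_scale=support_scale) + "\n")

    def __repr__(self) -> str:
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {self.n_tips} tips>"


def tip_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "")


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    Internal-node labels that parse as numbers are interpreted as supports;
    if any support exceeds 1 the whole tree is assumed to be on the 0-100
    scale and every support is divided by 100.  Missing branch lengths
    default to 0.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise ParseError(
            f"Newick statement must end with ';' (offset {len(stripped)})"
        )
    depth = 0
    for offset, ch in enumerate(stripped):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced ')' at offset {offset}")
        elif ch == "," and (depth == 0 or stripped[offset - 1] in "(,"):
            raise ParseError(f"dangling comma at offset {offset}")
    if depth != 0:
        raise ParseError(
            f"unbalanced parentheses ({depth} unclosed) at offset {len(stripped)}"
        )
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"Newick parse error: {exc}") from exc

    numeric_labels: list[tuple[dendropy.Node, float]] = []
    for node in dtree.preorder_internal_node_iter():
        node.support = None
        if node.label is not None and _is_number(node.label):
            numeric_labels.append((node, float(node.label)))
            node.label = None
    rescale = any(v > 1.0 for _, v in numeric_labels)
    for node, value in numeric_labels:
        support = value / 100.0 if rescale else value
        if not 0.0 <= support <= 1.0:
            raise DataError(f"support {value} out of range after rescaling")
        node.support = support
    rooted = dtree.seed_node.num_child_nodes() <= 2
    return PhyloTree(dtree, rooted=rooted)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def trees_isomorphic(a: PhyloTree, b: PhyloTree, tol: float = 1e-9) -> bool:
    """Topology + branch-length equality as unrooted weighted trees."""
    if set(a.tip_labels) != set(b.tip_labels):
        return False
    da, db = _path_lengths(a), _path_lengths(b)
    return all(math.isclose(da[k], db[k], abs_tol=tol) for k in da)


def _path_lengths(tree: PhyloTree) -> dict[tuple[str, str], float]:
    depths = tree.node_depths()
    leaves = list(tree.leaves())
    out = {}
    pdm = {}
    for lf in leaves:
        path = []
        node = lf
        while node is not None:
            path.append(node)
            node = node.parent_node
        pdm[lf] = {n: i for i, n in enumerate(path)}
    for i, u in enumerate(leaves):
        for v in leaves[i + 1:]:
            node = v
            while node not in pdm[u]:
                node = node.parent_node
            d = depths[u] + depths[v] - 2 * depths[node]
            key = tuple(sorted((tip_label(u), tip_label(v))))
            out[key] = d
    return out
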