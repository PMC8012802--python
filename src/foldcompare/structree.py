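"""Structure-based trees: distance matrices from pairwise alignments,
neighbor-joining and UPGMA construction, Robinson–Foulds comparison, and the
region-deletion robustness experiment.

Trees are built from all-against-all alignment distances (1 − TM-score by
default, which is length-normalized and therefore robust to the large
length spread typical of a fold family).  Construction is deterministic:
agglomeration ties are broken by cluster label order and negative
neighbor-joining branch lengths are clamped to zero with a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import TreeError
from .structio import CaTrace
from .superpose import AlignParams, align_pair

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "structure_distance_matrix",
    "build_tree",
    "robinson_foulds",
    "deletion_experiment",
    "DeletionResult",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise TreeError("matrix shape does not match labels")
        if np.any(np.isnan(self.values)):
            raise TreeError("NaN in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise TreeError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise TreeError("non-zero diagonal")
        if np.any(self.values < 0):
            raise TreeError("negative distances")

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "\t" + "\t".join(f"{v:.6g}" for v in row))
        return "\n".join(lines) + "\n"

    def to_phylip(self) -> str:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(f"{lab:<10s} " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


class TreeNode:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list["TreeNode"] = []
        self.parent: "TreeNode | None" = None

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Rooted representation of a (conceptually unrooted) tree.

    Leaf labels are unique; Newick round trips preserve topology and branch
    lengths to 1e-6.
    """

    root: TreeNode
    rooted: bool = False

    def postorder(self):
        def _walk(node):
            for c in node.children:
                yield from _walk(c)
            yield node

        yield from _walk(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def to_newick(self) -> str:
        def _fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.9g}"
            inner = ",".join(_fmt(c) for c in node.children)
            return f"({inner}):{node.length:.9g}"

        inner = ",".join(_fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

        def _conv(dnode) -> TreeNode:
            node = TreeNode(
                label=dnode.taxon.label if dnode.taxon else None,
                length=dnode.edge.length or 0.0,
            )
            for c in dnode.child_nodes():
                node.add(_conv(c))
            return node

        return cls(root=_conv(dt.seed_node))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits in canonical (reference-leaf-free side) form."""
        labels = set(self.leaf_labels())
        if len(labels) != len(self.leaf_labels()):
            raise TreeError("duplicate leaf labels")
        ref = min(labels)
        splits: set[frozenset[str]] = set()

        def _below(node) -> set[str]:
            if node.is_leaf:
                return {node.label}
            out: set[str] = set()
            for c in node.children:
                out |= _below(c)
            return out

        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = _below(node)
            if len(side) < 2 or len(side) > len(labels) - 2:
                continue
            if ref in side:
                side = labels - side
            splits.add(frozenset(side))
        return splits


# ---------------------------------------------------------------------------


def structure_distance_matrix(
    traces: list[CaTrace],
    metric: str = "one_minus_tm",
    params: AlignParams | None = None,
) -> DistanceMatrix:
    """All-against-all alignment distances between Cα traces.

    ``one_minus_tm`` uses TM-scores normalized by the shorter chain so the
    matrix is symmetric; ``rmsd_aligned`` uses the aligned-pair RMSD.
    """
    if metric not in ("one_minus_tm", "rmsd_aligned"):
        raise TreeError(f"unknown metric {metric!r}")
    params = params or AlignParams()
    labels = [t.label for t in traces]
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate trace labels")
    n = len(traces)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            pa = align_pair(traces[i], traces[j], params)
        except Exception as exc:
            raise TreeError(f"pairwise alignment failed for {labels[i]} vs {labels[j]}: {exc}") from exc
        v = 1.0 - pa.tm_score if metric == "one_minus_tm" else pa.rmsd_aligned
        d[i, j] = d[j, i] = max(0.0, v)
    return DistanceMatrix(labels, d)


def _clamp(v: float, context: str) -> float:
    if v < 0:
        if v < -1e-9:
            warnings.warn(f"negative branch length {v:.3g} clamped to 0 ({context})", stacklevel=3)
        return 0.0
    return v


def build_tree(dm: DistanceMatrix, method: str = "nj") -> PhyloTree:
    """Distance-matrix tree: Saitou–Nei neighbor joining or UPGMA.

    Deterministic: agglomeration ties are broken by the lexicographically
    smallest pair of cluster labels (a cluster is labelled by its smallest
    leaf).  NJ output is unrooted (trifurcating root); UPGMA is rooted and
    ultrametric.
    """
    n = len(dm.labels)
    if n < 3:
        raise TreeError(f"tree building needs >= 3 taxa, got {n}")
    if method == "nj":
        return _nj(dm)
    if method == "upgma":
        return _upgma(dm)
    raise TreeError(f"unknown method {method!r}")


def _nj(dm: DistanceMatrix) -> PhyloTree:
    nodes = {i: TreeNode(lab) for i, lab in enumerate(dm.labels)}
    names = {i: lab for i, lab in enumerate(dm.labels)}  # smallest leaf label
    D = {(i, j): dm.values[i, j] for i in nodes for j in nodes if i != j}
    active = sorted(nodes)
    nxt = len(dm.labels)
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[(i, k)] for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * D[(i, j)] - r[i] - r[j]
            key = (q, tuple(sorted((names[i], names[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = D[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        node = TreeNode()
        a, b = sorted((i, j), key=lambda k: names[k])
        for child, ln in ((a, li if a == i else lj), (b, lj if a == i else li)):
            nodes[child].length = _clamp(ln, f"join {names[i]}+{names[j]}")
            node.add(nodes[child])
        nodes[nxt] = node
        names[nxt] = min(names[i], names[j])
        for k in active:
            if k in (i, j):
                continue
            dv = 0.5 * (D[(i, k)] + D[(j, k)] - dij)
            D[(nxt, k)] = D[(k, nxt)] = max(0.0, dv)
        active = sorted(k for k in active if k not in (i, j)) + [nxt]
        nxt += 1
    # closed-form three-point resolution of the final star
    a, b, c = sorted(active, key=lambda k: names[k])
    dab, dac, dbc = D[(a, b)], D[(a, c)], D[(b, c)]
    root = TreeNode()
    for k, ln in (
        (a, (dab + dac - dbc) / 2),
        (b, (dab + dbc - dac) / 2),
        (c, (dac + dbc - dab) / 2),
    ):
        nodes[k].length = _clamp(ln, "terminal star")
        root.add(nodes[k])
    return PhyloTree(root=root, rooted=False)


def _upgma(dm: DistanceMatrix) -> PhyloTree:
    nodes = {i: TreeNode(lab) for i, lab in enumerate(dm.labels)}
    names = {i: lab for i, lab in enumerate(dm.labels)}
    sizes = {i: 1 for i in nodes}
    heights = {i: 0.0 for i in nodes}
    D = {(i, j): dm.values[i, j] for i in nodes for j in nodes if i != j}
    active = sorted(nodes)
    nxt = len(dm.labels)
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(active, 2):
            key = (D[(i, j)], tuple(sorted((names[i], names[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = D[(i, j)] / 2
        node = TreeNode()
        for child in sorted((i, j), key=lambda k: names[k]):
            nodes[child].length = _clamp(h - heights[child], "upgma merge")
            node.add(nodes[child])
        heights[nxt] = h
        sizes[nxt] = sizes[i] + sizes[j]
        nodes[nxt] = node
        names[nxt] = min(names[i], names[j])
        for k in active:
            if k in (i, j):
                continue
            dv = (sizes[i] * D[(i, k)] + sizes[j] * D[(j, k)]) / (sizes[i] + sizes[j])
            D[(nxt, k)] = D[(k, nxt)] = dv
        active = sorted(k for k in active if k not in (i, j)) + [nxt]
        nxt += 1
    return PhyloTree(root=nodes[active[0]], rooted=True)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Bipartitions present in exactly one tree (unrooted convention)."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise TreeError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    return len(t1.bipartitions() ^ t2.bipartitions())


# ---------------------------------------------------------------------------
# region-deletion robustness experiment


@dataclass
class DeletionResult:
    tree_full: PhyloTree
    tree_deleted: PhyloTree
    rf: int
    class_diff: dict[str, tuple[bool, bool]] = field(default_factory=dict)


def class_monophyly(tree: PhyloTree, classes: dict[str, str]) -> dict[str, bool]:
    """Whether each class's members are separated by some bipartition."""
    labels = set(tree.leaf_labels())
    splits = tree.bipartitions()
    out: dict[str, bool] = {}
    for cls in sorted(set(classes.values())):
        members = frozenset(l for l, c in classes.items() if c == cls)
        if len(members) < 2 or len(labels - members) < 2:
            out[cls] = True  # trivially separable
            continue
        out[cls] = members in splits or frozenset(labels - members) in splits
    return out


def deletion_experiment(
    traces: list[CaTrace],
    regions: dict[str, tuple[int, int] | None],
    metric: str = "one_minus_tm",
    method: str = "nj",
    params: AlignParams | None = None,
    classes: dict[str, str] | None = None,
) -> DeletionResult:
    """Rebuild the structure tree after deleting a region from each trace.

    ``regions`` maps trace labels to inclusive author-numbered intervals
    (``None`` or a missing entry deletes nothing).  An interval removing
    more than half of a trace is refused.  Returns both trees, their
    Robinson–Foulds distance, and — when a class map is supplied — which
    classes changed separability status.
    """
    params = params or AlignParams()
    deleted: list[CaTrace] = []
    for t in traces:
        iv = regions.get(t.label)
        if iv is None:
            deleted.append(t)
            continue
        lo, hi = iv
        cut = t.without_range(lo, hi)
        if len(cut) < 0.5 * len(t):
            raise TreeError(
                f"deleting {lo}-{hi} removes more than half of {t.label} "
                f"({len(t)} -> {len(cut)} residues)"
            )
        deleted.append(cut)
    dm_full = structure_distance_matrix(traces, metric, params)
    dm_del = structure_distance_matrix(deleted, metric, params)
    t_full = build_tree(dm_full, method)
    t_del = build_tree(dm_del, method)
    rf = robinson_foulds(t_full, t_del)
    diff: dict[str, tuple[bool, bool]] = {}
    if classes:
        m_full = class_monophyly(t_full, classes)
        m_del = class_monophyly(t_del, classes)
        diff = {
            c: (m_full[c], m_del[c]) for c in m_full if m_full[c] != m_del[c]
        }
    return DeletionResult(t_full, t_del, rf, diff)
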