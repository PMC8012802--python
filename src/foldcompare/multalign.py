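"""Progressive multiple structural alignment.

N Cα traces are merged bottom-up along a UPGMA guide tree computed from
pairwise TM-scores.  At each merge the two profiles are superposed (initial
frame from a pairwise alignment of their consensus coordinates) and aligned
by dynamic programming on the mean inter-profile Cα distance score
1/(1+(d̄_ij/d0)²); after the final merge every member is re-superposed once
onto the consensus of the others.  The result is a column table over all
members in a single consensus frame — the object from which per-position
divergence, conservation calls and superposed bundles are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import _dp
from .errors import AlignmentError, TreeError
from .structio import CaTrace, RigidTransform
from .superpose import AlignParams, align_pair, d0_auto, kabsch_fit, tm_score
from .structree import DistanceMatrix, PhyloTree, build_tree

__all__ = [
    "MultipleAlignment",
    "build_guide_tree",
    "progressive_align",
    "column_coordinates",
    "align_structures",
]


@dataclass
class MultipleAlignment:
    """Column table over N traces superposed in one frame.

    ``columns[c, m]`` is the residue index of member ``m`` in column ``c``
    or −1 for a gap; ``transforms[m]`` maps member coordinates into the
    consensus frame.  For every member, non-gap entries are strictly
    increasing down the columns and each residue appears in exactly one
    column.
    """

    members: list[CaTrace]
    columns: np.ndarray
    transforms: list[RigidTransform]
    params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, int)
        self.validate()

    @property
    def n_columns(self) -> int:
        return self.columns.shape[0]

    @property
    def n_members(self) -> int:
        return self.columns.shape[1]

    def member_count(self, column: int | None = None):
        counts = (self.columns >= 0).sum(axis=1)
        return counts if column is None else int(counts[column])

    def validate(self) -> None:
        ncol, nmem = self.columns.shape
        if nmem != len(self.members) or nmem != len(self.transforms):
            raise AlignmentError("members / columns / transforms size mismatch")
        for m, trace in enumerate(self.members):
            idx = self.columns[:, m]
            idx = idx[idx >= 0]
            if len(idx) != len(trace) or np.any(np.diff(idx) <= 0) or (
                len(idx) and (idx[0] != 0 or idx[-1] != len(trace) - 1)
            ):
                raise AlignmentError(
                    f"column table does not project onto member {trace.label}"
                )
        for tr in self.transforms:
            if not tr.is_proper(1e-6):
                raise AlignmentError("improper member transform")

    def superposed_coords(self, member: int) -> np.ndarray:
        return self.transforms[member].apply(self.members[member].coords)

    def column_letters(self, column: int) -> list[str]:
        out = []
        for m, trace in enumerate(self.members):
            i = self.columns[column, m]
            out.append(trace.sequence[i] if i >= 0 else "-")
        return out

    def gapped_sequence(self, member: int) -> str:
        trace = self.members[member]
        return "".join(
            trace.sequence[i] if i >= 0 else "-" for i in self.columns[:, member]
        )

    def to_fasta(self) -> str:
        out = []
        for m, trace in enumerate(self.members):
            out.append(f">{trace.label}")
            out.append(self.gapped_sequence(m))
        return "\n".join(out) + "\n"

    def to_clustal(self, width: int = 60, conservation: str | None = None) -> str:
        names = [t.label for t in self.members]
        w = max(len(n) for n in names) + 2
        seqs = [self.gapped_sequence(m) for m in range(self.n_members)]
        out = ["CLUSTAL-like structure-based multiple alignment", ""]
        for k in range(0, self.n_columns, width):
            for name, s in zip(names, seqs):
                out.append(f"{name:<{w}}{s[k:k + width]}")
            if conservation is not None:
                out.append(" " * w + conservation[k : k + width])
            out.append("")
        return "\n".join(out)


def column_coordinates(msa: MultipleAlignment, column: int) -> np.ndarray:
    """Superposed Cα positions of the members present in one column."""
    if not 0 <= column < msa.n_columns:
        raise IndexError(f"column {column} out of range (0..{msa.n_columns - 1})")
    pts = []
    for m in range(msa.n_members):
        i = msa.columns[column, m]
        if i >= 0:
            pts.append(msa.transforms[m].apply(msa.members[m].coords[i]))
    return np.asarray(pts).reshape(-1, 3)


# ---------------------------------------------------------------------------
# guide tree


def _pairwise_tm_matrix(traces: list[CaTrace], params: AlignParams) -> np.ndarray:
    n = len(traces)
    tm = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                pa = align_pair(traces[i], traces[j], params)
            except Exception as exc:
                raise AlignmentError(
                    f"guide-tree alignment failed for {traces[i].label} vs "
                    f"{traces[j].label}: {exc}"
                ) from exc
            tm[i, j] = tm[j, i] = pa.tm_score
    return tm


def build_guide_tree(
    traces: list[CaTrace], params: AlignParams | None = None
) -> PhyloTree:
    """UPGMA guide tree on d = 1 − TM-score between all trace pairs."""
    params = params or AlignParams()
    if len(traces) < 2:
        raise TreeError("guide tree needs >= 2 traces")
    tm = _pairwise_tm_matrix(traces, params)
    d = np.clip(1.0 - tm, 0.0, None)
    np.fill_diagonal(d, 0.0)
    labels = [t.label for t in traces]
    if len(traces) == 2:
        root_nwk = f"({labels[0]}:{d[0,1]/2:.9g},{labels[1]}:{d[0,1]/2:.9g});"
        return PhyloTree.from_newick(root_nwk)
    return build_tree(DistanceMatrix(labels, d), method="upgma")


# ---------------------------------------------------------------------------
# progressive alignment


class _Profile:
    """Working profile: member indices, column table, per-member frames."""

    def __init__(self, rows, cols, transforms):
        self.rows: list[int] = rows          # indices into the trace list
        self.cols: np.ndarray = cols         # (ncols, len(rows)) residue idx
        self.transforms: dict[int, RigidTransform] = transforms

    @classmethod
    def leaf(cls, member: int, trace: CaTrace) -> "_Profile":
        return cls(
            [member],
            np.arange(len(trace))[:, None],
            {member: RigidTransform.identity()},
        )


def _profile_coords(profile: _Profile, traces: list[CaTrace]) -> np.ndarray:
    """(ncols, nrows, 3) superposed coordinates, NaN at gaps."""
    ncols, nrows = profile.cols.shape
    out = np.full((ncols, nrows, 3), np.nan)
    for r, m in enumerate(profile.rows):
        idx = profile.cols[:, r]
        mask = idx >= 0
        out[mask, r] = profile.transforms[m].apply(traces[m].coords[idx[mask]])
    return out


def _consensus(coords: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nanmean(coords, axis=1)


def _mean_cross_distance(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Mean Cα distance between every column pair of two coordinate stacks."""
    na, nb = pa.shape[0], pb.shape[0]
    total = np.zeros((na, nb))
    count = np.zeros((na, nb))
    for r in range(pa.shape[1]):
        arow = pa[:, r]
        amask = np.isfinite(arow[:, 0])
        for s in range(pb.shape[1]):
            brow = pb[:, s]
            bmask = np.isfinite(brow[:, 0])
            if not amask.any() or not bmask.any():
                continue
            d = cdist(arow[amask], brow[bmask])
            total[np.ix_(amask, bmask)] += d
            count[np.ix_(amask, bmask)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.inf)
    return mean


def _merge(
    pa: _Profile, pb: _Profile, traces: list[CaTrace], params: AlignParams, d0: float
) -> _Profile:
    ca = _consensus(_profile_coords(pa, traces))
    cb = _consensus(_profile_coords(pb, traces))
    # initial frame: pairwise alignment of consensus pseudo-traces
    ta = CaTrace("consA", "", [(i + 1, "") for i in range(len(ca))], "X" * len(ca), ca)
    tb = CaTrace("consB", "", [(i + 1, "") for i in range(len(cb))], "X" * len(cb), cb)
    init = align_pair(ta, tb, params)
    for m in pb.rows:
        pb.transforms[m] = init.transform.compose(pb.transforms[m])

    merged_cols = None
    for _round in range(3):
        A = _profile_coords(pa, traces)
        B = _profile_coords(pb, traces)
        dbar = _mean_cross_distance(A, B)
        S = 1.0 / (1.0 + (dbar / d0) ** 2)
        pairs, _ = _dp.align(S, params.gap_open)
        if len(pairs) < 3:
            raise AlignmentError("profile merge produced fewer than 3 matched columns")
        merged_cols = _stitch_columns(pa.cols, pb.cols, pairs)
        # rigid correction of the whole B-side group on matched consensus columns
        ia, ib = pairs[:, 0], pairs[:, 1]
        both = np.isfinite(_consensus(A)[ia][:, 0]) & np.isfinite(_consensus(B)[ib][:, 0])
        if both.sum() >= 3:
            corr, _ = kabsch_fit(_consensus(A)[ia][both], _consensus(B)[ib][both])
            for m in pb.rows:
                pb.transforms[m] = corr.compose(pb.transforms[m])
    rows = pa.rows + pb.rows
    transforms = {**pa.transforms, **pb.transforms}
    return _Profile(rows, merged_cols, transforms)


def _stitch_columns(cols_a: np.ndarray, cols_b: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    na, ra = cols_a.shape
    nb, rb = cols_b.shape
    out_rows = []
    i = j = 0
    pi = 0
    gap_a = np.full(ra, -1)
    gap_b = np.full(rb, -1)
    while i < na or j < nb:
        if pi < len(pairs) and i == pairs[pi, 0] and j == pairs[pi, 1]:
            out_rows.append(np.concatenate([cols_a[i], cols_b[j]]))
            i += 1
            j += 1
            pi += 1
        elif (pi < len(pairs) and i < pairs[pi, 0]) or (pi >= len(pairs) and i < na):
            out_rows.append(np.concatenate([cols_a[i], gap_b]))
            i += 1
        else:
            out_rows.append(np.concatenate([gap_a, cols_b[j]]))
            j += 1
    return np.asarray(out_rows, int)


def progressive_align(
    traces: list[CaTrace],
    guide: PhyloTree,
    params: AlignParams | None = None,
    refine_rounds: int = 1,
) -> MultipleAlignment:
    """Merge traces bottom-up along the guide tree into one column table.

    After the final merge, the frame is anchored on the member with the
    highest mean TM-score to all others and each member is re-superposed
    once (``refine_rounds`` times) on the consensus of the others.
    """
    params = params or AlignParams()
    labels = [t.label for t in traces]
    if sorted(guide.leaf_labels()) != sorted(labels):
        raise TreeError("guide tree leaves do not match trace labels")
    index = {lab: i for i, lab in enumerate(labels)}
    mean_len = int(round(np.mean([len(t) for t in traces])))
    d0 = params.resolve_d0(mean_len)

    profiles: dict[int, _Profile] = {}
    for node in guide.postorder():
        if node.is_leaf:
            m = index[node.label]
            profiles[id(node)] = _Profile.leaf(m, traces[m])
        else:
            childs = [profiles.pop(id(c)) for c in node.children]
            prof = childs[0]
            for other in childs[1:]:
                prof = _merge(prof, other, traces, params, d0)
            profiles[id(node)] = prof
    prof = profiles[id(guide.root)]

    # reorder rows to the input member order
    cols = np.full((prof.cols.shape[0], len(traces)), -1, int)
    for r, m in enumerate(prof.rows):
        cols[:, m] = prof.cols[:, r]
    transforms = [prof.transforms[m] for m in range(len(traces))]

    msa = MultipleAlignment(traces, cols, transforms, params)
    msa = _anchor_frame(msa)
    for _ in range(max(0, refine_rounds)):
        msa = _refine_once(msa)
    return msa


def _msa_member_tm(msa: MultipleAlignment) -> np.ndarray:
    n = msa.n_members
    coords = [msa.superposed_coords(m) for m in range(n)]
    tm = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = msa.columns[:, i], msa.columns[:, j]
            mask = (ci >= 0) & (cj >= 0)
            if mask.sum() == 0:
                tm[i, j] = tm[j, i] = 0.0
                continue
            d = np.linalg.norm(coords[i][ci[mask]] - coords[j][cj[mask]], axis=1)
            l_norm = min(len(msa.members[i]), len(msa.members[j]))
            tm[i, j] = tm[j, i] = tm_score(d, l_norm, d0_auto(l_norm))
    return tm


def _anchor_frame(msa: MultipleAlignment) -> MultipleAlignment:
    tm = _msa_member_tm(msa)
    anchor = int(np.argmax(tm.sum(axis=1)))
    inv = msa.transforms[anchor].inverse()
    transforms = [inv.compose(t) for t in msa.transforms]
    return MultipleAlignment(msa.members, msa.columns, transforms, msa.params)


def _refine_once(msa: MultipleAlignment) -> MultipleAlignment:
    coords = np.full((msa.n_columns, msa.n_members, 3), np.nan)
    for m in range(msa.n_members):
        idx = msa.columns[:, m]
        mask = idx >= 0
        coords[mask, m] = msa.superposed_coords(m)[idx[mask]]
    transforms = list(msa.transforms)
    for m in range(msa.n_members):
        others = np.ones(msa.n_members, bool)
        others[m] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-gap columns
            cons = np.nanmean(coords[:, others], axis=1)
        idx = msa.columns[:, m]
        mask = (idx >= 0) & np.isfinite(cons[:, 0])
        if mask.sum() < 3:
            continue
        target = cons[mask]
        own = msa.members[m].coords[idx[mask]]
        tr, _ = kabsch_fit(target, own)
        transforms[m] = tr
    return MultipleAlignment(msa.members, msa.columns, transforms, msa.params)


def align_structures(
    traces: list[CaTrace], params: AlignParams | None = None
) -> MultipleAlignment:
    """Convenience wrapper: guide tree + progressive alignment + refinement."""
    params = params or AlignParams()
    guide = build_guide_tree(traces, params)
    return progressive_align(traces, guide, params)
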