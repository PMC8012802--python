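"""Pairwise sequence-independent structural alignment.

Implements the optimal rigid-body superposition (Kabsch), the TM-score, and
an iterative TM-align-style alignment search: seed correspondences from
gapless threading and secondary-structure string alignment are each refined
by alternating rigid superposition on the currently close residue pairs with
dynamic programming on the TM-score term matrix S(i,j) = 1/(1+(d_ij/d0)²).
The best-scoring alignment is kept; everything is deterministic for fixed
inputs and parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import _dp
from .chemdata import DEFAULT_SIMILARITY_GROUPS
from .errors import AlignmentError, TraceError
from .structio import CaTrace, RigidTransform, assign_secondary_structure

__all__ = [
    "AlignParams",
    "PairAlignment",
    "kabsch_fit",
    "d0_auto",
    "tm_score",
    "align_pair",
    "alignment_table",
    "format_alignment_clustal",
]


def d0_auto(l_norm: int) -> float:
    """TM-score distance scale: d0 = 1.24·(L−15)^⅓ − 1.8, clamped to ≥ 0.5 Å."""
    if l_norm <= 15:
        return 0.5
    return max(0.5, 1.24 * (l_norm - 15.0) ** (1.0 / 3.0) - 1.8)


@dataclass(frozen=True)
class AlignParams:
    """Parameters of the pairwise alignment search.

    ``d0_mode`` is either "auto" (length-dependent TM-score scale) or a fixed
    value in Å; ``norm_length`` selects which chain length normalizes the
    TM-score ("shorter" by default so a domain fully contained in a longer
    partner scores ≈ 1); ``gap_open`` is the (≤ 0) penalty for opening a gap
    in the DP, with free extension; ``aligned_cutoff`` is the distance below
    which a matched pair counts as aligned for n_aligned / rmsd_aligned.
    """

    d0_mode: str | float = "auto"
    norm_length: str | int = "shorter"
    gap_open: float = -0.6
    max_iter: int = 30
    aligned_cutoff: float = 5.0
    similarity_groups: dict = field(default_factory=lambda: dict(DEFAULT_SIMILARITY_GROUPS))

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.aligned_cutoff <= 0:
            raise ValueError("aligned_cutoff must be positive")
        if isinstance(self.d0_mode, (int, float)) and self.d0_mode <= 0:
            raise ValueError("fixed d0 must be positive")

    def resolve_l_norm(self, len_a: int, len_b: int) -> int:
        if self.norm_length == "shorter":
            return min(len_a, len_b)
        if self.norm_length == "longer":
            return max(len_a, len_b)
        if self.norm_length == "average":
            return int(round((len_a + len_b) / 2))
        if isinstance(self.norm_length, int):
            return self.norm_length
        raise ValueError(f"bad norm_length {self.norm_length!r}")

    def resolve_d0(self, l_norm: int) -> float:
        if self.d0_mode == "auto":
            return d0_auto(l_norm)
        return float(self.d0_mode)


@dataclass
class PairAlignment:
    """Residue correspondence, rigid transform and scores for two traces.

    ``transform`` maps trace_b coordinates onto trace_a's frame.  The
    reported rmsd_aligned / n_aligned follow the TM-align convention: they
    cover only matched pairs within ``aligned_cutoff`` Å.
    """

    trace_a: CaTrace
    trace_b: CaTrace
    pairs: np.ndarray  # (k, 2) indices into a and b, strictly increasing
    transform: RigidTransform
    tm_score: float
    pair_distances: np.ndarray
    aligned_cutoff: float
    identity: float = 0.0
    similarity: float = 0.0

    @property
    def n_aligned(self) -> int:
        return int(np.sum(self.pair_distances <= self.aligned_cutoff))

    @property
    def rmsd_aligned(self) -> float:
        mask = self.pair_distances <= self.aligned_cutoff
        if not np.any(mask):
            return float("nan")
        return float(np.sqrt(np.mean(self.pair_distances[mask] ** 2)))


def kabsch_fit(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired point sets (b onto a).

    Returns the proper rotation + translation minimizing the RMSD between
    ``R·b + t`` and ``a`` (reflections excluded by determinant correction)
    and the minimized RMSD.  Collinear/degenerate point sets produce a
    warning but still return the least-squares solution.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("paired n×3 coordinate arrays required")
    n = len(A)
    if n < 3:
        raise AlignmentError(f"kabsch_fit needs >= 3 paired points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    H = Bc.T @ Ac
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-10 * max(1.0, s[0]):
        warnings.warn("degenerate (collinear) point set in kabsch_fit", stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    tr = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(B) - A) ** 2, axis=1))))
    return tr, rmsd


def tm_score(distances: np.ndarray, l_norm: int, d0: float | None = None) -> float:
    """TM = (1/L_norm)·Σ 1/(1+(d_i/d0)²) over the matched pairs."""
    d = np.asarray(distances, float)
    if d.size == 0:
        raise AlignmentError("TM-score undefined for an empty alignment")
    if l_norm < 1:
        raise ValueError("l_norm must be >= 1")
    if d0 is None:
        d0 = d0_auto(l_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def tm_frame(
    coords_a: np.ndarray, coords_b: np.ndarray, d0: float
) -> RigidTransform:
    """Frame maximizing the TM-score sum for a fixed correspondence.

    Iterates Kabsch fits on shrinking close-pair subsets (the TM-score
    refinement scheme) and returns the best frame found.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    tr, _ = kabsch_fit(A, B)

    def score(t: RigidTransform) -> float:
        d = np.linalg.norm(t.apply(B) - A, axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)))

    best_tr, best_s = tr, score(tr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny subsets may be near-collinear
        for d_cut in (8.0, 5.0, 4.0, 3.0):
            prev_sub = None
            for _ in range(8):
                d = np.linalg.norm(tr.apply(B) - A, axis=1)
                sub = d < d_cut
                if sub.sum() < 3:
                    sub = np.zeros(len(A), bool)
                    sub[np.argsort(d, kind="stable")[:3]] = True
                key = sub.tobytes()
                if key == prev_sub:
                    break
                prev_sub = key
                tr, _ = kabsch_fit(A[sub], B[sub])
                s = score(tr)
                if s > best_s:
                    best_s, best_tr = s, tr
    return best_tr


def _threading_seeds(na: int, nb: int, min_overlap: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Gapless threading seeds: full overlap windows at sampled offsets,
    plus their half-windows so that frames undisturbed by an indel exist."""
    seeds = []
    offsets = range(-(nb - min_overlap), na - min_overlap + 1)
    step = max(1, (na + nb) // 40)
    for idx, off in enumerate(list(offsets)[::step]):
        ia0, ib0 = max(0, off), max(0, -off)
        k = min(na - ia0, nb - ib0)
        if k < min_overlap:
            continue
        seeds.append((np.arange(ia0, ia0 + k), np.arange(ib0, ib0 + k)))
        h = k // 2
        if h >= 4 and idx % 3 == 0:
            seeds.append((np.arange(ia0, ia0 + h), np.arange(ib0, ib0 + h)))
            seeds.append(
                (np.arange(ia0 + k - h, ia0 + k), np.arange(ib0 + k - h, ib0 + k))
            )
    return seeds


def _ss_seed(a: CaTrace, b: CaTrace) -> tuple[np.ndarray, np.ndarray] | None:
    try:
        sa = assign_secondary_structure(a)
        sb = assign_secondary_structure(b)
    except TraceError:
        return None
    S = (np.array(list(sa))[:, None] == np.array(list(sb))[None, :]).astype(float)
    S = 2.0 * S - 1.0
    pairs, _ = _dp.align(S, -1.0)
    if len(pairs) < 3:
        return None
    return pairs[:, 0], pairs[:, 1]


def align_pair(a: CaTrace, b: CaTrace, params: AlignParams | None = None) -> PairAlignment:
    """Sequence-independent structural alignment of two Cα traces.

    Seeds (gapless threading at multiple offsets plus a secondary-structure
    string alignment) are each refined by alternating (i) rigid fitting on
    the currently close pairs and (ii) DP on S(i,j) = 1/(1+(d_ij/d0)²); the
    refinement with the best final TM-score wins.
    """
    params = params or AlignParams()
    na, nb = len(a), len(b)
    if na < 10 or nb < 10:
        raise TraceError(f"align_pair needs traces of >= 10 residues ({na}, {nb})")
    l_norm = params.resolve_l_norm(na, nb)
    d0 = params.resolve_d0(l_norm)

    seeds = _threading_seeds(na, nb, min_overlap=min(10, na, nb))
    if min(na, nb) <= 24:
        # short traces: dense 4-residue fragment seeds so that a register
        # shifted by an indel anywhere still has one uncontaminated frame
        w = 4
        for i in range(0, na - w + 1, 2):
            for j in range(0, nb - w + 1):
                seeds.append((np.arange(i, i + w), np.arange(j, j + w)))
    ss = _ss_seed(a, b)
    if ss is not None:
        seeds.append(ss)

    best: tuple[float, np.ndarray, RigidTransform] | None = None
    scored: set[bytes] = set()
    for ia, ib in seeds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short seed fragments may be thin
            tr, _ = kabsch_fit(a.coords[ia], b.coords[ib])
        prev = None
        pairs = np.column_stack([ia, ib])
        for _ in range(params.max_iter):
            D = cdist(a.coords, tr.apply(b.coords))
            S = 1.0 / (1.0 + (D / d0) ** 2)
            pairs, _score = _dp.align(S, params.gap_open)
            if len(pairs) < 3:
                break
            key = pairs.tobytes()
            if key == prev:
                break
            prev = key
            # cheap frame update on the currently close pairs; the full
            # TM refinement runs once on the converged pair set below
            pa_c, pb_c = a.coords[pairs[:, 0]], b.coords[pairs[:, 1]]
            d = np.linalg.norm(tr.apply(pb_c) - pa_c, axis=1)
            close = d < max(4.5, 1.5 * d0)
            if close.sum() >= 3:
                tr, _ = kabsch_fit(pa_c[close], pb_c[close])
            else:
                tr, _ = kabsch_fit(pa_c, pb_c)
        if len(pairs) < 3:
            continue
        key = pairs.tobytes()
        if key in scored:
            continue
        scored.add(key)
        tr = tm_frame(a.coords[pairs[:, 0]], b.coords[pairs[:, 1]], d0)
        d = np.linalg.norm(tr.apply(b.coords[pairs[:, 1]]) - a.coords[pairs[:, 0]], axis=1)
        tm = tm_score(d, l_norm, d0)
        if best is None or tm > best[0] + 1e-15:
            best = (tm, pairs, tr)
    if best is None:
        raise AlignmentError(f"no alignment seed converged for {a.label} vs {b.label}")

    tm, pairs, tr = best
    d = np.linalg.norm(tr.apply(b.coords[pairs[:, 1]]) - a.coords[pairs[:, 0]], axis=1)
    ident, simil = _identity_similarity(a, b, pairs, d, params)
    return PairAlignment(
        trace_a=a,
        trace_b=b,
        pairs=pairs,
        transform=tr,
        tm_score=tm,
        pair_distances=d,
        aligned_cutoff=params.aligned_cutoff,
        identity=ident,
        similarity=simil,
    )


def _identity_similarity(a, b, pairs, distances, params) -> tuple[float, float]:
    group_of: dict[str, str] = {}
    for gname, members in params.similarity_groups.items():
        for aa in members:
            group_of[aa] = gname
    mask = distances <= params.aligned_cutoff
    if not np.any(mask):
        return 0.0, 0.0
    n_id = n_sim = n_tot = 0
    for (i, j), ok in zip(pairs, mask):
        if not ok:
            continue
        n_tot += 1
        la, lb = a.sequence[i], b.sequence[j]
        if la == lb:
            n_id += 1
        if la == lb or (
            group_of.get(la) is not None and group_of.get(la) == group_of.get(lb)
        ):
            n_sim += 1
    return n_id / n_tot, n_sim / n_tot


# ---------------------------------------------------------------------------
# export


def alignment_table(pa: PairAlignment) -> str:
    """TSV: index_a, index_b, residue ids/letters and pair distance in Å."""
    lines = ["index_a\tindex_b\tres_a\taa_a\tres_b\taa_b\tdistance_A"]
    for (i, j), d in zip(pa.pairs, pa.pair_distances):
        ra = pa.trace_a.res_ids[i][0]
        rb = pa.trace_b.res_ids[j][0]
        lines.append(
            f"{i}\t{j}\t{ra}\t{pa.trace_a.sequence[i]}\t{rb}\t{pa.trace_b.sequence[j]}\t{d:.6g}"
        )
    return "\n".join(lines) + "\n"


def format_alignment_clustal(pa: PairAlignment, width: int = 60) -> str:
    """CLUSTAL-like text of the pairwise structure-based alignment."""
    sa, sb, match = [], [], []
    pi = 0
    i = j = 0
    pairs = pa.pairs
    while i < len(pa.trace_a) or j < len(pa.trace_b):
        if pi < len(pairs) and i == pairs[pi, 0] and j == pairs[pi, 1]:
            la, lb = pa.trace_a.sequence[i], pa.trace_b.sequence[j]
            sa.append(la)
            sb.append(lb)
            match.append("*" if la == lb else ":")
            i += 1
            j += 1
            pi += 1
        elif pi < len(pairs) and i < pairs[pi, 0]:
            sa.append(pa.trace_a.sequence[i])
            sb.append("-")
            match.append(" ")
            i += 1
        elif pi < len(pairs) and j < pairs[pi, 1]:
            sa.append("-")
            sb.append(pa.trace_b.sequence[j])
            match.append(" ")
            j += 1
        elif i < len(pa.trace_a):
            sa.append(pa.trace_a.sequence[i])
            sb.append("-")
            match.append(" ")
            i += 1
        else:
            sa.append("-")
            sb.append(pa.trace_b.sequence[j])
            match.append(" ")
            j += 1
    na, nb = pa.trace_a.label, pa.trace_b.label
    w = max(len(na), len(nb)) + 2
    out = ["CLUSTAL-like structure-based alignment", ""]
    for k in range(0, len(sa), width):
        out.append(f"{na:<{w}}" + "".join(sa[k : k + width]))
        out.append(f"{nb:<{w}}" + "".join(sb[k : k + width]))
        out.append(" " * w + "".join(match[k : k + width]))
        out.append("")
    return "\n".join(out)
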