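"""Per-position divergence and conservation calls on a structural alignment.

For every column of a multiple structural alignment this module computes
the root-mean-square of the distances between all pairs of superposed
member Cα positions (the per-position divergence painted violet→red in the
fold-family comparison), bins it into a palette, and classifies columns as
identical / similar / variable / gapped over a chosen member scope using a
configurable physicochemical similarity partition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .chemdata import AA_ALPHABET, DEFAULT_SIMILARITY_GROUPS
from .errors import AlignmentError
from .multalign import MultipleAlignment, column_coordinates
from .superpose import PairAlignment

__all__ = [
    "SimilarityGroups",
    "PositionProfile",
    "column_rms_divergence",
    "assign_colors",
    "classify_conservation",
    "pairwise_identity",
    "profile_table",
    "viewer_attributes",
]


@dataclass(frozen=True)
class SimilarityGroups:
    """Named partition of the 20 amino acids into similarity classes."""

    groups: tuple[tuple[str, frozenset[str]], ...] = tuple(
        (k, v) for k, v in DEFAULT_SIMILARITY_GROUPS.items()
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for _, members in self.groups:
            if seen & members:
                raise ValueError("similarity groups overlap")
            seen |= members
        if seen != set(AA_ALPHABET):
            raise ValueError("similarity groups must partition the 20 amino acids")

    def group_of(self, letter: str) -> str | None:
        for name, members in self.groups:
            if letter in members:
                return name
        return None


@dataclass
class PositionProfile:
    """Per-column divergence statistics of a multiple structural alignment.

    ``rms`` is NaN for columns with fewer than two members (undefined);
    ``color_bin`` of −1 renders grey downstream.
    """

    rms: np.ndarray
    n_members: np.ndarray
    method: str = "quadratic"
    color_bins: np.ndarray | None = None
    conservation: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.rms)


def column_rms_divergence(
    msa: MultipleAlignment, method: str = "quadratic"
) -> PositionProfile:
    """Root-mean-square pairwise Cα distance per alignment column.

    For a column with superposed positions p₁..p_k (k ≥ 2):
    rms = sqrt( 2/(k(k−1)) · Σ_{i<j} ‖p_i − p_j‖² ); the "mean" method
    reports the arithmetic mean of the pairwise distances instead.
    """
    if method not in ("quadratic", "mean"):
        raise ValueError(f"unknown method {method!r}")
    ncols = msa.n_columns
    rms = np.full(ncols, np.nan)
    counts = msa.member_count()
    for c in range(ncols):
        if counts[c] < 2:
            continue
        pts = column_coordinates(msa, c)
        # quadratic mean over pairs via the centroid identity:
        # Σ_{i<j} d²  =  k · Σ_i ‖p_i − p̄‖²
        if method == "quadratic":
            k = len(pts)
            ss = float(np.sum((pts - pts.mean(axis=0)) ** 2))
            rms[c] = np.sqrt(2.0 * ss / (k - 1))
        else:
            rms[c] = float(np.mean(pdist(pts)))
    return PositionProfile(rms=rms, n_members=np.asarray(counts), method=method)


def assign_colors(
    profile: PositionProfile,
    msa: MultipleAlignment | None = None,
    palette_size: int = 10,
    mode: str = "linear",
    grey_policy: str = "any_gap",
) -> np.ndarray:
    """Bin per-column divergence into a violet(0)→red(max) palette.

    Undefined columns get −1 (grey).  ``grey_policy`` decides what counts
    as unalignable: "any_gap" greys every column where at least one member
    is absent; "min_members" greys only columns with fewer than two.
    The mapping is monotone in rms; "quantile" equalizes bin occupancy.
    """
    if palette_size < 2:
        raise ValueError("palette_size must be >= 2")
    if mode not in ("linear", "quantile"):
        raise ValueError(f"unknown mode {mode!r}")
    if grey_policy not in ("any_gap", "min_members"):
        raise ValueError(f"unknown grey policy {grey_policy!r}")
    defined = np.isfinite(profile.rms)
    if grey_policy == "any_gap":
        if msa is None:
            raise ValueError("any_gap grey policy needs the alignment")
        defined &= profile.n_members == msa.n_members
    bins = np.full(profile.n_columns, -1, int)
    vals = profile.rms[defined]
    if vals.size == 0:
        profile.color_bins = bins
        return bins
    if mode == "linear":
        lo, hi = float(vals.min()), float(vals.max())
        if hi - lo < 1e-12:
            bins[defined] = 0
        else:
            scaled = (profile.rms[defined] - lo) / (hi - lo)
            bins[defined] = np.minimum((scaled * palette_size).astype(int), palette_size - 1)
    else:
        order = np.argsort(vals, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(vals))
        bins[defined] = (ranks * palette_size) // len(vals)
    profile.color_bins = bins
    return bins


def classify_conservation(
    msa: MultipleAlignment,
    groups: SimilarityGroups | None = None,
    scope: list[int] | None = None,
) -> tuple[list[str], Counter]:
    """Identical / similar / variable / gapped call per column over a scope.

    A column is *identical* when every scope member shows the same residue,
    *similar* when all residues fall in one similarity group, *gapped* when
    any scope member is absent, otherwise *variable*.  Identical columns
    are counted as similar too in the census (identical ⇒ similar).
    """
    groups = groups or SimilarityGroups()
    scope = list(range(msa.n_members)) if scope is None else list(scope)
    if not scope:
        raise ValueError("empty member scope")
    classes: list[str] = []
    for c in range(msa.n_columns):
        letters = [msa.column_letters(c)[m] for m in scope]
        if "-" in letters:
            classes.append("gapped")
        elif len(set(letters)) == 1:
            classes.append("identical")
        else:
            gs = {groups.group_of(l) for l in letters}
            if len(gs) == 1 and None not in gs:
                classes.append("similar")
            else:
                classes.append("variable")
    census = Counter(classes)
    census["similar_or_identical"] = census["similar"] + census["identical"]
    return classes, census


def pairwise_identity(
    source: MultipleAlignment | PairAlignment,
    pair: tuple[int, int] | None = None,
    groups: SimilarityGroups | None = None,
) -> tuple[float, float]:
    """Identity and similarity fractions over the aligned columns of a pair."""
    groups = groups or SimilarityGroups()
    if isinstance(source, PairAlignment):
        return source.identity, source.similarity
    if pair is None:
        raise ValueError("member pair required for a multiple alignment")
    i, j = pair
    ci, cj = source.columns[:, i], source.columns[:, j]
    mask = (ci >= 0) & (cj >= 0)
    if not np.any(mask):
        raise AlignmentError(f"members {i} and {j} share no aligned columns")
    si, sj = source.members[i].sequence, source.members[j].sequence
    n_id = n_sim = 0
    total = int(mask.sum())
    for a, b in zip(ci[mask], cj[mask]):
        la, lb = si[a], sj[b]
        if la == lb:
            n_id += 1
            n_sim += 1
        elif groups.group_of(la) is not None and groups.group_of(la) == groups.group_of(lb):
            n_sim += 1
    return n_id / total, n_sim / total


# ---------------------------------------------------------------------------
# exports


def profile_table(
    msa: MultipleAlignment, profile: PositionProfile, classes: list[str] | None = None
) -> str:
    """Per-column TSV: column, members, rms Å, color bin, conservation class."""
    bins = profile.color_bins if profile.color_bins is not None else np.full(
        profile.n_columns, -1, int
    )
    lines = ["column\tn_members\trms_A\tcolor_bin\tclass"]
    for c in range(profile.n_columns):
        rms = "" if not np.isfinite(profile.rms[c]) else f"{profile.rms[c]:.6g}"
        cls = classes[c] if classes else ""
        lines.append(f"{c}\t{profile.n_members[c]}\t{rms}\t{bins[c]}\t{cls}")
    return "\n".join(lines) + "\n"


def viewer_attributes(msa: MultipleAlignment, profile: PositionProfile) -> str:
    """Plain-text attribute list for molecular viewers: member, residue, bin."""
    bins = profile.color_bins
    if bins is None:
        raise ValueError("assign_colors must run before exporting attributes")
    lines = ["# member\tres_seq\tcolor_bin"]
    for m, trace in enumerate(msa.members):
        for c in range(msa.n_columns):
            i = msa.columns[c, m]
            if i >= 0:
                lines.append(f"{trace.label}\t{trace.res_ids[i][0]}\t{bins[c]}")
    return "\n".join(lines) + "\n"
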