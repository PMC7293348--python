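"""Split-half reliability and reliability-based voxel selection.

A voxel's split-half reliability is the Pearson correlation of its
60-condition response vector between odd and even runs.  Item-pattern
reliability is the complementary quantity for one stimulus: the correlation
of its multi-voxel pattern between the two splits.  Voxel selection sweeps
a grid of reliability cutoffs, computes the mean item-pattern reliability
among surviving voxels at each cutoff, and picks the cutoff where that
curve begins to plateau — stricter cutoffs past that point shrink coverage
without buying reliability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DataError

CUTOFF_GRID = np.round(np.arange(-1.0, 0.9001, 0.05), 10)
MIN_SUBSET = 10          # minimum surviving voxels for a curve point
PLATEAU_TOL = 0.05       # plateau band below the ceiling, as a fraction
                         # of the curve's total range


@dataclass
class VoxelResponseSet:
    """Per-voxel response magnitudes indexed by (video set, run split).

    responses maps (set, split) -> voxels x conditions array, with
    set in {1, 2} and split in {"odd", "even"}.  voxel_coords are integer
    3-D indices into a volume of shape mask_shape; condition_ids label the
    columns per set.
    """

    responses: dict[tuple[int, str], np.ndarray]
    voxel_coords: np.ndarray
    mask_shape: tuple[int, int, int]
    condition_ids: dict[int, list[str]]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        shapes = {k: v.shape for k, v in self.responses.items()}
        n_vox = {s[0] for s in shapes.values()}
        if len(n_vox) != 1:
            raise DataError("all (set, split) matrices must share voxels")
        for (s, _), shape in shapes.items():
            if shape[1] != len(self.condition_ids[s]):
                raise DataError(
                    f"set {s}: condition count mismatch between responses "
                    "and condition_ids")
        if len(self.voxel_coords) != n_vox.pop():
            raise DataError("voxel_coords length must match responses")

    @property
    def n_voxels(self) -> int:
        return next(iter(self.responses.values())).shape[0]

    @property
    def sets(self) -> list[int]:
        return sorted({s for s, _ in self.responses})

    def split_average(self, s: int) -> np.ndarray:
        """Mean of odd and even responses for one set (voxels x conds)."""
        return 0.5 * (self.responses[(s, "odd")] + self.responses[(s, "even")])


@dataclass
class ReliabilityResult:
    """Per-voxel split-half reliability plus the selection curve."""

    voxel_r: np.ndarray
    scheme: str
    curve: pd.DataFrame | None = None
    selected_cutoff: float | None = None

    def surviving(self, cutoff: float) -> np.ndarray:
        """Boolean mask of voxels with reliability >= cutoff (NaN fails)."""
        r = np.where(np.isnan(self.voxel_r), -np.inf, self.voxel_r)
        return r >= cutoff


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows; NaN where either row is constant."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(axis=1) / denom, np.nan)
    return np.clip(r, -1.0, 1.0)


def _split_pairs(data: VoxelResponseSet, scheme: str
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    r = data.responses
    if scheme == "within_set":
        return [(r[(s, "odd")], r[(s, "even")]) for s in data.sets]
    if scheme == "across_set":
        if len(data.sets) < 2:
            raise DataError("across_set reliability needs two sets")
        s1, s2 = data.sets[:2]
        return [(r[(s1, "odd")], r[(s2, "even")]),
                (r[(s2, "odd")], r[(s1, "even")])]
    raise ValueError(f"unknown scheme {scheme!r}")


def splithalf_reliability(data: VoxelResponseSet,
                          scheme: str = "across_set") -> ReliabilityResult:
    """Per-voxel split-half reliability.

    within_set: correlate odd vs even betas separately for each set, then
    average the two r-maps.  across_set: correlate odd and even betas taken
    from the two different sets (both pairings, averaged), which requires
    responses to generalize across exemplar videos of the same action.
    Zero-variance voxels get NaN and are excluded downstream.
    """
    pairs = _split_pairs(data, scheme)
    if any(p[0].shape[1] < 3 for p in pairs):
        raise DataError("split-half reliability needs at least 3 conditions")
    rmaps = np.stack([_rowwise_pearson(a, b) for a, b in pairs])
    return ReliabilityResult(voxel_r=rmaps.mean(axis=0), scheme=scheme)


def item_pattern_reliability(data: VoxelResponseSet,
                             voxel_subset: np.ndarray,
                             scheme: str = "across_set",
                             ) -> tuple[np.ndarray, float]:
    """Split-half reliability of each item's multi-voxel pattern.

    For each condition, correlates its odd-split pattern with its
    even-split pattern over the subset voxels (averaged over the scheme's
    split pairings).  Returns (per-condition r vector, mean).
    """
    subset = np.asarray(voxel_subset)
    if subset.dtype == bool:
        subset = np.flatnonzero(subset)
    if subset.size == 0:
        raise DataError("voxel subset is empty")
    if subset.size < 2:
        raise DataError("item-pattern reliability needs >= 2 voxels")
    pairs = _split_pairs(data, scheme)
    rs = np.stack([_rowwise_pearson(a[subset].T, b[subset].T)
                   for a, b in pairs])
    item_r = rs.mean(axis=0)
    return item_r, float(np.nanmean(item_r))


def reliability_curve(data: VoxelResponseSet,
                      cutoffs: np.ndarray = CUTOFF_GRID,
                      scheme: str = "across_set",
                      min_subset: int = MIN_SUBSET) -> ReliabilityResult:
    """Mean item-pattern reliability among voxels surviving each cutoff.

    Points whose surviving subset is smaller than ``min_subset`` voxels are
    marked unavailable (mean_item_r = NaN).
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoffs must be strictly increasing")
    if cutoffs.min() < -1 or cutoffs.max() > 1:
        raise ValueError("cutoffs must lie within [-1, 1]")
    res = splithalf_reliability(data, scheme)
    rows = []
    for c in cutoffs:
        mask = res.surviving(c)
        n = int(mask.sum())
        if n >= max(min_subset, 2):
            _, mean_r = item_pattern_reliability(data, mask, scheme)
            rows.append((c, mean_r, n, True))
        else:
            rows.append((c, np.nan, n, False))
    res.curve = pd.DataFrame(
        rows, columns=["cutoff", "mean_item_r", "n_voxels", "available"])
    return res


def select_cutoff(curve: pd.DataFrame,
                  tol: float = PLATEAU_TOL) -> float:
    """Pick the reliability cutoff where the item-pattern curve plateaus.

    The plateau is the first available cutoff whose mean item-pattern
    reliability comes within ``tol`` (a fraction of the curve's total
    range) of the curve's ceiling: beyond that point a stricter cutoff
    restricts coverage without meaningfully increasing reliability.  A
    flat curve returns the smallest available cutoff.  If the plateau
    only begins in the last two grid points (e.g., a strictly rising
    curve), no plateau exists and the function falls back to the cutoff
    maximizing normalized reliability minus lost coverage, with a warning.
    """
    avail = curve[curve["available"]].reset_index(drop=True)
    if len(avail) < 3:
        raise DataError("need at least 3 available curve points")
    y = avail["mean_item_r"].to_numpy()
    rng = float(y.max() - y.min())
    if rng == 0:
        return float(avail["cutoff"].iloc[0])
    first = int(np.argmax(y >= y.max() - tol * rng))
    if first < len(y) - 2:
        return float(avail["cutoff"].iloc[first])
    warnings.warn("no plateau found; falling back to gain/coverage score",
                  RuntimeWarning, stacklevel=2)
    n = avail["n_voxels"].to_numpy(dtype=float)
    score = (y - y.min()) / rng - (1.0 - n / n.max())
    return float(avail["cutoff"].iloc[int(np.argmax(score))])
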