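"""Voxelwise functional-connectivity statistics on subject spatial maps.

One-sample t-maps give each network's group-level topography; paired t-maps
localise condition differences.  Thresholding is either Benjamini-Hochberg
FDR or an uncorrected p cut, followed by connected-component cluster
extraction with a minimum-extent filter.  A region of interest is a peak
voxel plus its 26 neighbours (a 3 x 3 x 3 block, 9 x 9 x 9 mm^3 at 3 mm
voxels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage, stats

from .errors import BoundaryError, DegenerateInputError, ValidationError
from .grid import VolumeGrid
from .prep import FmriSession, TimeCourse

logger = logging.getLogger(__name__)


@dataclass
class StatMap:
    """Voxelwise t and two-sided p values of a one-sample or paired test."""

    grid: VolumeGrid
    t_values: np.ndarray  # grid-shaped
    p_values: np.ndarray
    df: int
    test: Literal["one_sample", "paired"]
    n_degenerate: int = 0  # zero-variance voxels mapped to +/- inf sentinels

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValidationError(f"df must be >= 1, got {self.df}")
        if self.t_values.shape != self.grid.dims or self.p_values.shape != self.grid.dims:
            raise ValidationError("stat maps must be grid shaped")


@dataclass
class Cluster:
    """A connected suprathreshold cluster with its peak statistics."""

    member_voxels: frozenset[tuple[int, int, int]]
    size_voxels: int
    peak_voxel: tuple[int, int, int]
    peak_t: float
    peak_mm: tuple[float, float, float]
    direction: Literal["A>B", "B>A"]

    def __post_init__(self) -> None:
        if self.size_voxels != len(self.member_voxels):
            raise ValidationError("cluster size must equal the member count")
        if self.peak_voxel not in self.member_voxels:
            raise ValidationError("cluster peak must be a member voxel")


@dataclass
class Roi:
    """A peak voxel plus its 26 neighbours."""

    name: str
    center_voxel: tuple[int, int, int]
    member_voxels: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.member_voxels) != 27:
            raise ValidationError(f"an ROI has exactly 27 voxels, got {len(self.member_voxels)}")


def zscore_map(volume: np.ndarray) -> np.ndarray:
    """Normalise a spatial map to zero mean and unit sd over voxels."""
    v = np.asarray(volume, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot z-score a constant map")
    return (v - v.mean()) / sd


def _t_to_p(t: np.ndarray, df: int) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def _ttest_stack(stack: np.ndarray, grid: VolumeGrid, test: str) -> StatMap:
    """One-sample t over the first axis of (n, nx, ny, nz)."""
    n = stack.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 maps")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    n_degenerate = int(degenerate.sum())
    # zero-variance voxels: +/- inf sentinel (p = 0) when the mean is nonzero,
    # t = 0 (p = 1) when the data are identically zero
    dm = mean[degenerate]
    t[degenerate] = np.where(dm > 0, np.inf, np.where(dm < 0, -np.inf, 0.0))
    p = np.where(np.isinf(t), 0.0, _t_to_p(np.where(np.isfinite(t), t, 0.0), n - 1))
    p[(t == 0) & degenerate] = 1.0
    if n_degenerate:
        logger.info("%s t-test: %d zero-variance voxels mapped to sentinels", test, n_degenerate)
    return StatMap(grid, t, p, df=n - 1, test=test, n_degenerate=n_degenerate)  # type: ignore[arg-type]


def one_sample_ttest(maps: list[np.ndarray] | np.ndarray, grid: VolumeGrid) -> StatMap:
    """Random-effects one-sample t-test across subject maps, df = n - 1."""
    stack = np.stack([np.asarray(m, dtype=float).reshape(grid.dims) for m in maps])
    return _ttest_stack(stack, grid, "one_sample")


def paired_ttest(
    maps_a: list[np.ndarray] | np.ndarray,
    maps_b: list[np.ndarray] | np.ndarray,
    grid: VolumeGrid,
    subject_ids_a: list[str] | None = None,
    subject_ids_b: list[str] | None = None,
) -> StatMap:
    """Paired t-test (one-sample on per-subject A - B differences).

    Positive t means A > B.  If subject id lists are supplied they must be
    aligned; a mismatch is an error rather than a silent reordering.
    """
    a = np.stack([np.asarray(m, dtype=float).reshape(grid.dims) for m in maps_a])
    b = np.stack([np.asarray(m, dtype=float).reshape(grid.dims) for m in maps_b])
    if a.shape != b.shape:
        raise ValidationError(f"paired test needs equal group sizes, got {a.shape[0]} vs {b.shape[0]}")
    if subject_ids_a is not None or subject_ids_b is not None:
        if list(subject_ids_a or []) != list(subject_ids_b or []):
            raise ValidationError("paired test requires identically ordered subject ids")
    out = _ttest_stack(a - b, grid, "paired")
    return out


def fdr_threshold(p_values: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Returns a boolean rejection mask (same shape as the input) and the
    critical p value (0.0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValidationError(f"q must lie in (0, 1), got {q}")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    if not np.any(below):
        return np.zeros_like(p, dtype=bool), 0.0
    k = int(np.flatnonzero(below)[-1])
    crit = float(ranked[k])
    return p <= crit, crit


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    stat: StatMap,
    p_thresh: float = 0.005,
    min_extent: int = 20,
    connectivity: Literal[6, 18, 26] = 26,
) -> list[Cluster]:
    """Connected suprathreshold clusters, split by effect direction.

    The suprathreshold mask (p below threshold) is partitioned by the sign of
    t into A>B and B>A masks, each labelled with the requested neighbourhood;
    clusters smaller than ``min_extent`` are dropped.  The peak is the member
    with maximal |t|; output order is (direction, descending peak t).
    """
    if connectivity not in _STRUCTS:
        raise ValidationError(f"connectivity must be one of {sorted(_STRUCTS)}")
    if not (0 < p_thresh < 1):
        raise ValidationError(f"p threshold must be in (0, 1), got {p_thresh}")
    if min_extent < 1:
        raise ValidationError("min_extent must be >= 1")
    clusters: list[Cluster] = []
    base = stat.p_values < p_thresh
    for direction, mask in (("A>B", base & (stat.t_values > 0)), ("B>A", base & (stat.t_values < 0))):
        labels, n_lab = ndimage.label(mask, structure=_STRUCTS[connectivity])
        for lab in range(1, n_lab + 1):
            members = np.argwhere(labels == lab)
            if members.shape[0] < min_extent:
                continue
            t_vals = stat.t_values[tuple(members.T)]
            peak = members[int(np.argmax(np.abs(t_vals)))]
            peak_t = float(stat.t_values[tuple(peak)])
            clusters.append(
                Cluster(
                    member_voxels=frozenset(map(tuple, members.tolist())),
                    size_voxels=int(members.shape[0]),
                    peak_voxel=tuple(int(i) for i in peak),
                    peak_t=peak_t,
                    peak_mm=tuple(stat.grid.voxel_to_mm(peak)),
                    direction=direction,  # type: ignore[arg-type]
                )
            )
    clusters.sort(key=lambda c: (c.direction, -abs(c.peak_t)))
    return clusters


def define_roi(peak_voxel: tuple[int, int, int], grid: VolumeGrid, name: str) -> Roi:
    """The 3 x 3 x 3 voxel block centred on a peak voxel.

    The full block must fit inside the grid; a peak on the boundary is an
    error rather than a truncated ROI.
    """
    c = tuple(int(i) for i in peak_voxel)
    for axis in range(3):
        if not (1 <= c[axis] <= grid.dims[axis] - 2):
            raise BoundaryError(
                f"ROI at {c} would extend past the grid boundary on axis {axis}"
            )
    members = tuple(
        (c[0] + dx, c[1] + dy, c[2] + dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    )
    return Roi(name=name, center_voxel=c, member_voxels=members)


def roi_timeseries(session: FmriSession, roi: Roi) -> TimeCourse:
    """Zero-meaned average BOLD series over the ROI's 27 voxels."""
    for v in roi.member_voxels:
        for axis in range(3):
            if not (0 <= v[axis] < session.grid.dims[axis]):
                raise ValidationError(f"ROI voxel {v} lies outside the session grid")
    idx = np.array(roi.member_voxels)
    series = session.data[idx[:, 0], idx[:, 1], idx[:, 2], :].mean(axis=0)
    return TimeCourse(series - series.mean(), session.tr_s)
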