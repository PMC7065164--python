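"""AP profiles: cross-sectional areas, qT2 points, regions, metrics.

A *profile* pairs anterior-posterior template-space positions (mm) with a
measurement: cross-sectional area (CSA, mm^2) of the hippocampal
segmentation per coronal slice, or mean qT2 (ms) per dual-echo slice.  CSA
profiles come from 1-mm isotropic data and are resampled to a uniform 1-mm
grid (continuous); qT2 profiles keep one discrete point per acquired 4-mm
slice.

CSA values are corrected for head size by ratio scaling with the total
intracranial volume: ``CSA_corrected = CSA_raw * (tiv_ref / tiv)``, with
``tiv_ref`` the normative-cohort mean TIV.  Applying the same factor to
slice areas and volumes keeps profiles integrating exactly to corrected
volumes.

Regions (tail, body, head, posterior to anterior) are defined from the
normative CSA curve: the body is the maximal contiguous run of grid points
where the absolute CSA slope is below 2 mm^2/mm (central differences);
everything posterior is tail, everything anterior is head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .alignment import AlignmentError, SliceDistanceTable
from .image_io import EmptyInputError, Segmentation, ap_axis, in_plane_area
from .relaxometry import MaskedQT2

__all__ = [
    "Profile",
    "RegionPartition",
    "SubjectMetrics",
    "NoBodyError",
    "csa_profile",
    "qt2_profile",
    "partition_regions",
    "region_metrics",
]

REGION_NAMES = ("tail", "body", "head")
SLOPE_THRESHOLD = 2.0  # mm^2/mm: "stable" CSA defining the hippocampal body


class NoBodyError(RuntimeError):
    """No grid point satisfies the body stability criterion."""


@dataclass
class Profile:
    """Positions (mm, strictly ascending) paired with CSA or qT2 values."""

    positions: np.ndarray
    values: np.ndarray
    modality: Literal["csa", "qt2"]
    side: Literal["left", "right"] = "left"
    subject_id: str = ""
    sampling: Literal["continuous-1mm", "discrete-slice"] = "continuous-1mm"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.values.shape:
            raise ValueError("positions and values must be matching 1-D arrays")
        if len(self.positions) and not np.all(np.diff(self.positions) > 0):
            raise ValueError("profile positions must be strictly ascending")
        if self.modality == "csa" and np.any(self.values < 0):
            raise ValueError("CSA values must be nonnegative")
        if self.modality == "qt2" and np.any(self.values[np.isfinite(self.values)] <= 0):
            raise ValueError("qT2 values must be positive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid``; NaN outside the support."""
        grid = np.asarray(grid, dtype=float)
        out = np.interp(grid, self.positions, self.values,
                        left=np.nan, right=np.nan)
        return out

    def integral(self) -> float:
        """Trapezoidal integral (mm^3 for CSA profiles)."""
        return float(np.trapezoid(self.values, self.positions))


def _uniform_grid(lo: float, hi: float, step: float = 1.0) -> np.ndarray:
    start = np.ceil(lo / step) * step
    stop = np.floor(hi / step) * step
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(max(n, 0))


@dataclass(frozen=True)
class RegionPartition:
    """Tail | body | head boundaries along the AP axis (mm)."""

    side: Literal["left", "right"]
    extent: tuple[float, float]        # profiled extent (posterior, anterior)
    tail_body_mm: float                # posterior body boundary
    body_head_mm: float                # anterior body boundary
    degenerate: bool = False           # body spans the whole extent

    @property
    def lengths(self) -> dict[str, float]:
        lo, hi = self.extent
        return {
            "tail": self.tail_body_mm - lo,
            "body": self.body_head_mm - self.tail_body_mm,
            "head": hi - self.body_head_mm,
        }

    def region_of(self, position: float | np.ndarray) -> np.ndarray:
        """Region name per position ('' outside the extent)."""
        pos = np.atleast_1d(np.asarray(position, dtype=float))
        out = np.full(pos.shape, "", dtype=object)
        lo, hi = self.extent
        out[(pos >= lo) & (pos < self.tail_body_mm)] = "tail"
        out[(pos >= self.tail_body_mm) & (pos < self.body_head_mm)] = "body"
        out[(pos >= self.body_head_mm) & (pos <= hi)] = "head"
        return out


@dataclass
class SubjectMetrics:
    """Whole and regional TIV-corrected volumes (mL) and qT2 (ms)."""

    subject_id: str
    side: Literal["left", "right"]
    tiv_ml: float
    whole_volume_ml: float
    region_volumes_ml: dict[str, float]
    whole_qt2_ms: float
    region_qt2_ms: dict[str, float]          # NaN where no slice fell in a region
    missing_qt2_regions: tuple[str, ...] = ()


def slice_areas(seg: Segmentation) -> tuple[np.ndarray, np.ndarray]:
    """Fractional in-mask area (mm^2) per coronal slice of the segmentation.

    Returns ``(slice_indices, areas)`` for occupied slices.  The fractional
    sum equals the voxel count for binary masks; for probabilistic masks it
    is the expected area.
    """
    vol = seg.as_volume()
    axis, _ = ap_axis(vol)
    sums = seg.data.sum(axis=tuple(i for i in range(3) if i != axis))
    occupied = np.nonzero(sums > 1e-9)[0]
    if occupied.size == 0:
        raise EmptyInputError("segmentation is empty")
    return occupied, sums[occupied] * in_plane_area(vol)


def csa_profile(seg: Segmentation, table: SliceDistanceTable,
                tiv_ml: float, tiv_ref_ml: float,
                subject_id: str = "", grid_step: float = 1.0) -> Profile:
    """TIV-corrected CSA profile on the uniform 1-mm template grid.

    Raw per-slice areas are scaled by ``tiv_ref / tiv``, paired with each
    slice's mean propagated AP distance, and linearly interpolated to the
    uniform grid so profiles are comparable across subjects.
    """
    if tiv_ml <= 0 or tiv_ref_ml <= 0:
        raise ValueError("TIV values must be positive")
    idx, areas = slice_areas(seg)
    lookup = dict(zip(table.slice_indices.tolist(),
                      table.mean_distance_mm.tolist()))
    missing = [int(i) for i in idx if int(i) not in lookup]
    if missing:
        raise AlignmentError(
            f"distance table does not cover occupied slices {missing}")
    dist = np.array([lookup[int(i)] for i in idx])
    order = np.argsort(dist)
    dist, areas = dist[order], areas[order]
    if len(dist) > 1 and not np.all(np.diff(dist) > 0):
        raise AlignmentError("slice distances are not strictly increasing")
    corrected = areas * (tiv_ref_ml / tiv_ml)
    grid = _uniform_grid(dist[0], dist[-1], grid_step)
    if grid.size == 0:
        grid = dist[:1]
    values = np.interp(grid, dist, corrected)
    return Profile(grid, values, modality="csa", side=seg.side,
                   subject_id=subject_id, sampling="continuous-1mm")


def qt2_profile(summary: MaskedQT2, table: SliceDistanceTable,
                side: Literal["left", "right"] = "left",
                subject_id: str = "", min_valid_voxels: int = 5
                ) -> tuple[Profile, np.ndarray]:
    """Discrete qT2 profile: one point per usable dual-echo slice.

    Slices with fewer than ``min_valid_voxels`` valid non-partial-volume
    voxels are omitted (missing, never zero).  Returns the profile and the
    per-point segmentation slice volume (mm^3) used later as the
    region-averaging weight.
    """
    lookup = dict(zip(table.slice_indices.tolist(),
                      table.mean_distance_mm.tolist()))
    pts = []
    for i, mean_ms, count, vol in zip(summary.slice_indices,
                                      summary.slice_means_ms,
                                      summary.slice_valid_counts,
                                      summary.slice_seg_volumes_mm3):
        if count < min_valid_voxels or not np.isfinite(mean_ms):
            continue
        if int(i) not in lookup:
            continue
        pts.append((lookup[int(i)], float(mean_ms), float(vol)))
    if not pts:
        raise EmptyInputError("no usable qT2 slices")
    pts.sort()
    pos, vals, vols = map(np.asarray, zip(*pts))
    profile = Profile(pos, vals, modality="qt2", side=side,
                      subject_id=subject_id, sampling="discrete-slice")
    return profile, vols


def partition_regions(positions: np.ndarray, mu: np.ndarray,
                      side: Literal["left", "right"] = "left",
                      slope_threshold: float = SLOPE_THRESHOLD
                      ) -> RegionPartition:
    """Partition the AP extent into tail/body/head from a normative CSA curve.

    The body is the maximal contiguous run of grid points where the central
    difference |d mu / dx| is below ``slope_threshold``; equal-length runs
    tie-break toward the more posterior one.  A run spanning the entire
    extent is flagged degenerate (tail and head lengths zero).
    """
    positions = np.asarray(positions, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if len(positions) < 3:
        raise EmptyInputError("need at least 3 grid points to partition")
    slope = np.gradient(mu, positions)  # central differences, one-sided at ends
    stable = np.abs(slope) < slope_threshold
    if not stable.any():
        raise NoBodyError("no grid point satisfies the CSA stability rule")
    # maximal runs of True
    padded = np.concatenate([[False], stable, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0]  # exclusive
    lengths = ends - starts
    best = int(np.argmax(lengths))  # argmax takes the first (posterior) tie
    s, e = int(starts[best]), int(ends[best]) - 1
    degenerate = (s == 0) and (e == len(positions) - 1)
    return RegionPartition(
        side=side,
        extent=(float(positions[0]), float(positions[-1])),
        tail_body_mm=float(positions[s]),
        body_head_mm=float(positions[e]),
        degenerate=degenerate,
    )


def region_metrics(profile: Profile, qt2_points: Profile | None,
                   qt2_slice_volumes: np.ndarray | None,
                   partition: RegionPartition,
                   tiv_ml: float, subject_id: str = "") -> SubjectMetrics:
    """Whole and regional volumes (CSA summation) and volume-weighted qT2.

    Region volume is the sum of CSA values times the grid step over the
    region; region qT2 averages slicewise qT2 weighted by the segmentation
    volume in each slice, with each slice assigned to the region containing
    its mean AP distance.
    """
    if profile.modality != "csa":
        raise ValueError("region metrics need a CSA profile")
    step = float(np.median(np.diff(profile.positions))) if len(profile) > 1 else 1.0
    regions = partition.region_of(profile.positions)
    region_volumes = {}
    for name in REGION_NAMES:
        sel = regions == name
        region_volumes[name] = float(profile.values[sel].sum() * step) / 1000.0
    whole = float(profile.values.sum() * step) / 1000.0

    region_qt2 = {name: float("nan") for name in REGION_NAMES}
    whole_qt2 = float("nan")
    missing: list[str] = []
    if qt2_points is not None and len(qt2_points):
        if qt2_slice_volumes is None or len(qt2_slice_volumes) != len(qt2_points):
            raise ValueError("qT2 points need matching slice volumes")
        w = np.asarray(qt2_slice_volumes, dtype=float)
        whole_qt2 = float(np.sum(qt2_points.values * w) / np.sum(w))
        point_regions = partition.region_of(qt2_points.positions)
        for name in REGION_NAMES:
            sel = point_regions == name
            if sel.any():
                region_qt2[name] = float(
                    np.sum(qt2_points.values[sel] * w[sel]) / np.sum(w[sel]))
            else:
                missing.append(name)
    return SubjectMetrics(
        subject_id=subject_id or profile.subject_id,
        side=profile.side,
        tiv_ml=tiv_ml,
        whole_volume_ml=whole,
        region_volumes_ml=region_volumes,
        whole_qt2_ms=whole_qt2,
        region_qt2_ms=region_qt2,
        missing_qt2_regions=tuple(missing),
    )
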