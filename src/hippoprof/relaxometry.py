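"""Voxelwise quantitative T2 from dual-echo data, with masked summaries.

A dual-echo acquisition samples the mono-exponential decay
``S(TE) = S0 exp(-TE / T2)`` at two echo times, giving the closed-form
two-point estimator

    qT2 = (TE2 - TE1) / ln(S(TE1) / S(TE2))    [ms]

Voxels where the closed form is undefined or unphysical (non-positive
signal, non-decaying signal, or qT2 above a CSF-level ceiling) are marked
invalid with an explicit reason, never silently clamped.  Hippocampal qT2
summaries exclude partial-volume voxels: the segmentation is resampled to
the dual-echo grid with linear interpolation and only voxels with mask
fraction >= ``pv_threshold`` (default 0.99) are kept, falling back to a
one-voxel interior erosion if too few voxels survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import (
    EmptyInputError,
    GeometryError,
    ImageVolume,
    Segmentation,
    Transform,
    ap_axis,
    resample,
)

__all__ = ["ExclusionReason", "QT2Result", "MaskedQT2", "fit_qt2", "masked_qt2"]

QT2_CEILING_MS = 1000.0  # above this the voxel is treated as CSF-dominated


class ExclusionReason:
    """Integer codes stored in the exclusion map of a :class:`QT2Result`."""

    VALID = 0
    NONPOSITIVE_SIGNAL = 1
    NONDECAYING = 2
    ABOVE_CEILING = 3
    PV_EXCLUDED = 4  # only used in masked summaries


@dataclass
class QT2Result:
    """Voxelwise qT2 map plus validity bookkeeping."""

    qt2_map: ImageVolume            # ms; NaN at invalid voxels
    valid: np.ndarray               # bool, same grid
    exclusion: np.ndarray           # uint8 ExclusionReason codes
    echo_times: tuple[float, float]

    @property
    def excluded_voxel_count(self) -> int:
        return int((~self.valid).sum())


@dataclass
class MaskedQT2:
    """Hippocampal qT2 summary after partial-volume exclusion."""

    mean_ms: float
    slice_indices: np.ndarray       # coronal slice index on the qT2 grid
    slice_means_ms: np.ndarray      # NaN where a slice has no usable voxels
    slice_valid_counts: np.ndarray
    slice_seg_volumes_mm3: np.ndarray  # segmentation volume per slice (all voxels)
    n_voxels_used: int
    pv_excluded_count: int


def fit_qt2(echo1: ImageVolume, echo2: ImageVolume,
            te1: float, te2: float,
            ceiling_ms: float = QT2_CEILING_MS) -> QT2Result:
    """Two-point mono-exponential T2 fit of a co-registered echo pair."""
    if not 0 < te1 < te2:
        raise ValueError(f"echo times must satisfy TE2 > TE1 > 0, got {te1}/{te2}")
    if echo1.shape != echo2.shape or not np.allclose(echo1.affine, echo2.affine,
                                                    atol=1e-5):
        raise GeometryError("echo volumes must share one grid")
    s1 = np.asarray(echo1.data, dtype=float)
    s2 = np.asarray(echo2.data, dtype=float)
    exclusion = np.zeros(s1.shape, dtype=np.uint8)
    exclusion[(s1 <= 0) | (s2 <= 0)] = ExclusionReason.NONPOSITIVE_SIGNAL
    nondecay = (exclusion == 0) & (s2 >= s1)
    exclusion[nondecay] = ExclusionReason.NONDECAYING

    qt2 = np.full(s1.shape, np.nan)
    ok = exclusion == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        qt2[ok] = (te2 - te1) / np.log(s1[ok] / s2[ok])
    over = ok & (qt2 > ceiling_ms)
    exclusion[over] = ExclusionReason.ABOVE_CEILING
    qt2[~(exclusion == 0)] = np.nan
    valid = exclusion == ExclusionReason.VALID
    return QT2Result(
        qt2_map=ImageVolume(qt2, echo1.affine.copy(), modality="qT2"),
        valid=valid,
        exclusion=exclusion,
        echo_times=(float(te1), float(te2)),
    )


def masked_qt2(result: QT2Result, seg: Segmentation,
               pv_threshold: float = 0.99,
               min_surviving_voxels: int = 10,
               transform: Transform | None = None) -> MaskedQT2:
    """qT2 means within a hippocampal segmentation, partial volume excluded.

    ``seg`` may live on any grid; it is resampled (linear) onto the qT2 grid
    through ``transform`` (segmentation world -> qT2 world; identity when
    both already share a world frame).  Voxels with resampled mask fraction
    below ``pv_threshold`` are partial-volume and excluded.  If fewer than
    ``min_surviving_voxels`` survive, the criterion falls back to the
    one-voxel interior erosion of the binarised resampled mask.
    Slices with no usable voxel are reported as missing (NaN), never zero.
    """
    if seg.n_voxels == 0:
        raise EmptyInputError("segmentation is empty")
    t = transform or Transform.identity()
    frac_vol = resample(seg.as_volume(), t, result.qt2_map, interp="linear", fill=0.0)
    frac = np.clip(frac_vol.data, 0.0, 1.0)
    inside = frac >= 0.5
    core = frac >= pv_threshold
    if core.sum() < min_surviving_voxels:
        core = ndimage.binary_erosion(inside)
    usable = core & result.valid
    if not usable.any():
        raise EmptyInputError("no valid non-partial-volume voxels inside the mask")

    qt2 = result.qt2_map.data
    axis, sign = ap_axis(result.qt2_map)
    n_slices = qt2.shape[axis]
    means = np.full(n_slices, np.nan)
    counts = np.zeros(n_slices, dtype=int)
    seg_vol = np.zeros(n_slices)
    vox_vol = float(np.prod(result.qt2_map.spacing))
    for k in range(n_slices):
        sl = [slice(None)] * 3
        sl[axis] = k
        sl = tuple(sl)
        use = usable[sl]
        counts[k] = int(use.sum())
        if counts[k]:
            means[k] = float(np.nanmean(qt2[sl][use]))
        seg_vol[k] = float(frac[sl][frac[sl] >= 0.5].sum()) * vox_vol
    occupied = np.nonzero(inside.sum(axis=tuple(i for i in range(3) if i != axis)))[0]
    return MaskedQT2(
        mean_ms=float(np.nanmean(qt2[usable])),
        slice_indices=occupied,
        slice_means_ms=means[occupied],
        slice_valid_counts=counts[occupied],
        slice_seg_volumes_mm3=seg_vol[occupied],
        n_voxels_used=int(usable.sum()),
        pv_excluded_count=int((inside & ~core).sum()),
    )
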