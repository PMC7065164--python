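"""Long-axis alignment: reorientation, registration, distance maps.

The profiling frame is defined by a template whose hippocampi run along
world +y (anterior-posterior).  This module provides:

* principal-axis extraction of a hippocampal mask (PCA of in-mask world
  coordinates) and the rigid reorientation that puts the mean long axis
  of the two hippocampi along +y;
* groupwise template construction by iterated registration to the evolving
  mean image;
* subject-to-template registration (rigid then full affine, normalized
  cross-correlation, cost function evaluated only outside the hippocampal
  exclusion mask so pathology cannot bias the alignment); a nonlinear
  refinement stage is a pluggable callable and defaults to none;
* the AP distance map (slice k, 1-based from the most posterior template
  slice, holds k x slice-spacing mm), its propagation into subject space,
  and per-slice mean distances over a segmentation;
* groupwise majority-vote masks.

Rigid/affine optimisation is delegated to SimpleITK's registration
framework configured for determinism (full sampling, fixed multi-resolution
schedule); transforms are exposed as plain 4x4 RAS+ world matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import SimpleITK as sitk
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

__all__ = [
    "AlignmentError",
    "AlignmentWarning",
    "DistanceMap",
    "SliceDistanceTable",
    "principal_axis",
    "reorient_to_ap",
    "register_subject",
    "build_group_template",
    "build_distance_map",
    "propagate_distance_map",
    "slice_distance_table",
    "majority_mask",
]


class AlignmentError(RuntimeError):
    """Registration or reorientation failed or produced unusable output."""


class AlignmentWarning(UserWarning):
    """Alignment produced a result that should be reviewed."""


# ---------------------------------------------------------------------------
# principal axis and reorientation

def principal_axis(seg: Segmentation) -> tuple[np.ndarray, np.ndarray]:
    """First principal axis of the in-mask world coordinates.

    Returns ``(axis, eigenvalues)`` with the axis sign fixed so its AP (y)
    component is nonnegative and eigenvalues sorted descending.  Raises for
    near-isotropic masks (first/second eigenvalue ratio < 1.2), where the
    long axis is not defined.
    """
    if seg.n_voxels < 10:
        raise EmptyInputError("need at least 10 in-mask voxels for a long axis")
    coords = seg.world_coordinates()
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] / max(evals[1], 1e-12) < 1.2:
        raise AlignmentError(
            f"mask is near-isotropic (eigenvalue ratio "
            f"{evals[0] / max(evals[1], 1e-12):.3f} < 1.2); long axis undefined"
        )
    axis = evecs[:, 0]
    if axis[1] < 0:
        axis = -axis
    return axis, evals


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix mapping unit vector ``a`` onto ``b``."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis perpendicular to a
        perp = np.eye(3)[np.argmin(np.abs(a))]
        perp = perp - a * np.dot(perp, a)
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def reorient_to_ap(volume: ImageVolume, seg_left: Segmentation,
                   seg_right: Segmentation) -> Transform:
    """Rigid transform rotating the mean hippocampal long axis onto +y.

    The rotation is the minimal one taking the mean of the two per-side
    principal axes to the AP axis, pivoted at the joint mask centroid so
    the hippocampi stay in the field of view.  For a left/right symmetric
    pair this rotation keeps the midsagittal plane fixed.
    """
    axis_l, _ = principal_axis(seg_left)
    axis_r, _ = principal_axis(seg_right)
    angle = np.rad2deg(np.arccos(np.clip(np.dot(axis_l, axis_r), -1.0, 1.0)))
    if angle > 45.0:
        raise AlignmentError(
            f"left/right long axes disagree by {angle:.1f} deg (> 45)"
        )
    mean_axis = axis_l + axis_r
    mean_axis /= np.linalg.norm(mean_axis)
    rot = _rotation_between(mean_axis, np.array([0.0, 1.0, 0.0]))
    centroid = np.concatenate(
        [seg_left.world_coordinates(), seg_right.world_coordinates()]
    ).mean(axis=0)
    translation = centroid - rot @ centroid
    return Transform.from_rotation_translation(rot, translation)


# ---------------------------------------------------------------------------
# SimpleITK bridge

def _to_sitk(volume: ImageVolume) -> sitk.Image:
    """ImageVolume -> sitk.Image whose physical space is the RAS+ world."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.asarray(volume.data, dtype=np.float64).transpose(2, 1, 0)))
    spacing = volume.spacing
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in volume.affine[:3, 3]))
    direction = volume.affine[:3, :3] / spacing
    img.SetDirection(tuple(direction.flatten(order="C")))
    return img


def _sitk_to_matrix(tx: sitk.Transform) -> np.ndarray:
    """Flatten an (affine-class) sitk transform to a 4x4 fixed->moving map."""
    tx = sitk.AffineTransform(sitk.CompositeTransform(tx).FlattenTransform()
                              .GetNthTransform(0)) \
        if isinstance(tx, sitk.CompositeTransform) else tx
    a = np.asarray(tx.GetMatrix(), dtype=float).reshape(3, 3)
    c = np.asarray(tx.GetCenter(), dtype=float)
    t = np.asarray(tx.GetTranslation(), dtype=float)
    m = np.eye(4)
    m[:3, :3] = a
    m[:3, 3] = c + t - a @ c
    return m


@dataclass
class RegistrationResult:
    transform: Transform          # subject world -> template world
    similarity: float             # negated NCC at the optimum (lower = better)
    stages: tuple[str, ...]


def _run_stage(fixed: sitk.Image, moving: sitk.Image,
               initial: sitk.Transform, fixed_mask: sitk.Image | None,
               mode: str, shrink: Sequence[int], smooth: Sequence[float],
               iterations: int) -> tuple[sitk.Transform, float]:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    if fixed_mask is not None:
        reg.SetMetricFixedMask(fixed_mask)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetMetricSamplingStrategy(reg.NONE)  # all voxels: deterministic
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-6, numberOfIterations=iterations,
        relaxationFactor=0.6)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink))
    reg.SetSmoothingSigmasPerLevel(list(smooth))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    centre = fixed.TransformContinuousIndexToPhysicalPoint(
        [(sz - 1) / 2.0 for sz in fixed.GetSize()])
    tx = sitk.Euler3DTransform() if mode == "rigid" else sitk.AffineTransform(3)
    tx.SetCenter(centre)
    composed = sitk.CompositeTransform(initial)
    reg.SetMovingInitialTransform(composed)
    reg.SetInitialTransform(tx, inPlace=True)
    out = reg.Execute(fixed, moving)
    final = sitk.CompositeTransform([composed, out])
    return final, float(reg.GetMetricValue())


def register_subject(subject_t1: ImageVolume, template: ImageVolume,
                     exclusion_mask: Segmentation | None = None,
                     do_affine: bool = True,
                     nonlinear: Callable[..., Transform] | None = None,
                     quality_threshold: float = -0.2,
                     iterations: int = 200) -> RegistrationResult:
    """Register a subject T1 to the template (rigid, then affine).

    The similarity (normalized cross-correlation) is evaluated only inside
    the template foreground *excluding* ``exclusion_mask`` (the template
    hippocampi), so hippocampal atrophy does not bias the alignment.
    Returns the transform mapping subject world coordinates into template
    world coordinates; its ``inverse()`` maps template to subject.

    ``nonlinear``, when given, is called as
    ``nonlinear(template, resampled_subject, cost_mask)`` and must return a
    Transform to compose on top; the default pipeline runs affine-only.
    """
    fixed = _to_sitk(template)
    moving = _to_sitk(subject_t1)
    # cost mask: brain plus a generous margin (the brain/background edge
    # carries most of the scale information), minus the hippocampi
    fg = np.asarray(template.data) > 0.05 * float(np.max(template.data))
    fg = ndimage.binary_dilation(fg, iterations=int(np.ceil(
        8.0 / float(min(template.spacing)))))
    if exclusion_mask is not None:
        fg = fg & ~exclusion_mask.binary
    mask_img = sitk.GetImageFromArray(
        fg.astype(np.uint8).transpose(2, 1, 0))
    mask_img.CopyInformation(fixed)

    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    center = sitk.Euler3DTransform(init).GetCenter()

    stages = ["rigid"]
    rigid_init = sitk.Euler3DTransform(init)
    tx, metric = _run_stage(fixed, moving, rigid_init, mask_img, "rigid",
                            shrink=[4, 2, 1], smooth=[2.0, 1.0, 0.0],
                            iterations=iterations)
    if do_affine:
        stages.append("affine")
        tx, metric = _run_stage(fixed, moving, tx, mask_img, "affine",
                                shrink=[4, 2, 1], smooth=[2.0, 1.0, 0.0],
                                iterations=iterations)
    if metric > quality_threshold:
        raise AlignmentError(
            f"registration quality too low (NCC metric {metric:.3f} > "
            f"{quality_threshold})"
        )
    # sitk transform maps fixed physical points -> moving physical points;
    # our convention is moving world -> fixed world, i.e. its inverse.
    flat = sitk.CompositeTransform(tx)
    flat.FlattenTransform()
    m = np.eye(4)
    for i in range(flat.GetNumberOfTransforms()):
        m = m @ _sitk_to_matrix(flat.GetNthTransform(i))
    forward = Transform(np.linalg.inv(m), kind="affine")
    if nonlinear is not None:
        stages.append("nonlinear")
        warped = resample(subject_t1, forward, template)
        cost_mask = Segmentation(fg.astype(float), template.affine.copy())
        extra = nonlinear(template, warped, cost_mask)
        forward = extra.compose(forward)
    return RegistrationResult(transform=forward, similarity=metric,
                              stages=tuple(stages))


# ---------------------------------------------------------------------------
# groupwise template

def build_group_template(t1s: Sequence[ImageVolume], n_affine: int = 10,
                         nonlinear: Callable[..., Transform] | None = None,
                         reference: ImageVolume | None = None,
                         iterations: int = 100
                         ) -> tuple[ImageVolume, list[Transform]]:
    """Iterative mean-image group template.

    Starting from the voxelwise mean on the reference grid (default: the
    first subject's grid), each iteration registers every subject
    (rigid + affine) to the current mean and re-averages.  Stops after
    ``n_affine`` iterations, or earlier with a warning if the mean
    similarity worsens on two consecutive iterations (best-so-far result
    is returned).  Deterministic given its inputs.
    """
    if len(t1s) < 2:
        raise EmptyInputError("template construction needs >= 2 subjects")
    ref = reference or t1s[0]
    transforms: list[Transform] = [Transform.identity("affine")
                                   for _ in t1s]
    template = ImageVolume(
        np.mean([resample(v, Transform.identity(), ref).data for v in t1s],
                axis=0),
        ref.affine.copy(), modality="T1")
    best = (np.inf, template, list(transforms))
    worse_streak = 0
    prev_metric = np.inf
    for it in range(max(1, n_affine)):
        metrics = []
        new_transforms = []
        warped = []
        for vol in t1s:
            res = register_subject(vol, template, exclusion_mask=None,
                                   do_affine=True, iterations=iterations)
            new_transforms.append(res.transform)
            metrics.append(res.similarity)
            warped.append(resample(vol, res.transform, template).data)
        template = ImageVolume(np.mean(warped, axis=0), template.affine.copy(),
                               modality="T1")
        transforms = new_transforms
        mean_metric = float(np.mean(metrics))
        if mean_metric < best[0]:
            best = (mean_metric, template, list(transforms))
        worse_streak = worse_streak + 1 if mean_metric > prev_metric else 0
        if worse_streak >= 2:
            warnings.warn("template registration similarity worsened on two "
                          "consecutive iterations; returning best-so-far",
                          AlignmentWarning)
            _, template, transforms = best
            break
        prev_metric = mean_metric
    if nonlinear is not None:
        # nonlinear refinement stage mirrors the affine loop via the plug-in
        warped = []
        for vol, t in zip(t1s, transforms):
            extra = nonlinear(template, resample(vol, t, template), None)
            warped.append(resample(vol, extra.compose(t), template).data)
        template = ImageVolume(np.mean(warped, axis=0), template.affine.copy(),
                               modality="T1")
    return template, transforms


# ---------------------------------------------------------------------------
# distance maps

@dataclass
class DistanceMap:
    """AP position (mm) per voxel; constant per coronal template slice."""

    volume: ImageVolume

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


@dataclass
class SliceDistanceTable:
    """Per subject-coronal-slice mean propagated AP distance."""

    slice_indices: np.ndarray     # voxel index along the subject's AP axis
    mean_distance_mm: np.ndarray  # ordered posterior -> anterior
    voxel_counts: np.ndarray

    def __post_init__(self) -> None:
        d = self.mean_distance_mm
        if len(d) > 1 and not np.all(np.diff(d) > 0):
            warnings.warn(
                "slice mean distances are not strictly increasing along the "
                "AP axis; alignment may have failed", AlignmentWarning)

    @property
    def is_monotone(self) -> bool:
        return len(self.mean_distance_mm) < 2 or bool(
            np.all(np.diff(self.mean_distance_mm) > 0))


def build_distance_map(template: ImageVolume) -> DistanceMap:
    """Distance map on an AP-aligned template.

    Coronal slice k (1-based, counting from the most posterior slice) takes
    the constant value ``k * slice_spacing`` mm; a 218-slice 1-mm template
    maps to 1..218 mm.
    """
    axis, sign = ap_axis(template)
    n = template.shape[axis]
    spacing = float(template.spacing[axis])
    ladder = (np.arange(1, n + 1) * spacing) if sign > 0 else \
             (np.arange(n, 0, -1) * spacing)
    shape = [1, 1, 1]
    shape[axis] = n
    data = np.broadcast_to(ladder.reshape(shape), template.shape).copy()
    return DistanceMap(ImageVolume(data, template.affine.copy(),
                                   modality="distance"))


def propagate_distance_map(dmap: DistanceMap, template_to_subject: Transform,
                           subject_grid: ImageVolume) -> ImageVolume:
    """Resample the template distance map into subject space (linear, NaN
    outside the field so downstream means ignore undefined voxels)."""
    return resample(dmap.volume, template_to_subject, subject_grid,
                    interp="linear", fill=np.nan)


def slice_distance_table(propagated: ImageVolume,
                         seg: Segmentation) -> SliceDistanceTable:
    """Average the propagated distances over the mask, slice by slice.

    Fractional (probabilistic) masks weight each voxel's distance by its
    mask fraction; for binary masks this is the plain in-mask mean.
    """
    if seg.data.sum() <= 0:
        raise EmptyInputError("segmentation is empty")
    if seg.data.shape != propagated.shape:
        raise GeometryError("segmentation and distance volume must share a grid")
    axis, sign = ap_axis(propagated)
    w = seg.data
    dist = propagated.data
    finite = np.isfinite(dist)
    outside_weight = float(w[~finite].sum())
    if outside_weight > 0.10 * float(w.sum()):
        warnings.warn(
            f"{outside_weight:.0f} of {w.sum():.0f} in-mask (weighted) voxels "
            "fall outside the propagated distance field", AlignmentWarning)
    rows = []
    order = range(propagated.shape[axis]) if sign > 0 else \
        range(propagated.shape[axis] - 1, -1, -1)
    for k in order:
        sl = [slice(None)] * 3
        sl[axis] = k
        wk = np.where(finite[tuple(sl)], w[tuple(sl)], 0.0)
        total = wk.sum()
        if total <= 1e-9:
            continue
        mean = float((np.where(finite[tuple(sl)], dist[tuple(sl)], 0.0)
                      * wk).sum() / total)
        rows.append((k, mean, float(total)))
    if not rows:
        raise EmptyInputError("no in-mask voxels with defined distances")
    idx, means, counts = zip(*rows)
    return SliceDistanceTable(np.asarray(idx), np.asarray(means),
                              np.asarray(counts))


# ---------------------------------------------------------------------------
# majority masks

def majority_mask(segs: Sequence[Segmentation],
                  threshold: float = 0.5) -> Segmentation:
    """Groupwise mask: voxels included in at least ``threshold`` of the
    individual segmentations (inclusive at exactly the threshold)."""
    if not segs:
        raise EmptyInputError("no segmentations given")
    ref = segs[0]
    for s in segs[1:]:
        if s.data.shape != ref.data.shape or not np.allclose(
                s.affine, ref.affine, atol=1e-5):
            raise GeometryError("all segmentations must share the template grid")
    frac = np.mean([s.binary for s in segs], axis=0)
    included = frac >= threshold - 1e-12
    return Segmentation(included.astype(float), ref.affine.copy(),
                        side=ref.side)
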