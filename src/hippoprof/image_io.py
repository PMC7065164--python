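"""Volumetric image containers, affine geometry, and NIfTI I/O.

All volumes live in a RAS+ world coordinate system in millimetres: +x is
subject-left-to-right, +y posterior-to-anterior, +z inferior-to-superior.
The anterior-posterior (AP) profiling axis used throughout the package is
world +y.  Files are reoriented to the closest RAS+ canonical orientation
on load, so downstream code can rely on voxel axis 1 running
posterior -> anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GeometryError",
    "UnsupportedInputError",
    "EmptyInputError",
    "ImageVolume",
    "Transform",
    "Segmentation",
    "load_volume",
    "save_volume",
    "resample",
    "voxel_volume",
    "ap_axis",
]

Modality = Literal["T1", "PD", "T2echo", "qT2", "distance", "mask"]


class GeometryError(ValueError):
    """Invalid or degenerate image geometry (affine, grid, transform)."""


class UnsupportedInputError(ValueError):
    """Input file or volume of a kind the pipeline does not handle."""


class EmptyInputError(ValueError):
    """An operation received an empty mask, list, or profile."""


@dataclass
class ImageVolume:
    """A 3-D scalar grid with a voxel-to-world affine (RAS+ mm).

    Parameters
    ----------
    data
        3-D array of voxel values.
    affine
        4x4 voxel-index -> world-mm map; last row must be (0, 0, 0, 1).
    modality
        Tag identifying what the voxels mean; purely informational.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: Modality = "T1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise UnsupportedInputError(
                f"expected a 3-D volume, got {self.data.ndim}-D"
            )
        _check_affine(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacings in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world coordinates (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world coordinates (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def like(self, data: np.ndarray, modality: Modality | None = None) -> "ImageVolume":
        """New volume with the same geometry but different voxel data."""
        return ImageVolume(data, self.affine.copy(), modality or self.modality)


def _check_affine(affine: np.ndarray) -> None:
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    if not np.allclose(affine[3], [0, 0, 0, 1]):
        raise GeometryError("affine last row must be (0, 0, 0, 1)")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine is not invertible")
    if np.any(np.linalg.norm(affine[:3, :3], axis=0) <= 0):
        raise GeometryError("voxel spacings must be strictly positive")


@dataclass(frozen=True)
class Transform:
    """A world-to-world spatial map, applied to points as ``y = M @ x``.

    ``matrix`` maps points from the *moving* (source) world frame into the
    *fixed* (target) world frame.  Composite transforms apply right-to-left:
    ``(A @ B)(x) == A(B(x))``.
    """

    matrix: np.ndarray
    kind: Literal["rigid", "affine", "composite"] = "affine"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        _check_affine(m)
        if self.kind == "rigid":
            r = m[:3, :3]
            if not (np.allclose(r @ r.T, np.eye(3), atol=1e-6)
                    and np.isclose(np.linalg.det(r), 1.0, atol=1e-6)):
                raise GeometryError("rigid transform must have a proper rotation block")

    @classmethod
    def identity(cls, kind: Literal["rigid", "affine"] = "rigid") -> "Transform":
        return cls(np.eye(4), kind=kind)

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation: Iterable[float] = (0.0, 0.0, 0.0)
    ) -> "Transform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = list(translation)
        kind = "rigid" if np.isclose(np.linalg.det(rotation), 1.0, atol=1e-6) else "affine"
        return cls(m, kind=kind)

    def inverse(self) -> "Transform":
        return Transform(np.linalg.inv(self.matrix), kind=self.kind)

    def compose(self, other: "Transform") -> "Transform":
        """Return ``self after other``: applies ``other`` first."""
        kind = "rigid" if self.kind == other.kind == "rigid" else "composite"
        return Transform(self.matrix @ other.matrix, kind=kind)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def rigid_part(self) -> "Transform":
        """Closest rigid transform (polar decomposition of the 3x3 block,
        translation kept).  Used to reorient masks without scaling them, so
        per-slice areas stay true cross-sections."""
        u, _, vt = np.linalg.svd(self.matrix[:3, :3])
        r = u @ vt
        if np.linalg.det(r) < 0:
            u = u.copy()
            u[:, -1] *= -1
            r = u @ vt
        return Transform.from_rotation_translation(r, self.matrix[:3, 3])


@dataclass
class Segmentation:
    """A (possibly fractional) hippocampus mask aligned to a reference grid.

    Values lie in [0, 1]; the binary view thresholds at 0.5 (the fixed
    binarization rule after any resampling).
    """

    data: np.ndarray
    affine: np.ndarray
    side: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise UnsupportedInputError("segmentation must be 3-D")
        _check_affine(self.affine)
        if self.data.size and (self.data.min() < -1e-6 or self.data.max() > 1 + 1e-6):
            raise ValueError("segmentation values must lie in [0, 1]")
        self.data = np.clip(self.data, 0.0, 1.0)

    @property
    def binary(self) -> np.ndarray:
        return self.data >= 0.5

    @property
    def n_voxels(self) -> int:
        return int(self.binary.sum())

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.data, self.affine, modality="mask")

    def world_coordinates(self) -> np.ndarray:
        """World coordinates (n, 3) of all binary-mask voxels."""
        idx = np.argwhere(self.binary)
        if idx.size == 0:
            raise EmptyInputError("segmentation is empty")
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def load_volume(path: str | Path, modality: Modality = "T1") -> ImageVolume:
    """Load a NIfTI volume and reorient it to canonical RAS+.

    4-D files are accepted only when the trailing axis is a singleton.
    """
    img = nib.load(str(path))
    if img.ndim == 4:
        if img.shape[3] != 1:
            raise UnsupportedInputError(
                f"{path}: 4-D multi-frame images are not supported"
            )
        img = img.slicer[..., 0]
    elif img.ndim != 3:
        raise UnsupportedInputError(f"{path}: expected a 3-D image, got {img.ndim}-D")
    img = nib.as_closest_canonical(img)
    affine = np.asarray(img.affine, dtype=float)
    _check_affine(affine)
    data = np.asarray(img.dataobj, dtype=np.float64)
    return ImageVolume(data, affine, modality)


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                             volume.affine), str(path))


def load_segmentation(path: str | Path, side: Literal["left", "right"]) -> Segmentation:
    vol = load_volume(path, modality="mask")
    return Segmentation(vol.data, vol.affine, side=side)


def save_segmentation(seg: Segmentation, path: str | Path) -> None:
    save_volume(seg.as_volume(), path)


def resample(
    volume: ImageVolume,
    transform: Transform,
    reference: ImageVolume,
    interp: Literal["nearest", "linear"] = "linear",
    fill: float = 0.0,
) -> ImageVolume:
    """Resample ``volume`` onto ``reference``'s grid through ``transform``.

    ``transform`` maps the moving volume's world frame into the reference
    world frame; sampling pulls values through its inverse.  Out-of-field
    voxels get ``fill`` (convention: 0 for masks, NaN for qT2/distance maps
    so that downstream averages ignore them).
    """
    if min(reference.shape) < 1:
        raise GeometryError("degenerate reference grid")
    order = {"nearest": 0, "linear": 1}[interp]
    # reference voxel -> reference world -> moving world -> moving voxel
    m = (
        np.linalg.inv(volume.affine)
        @ np.linalg.inv(transform.matrix)
        @ reference.affine
    )
    out = ndimage.affine_transform(
        np.asarray(volume.data, dtype=float),
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=fill,
        prefilter=False,
    )
    return ImageVolume(out, reference.affine.copy(), volume.modality)


def resample_segmentation(
    seg: Segmentation,
    transform: Transform,
    reference: ImageVolume,
    interp: Literal["nearest", "linear"] = "nearest",
) -> Segmentation:
    vol = resample(seg.as_volume(), transform, reference, interp=interp, fill=0.0)
    return Segmentation(np.clip(vol.data, 0.0, 1.0), vol.affine, side=seg.side)


def voxel_volume(volume: ImageVolume) -> float:
    """Volume of one voxel in mm^3 (product of the three spacings)."""
    return float(np.prod(volume.spacing))


def ap_axis(volume: ImageVolume) -> tuple[int, int]:
    """Voxel axis most aligned with world +y and its direction sign.

    Returns ``(axis, sign)`` where stepping ``sign`` along ``axis`` moves
    anteriorly.  For canonical RAS+ volumes this is ``(1, +1)``.
    """
    directions = volume.affine[:3, :3] / volume.spacing
    y_components = directions[1]
    axis = int(np.argmax(np.abs(y_components)))
    sign = 1 if y_components[axis] >= 0 else -1
    return axis, sign


def in_plane_area(volume: ImageVolume) -> float:
    """Area in mm^2 of one voxel face within a coronal (AP-normal) slice."""
    axis, _ = ap_axis(volume)
    spacings = [s for i, s in enumerate(volume.spacing) if i != axis]
    return float(spacings[0] * spacings[1])
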