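"""Synthetic hippocampus phantom: masks, dual-echo signals, cohorts.

The phantom emulates the measurement setup the pipeline targets: a 1-mm
isotropic T1-like volume carrying bilateral hippocampus-shaped binary
masks, and a coronal dual-echo pair (0.43 x 0.43 mm in-plane, 4-mm slices,
TE = 30/119 ms) with mono-exponential T2 decay.  Each hippocampus is an
elongated curved tube whose per-coronal-slice cross-sectional area (CSA)
follows a parametric anterior-posterior profile: a tapering tail, a stable
body (|slope| < 2 mm^2/mm by construction), and a bulging then tapering
head.  Focal lesions (partial atrophy and/or a T2 increase over a short AP
band) can be implanted with known location, and a population generator adds
between-subject CSA scale, tissue-T2, and intracranial-volume variability
plus random rigid poses.

Every quantity the generator randomises is derived from a single integer
seed; identical spec + seed reproduce outputs bit for bit.  Ground truth
(per-slice CSA before posing, tissue T2, lesion band, TIV, pose) is
retained on every subject so downstream estimates can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .image_io import (
    EmptyInputError,
    GeometryError,
    ImageVolume,
    Segmentation,
    Transform,
    save_segmentation,
    save_volume,
)

__all__ = [
    "CSAProfileSpec",
    "Lesion",
    "RigidPose",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomSubject",
    "default_t1_grid",
    "default_dual_echo_grid",
    "make_mask",
    "make_t1_like",
    "make_dual_echo",
    "make_subject",
    "make_population",
    "write_subject",
]

# Acquisition geometry the phantom mimics (mm / ms)
T1_SPACING = (1.0, 1.0, 1.0)
DUAL_ECHO_SPACING = (0.43, 4.0, 0.43)  # RAS (x, y=slice, z); coronal 4-mm slices
DEFAULT_TE = (30.0, 119.0)


@dataclass(frozen=True)
class CSAProfileSpec:
    """Piecewise AP profile of cross-sectional area, posterior (0) to anterior.

    Tail: linear taper up from ``csa_tip`` to the body plateau.
    Body: near-constant plateau with a small linear drift (stable region).
    Head: raised-cosine bulge up to ``csa_peak`` then taper to ``csa_tip``.

    Default lengths (tail 8, body 15, head 24 mm) and areas put the
    integrated one-sided volume near 2.7 mL, inside the healthy-control
    whole-hippocampus range used for calibration (2.40-3.39 mL).
    """

    tail_mm: float = 8.0
    body_mm: float = 15.0
    head_mm: float = 24.0
    csa_tip: float = 4.0      # mm^2 at the extreme ends
    csa_body: float = 60.0    # mm^2 plateau
    body_drift: float = 0.5   # mm^2 change across the body (slope << 2 mm^2/mm)
    csa_peak: float = 110.0   # mm^2 at the widest point of the head
    head_peak_frac: float = 0.3  # position of the peak within the head segment

    @property
    def length_mm(self) -> float:
        return self.tail_mm + self.body_mm + self.head_mm

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """CSA in mm^2 at AP position ``x`` mm from the posterior end."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        L = self.length_mm
        t0, t1 = 0.0, self.tail_mm
        b1 = t1 + self.body_mm
        peak = b1 + self.head_peak_frac * self.head_mm

        in_tail = (x >= t0) & (x < t1)
        out[in_tail] = self.csa_tip + (self.csa_body - self.csa_tip) * (
            (x[in_tail] - t0) / max(self.tail_mm, 1e-9)
        )
        in_body = (x >= t1) & (x < b1)
        out[in_body] = self.csa_body + self.body_drift * (
            (x[in_body] - t1) / max(self.body_mm, 1e-9)
        )
        body_end = self.csa_body + self.body_drift
        in_rise = (x >= b1) & (x < peak)
        u = (x[in_rise] - b1) / max(peak - b1, 1e-9)
        out[in_rise] = body_end + (self.csa_peak - body_end) * 0.5 * (1 - np.cos(np.pi * u))
        in_fall = (x >= peak) & (x <= L)
        v = (x[in_fall] - peak) / max(L - peak, 1e-9)
        out[in_fall] = self.csa_tip + (self.csa_peak - self.csa_tip) * 0.5 * (
            1 + np.cos(np.pi * v)
        )
        return out


@dataclass(frozen=True)
class Lesion:
    """Focal abnormality over an AP band: fractional atrophy and/or qT2 shift."""

    center_mm: float
    extent_mm: float
    atrophy_fraction: float = 0.0  # 0 = intact, 1 = complete loss of CSA
    delta_t2_ms: float = 0.0
    side: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        if not 0.0 <= self.atrophy_fraction <= 1.0:
            raise ValueError("atrophy_fraction must lie in [0, 1]")
        if self.extent_mm <= 0:
            raise ValueError("lesion extent must be positive")

    def band(self) -> tuple[float, float]:
        return (self.center_mm - self.extent_mm / 2.0,
                self.center_mm + self.extent_mm / 2.0)


@dataclass(frozen=True)
class RigidPose:
    """Rigid subject pose: intrinsic rotations (deg, about x, y, z) + shift."""

    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def transform(self) -> Transform:
        """World-to-world transform taking canonical coordinates to posed ones."""
        ax, ay, az = np.deg2rad(self.angles_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Transform.from_rotation_translation(rz @ ry @ rx, self.translation_mm)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameter set for one synthetic subject.

    Tissue T2 defaults near the middle of the healthy-control hippocampal
    band (108.5-123.8 ms); background T2 is white-matter-like.  Echo times
    default to the dual-echo acquisition (30/119 ms).
    """

    csa_profile: CSAProfileSpec = field(default_factory=CSAProfileSpec)
    shape: Literal["hippocampus", "ellipsoid"] = "hippocampus"
    ellipsoid_semi_axes: tuple[float, float, float] = (25.0, 10.0, 8.0)  # (AP, x, z)
    lateral_offset_mm: float = 14.0  # midline to each hippocampus centre
    arc_sagitta_mm: float = 6.0      # depth of the sagittal-plane centreline arc
    t2_tissue: float = 116.0         # ms
    t2_background: float = 80.0      # ms
    s0: float = 1000.0               # proton-density signal scale
    noise_sd: float = 10.0           # additive Gaussian noise on echo signals
    t1_noise_sd: float = 10.0        # additive noise on the T1-like volume
    echo_times: tuple[float, float] = DEFAULT_TE
    tiv_ml: float = 1500.0
    pose: RigidPose = field(default_factory=RigidPose)
    lesion: Lesion | None = None
    antialias: int = 4  # in-plane subsamples per voxel edge when rasterising
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t2_tissue <= 0 or self.t2_background <= 0:
            raise ValueError("T2 values must be positive")
        if self.noise_sd < 0 or self.t1_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        te1, te2 = self.echo_times
        if not 0 < te1 < te2:
            raise ValueError("echo times must satisfy TE2 > TE1 > 0")

    @property
    def length_mm(self) -> float:
        if self.shape == "ellipsoid":
            return 2.0 * self.ellipsoid_semi_axes[0]
        return self.csa_profile.length_mm


@dataclass
class PhantomTruth:
    """Ground truth retained per subject for oracle comparisons."""

    csa: dict  # side -> (positions_mm array, csa_mm2 array), pre-pose discretised
    t2_tissue: float
    tiv_ml: float
    pose: RigidPose
    lesion: Lesion | None
    seed: int

    def csa_profile(self, side: str) -> tuple[np.ndarray, np.ndarray]:
        pos, val = self.csa[side]
        return np.asarray(pos), np.asarray(val)


@dataclass
class PhantomSubject:
    subject_id: str
    t1_like: ImageVolume
    echo1: ImageVolume | None
    echo2: ImageVolume | None
    mask_left: Segmentation
    mask_right: Segmentation
    truth: PhantomTruth
    spec: PhantomSpec

    def mask(self, side: str) -> Segmentation:
        return self.mask_left if side == "left" else self.mask_right


def default_t1_grid(shape: tuple[int, int, int] = (72, 96, 72)) -> ImageVolume:
    """Empty 1-mm isotropic RAS+ grid centred on the world origin."""
    affine = np.eye(4)
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0
    return ImageVolume(np.zeros(shape), affine, modality="T1")


def default_dual_echo_grid() -> ImageVolume:
    """Empty coronal dual-echo grid: 0.43 x 0.43 mm in-plane, 4-mm slices."""
    spacing = np.asarray(DUAL_ECHO_SPACING)
    shape = (112, 16, 74)
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = -spacing * (np.asarray(shape) - 1) / 2.0
    return ImageVolume(np.zeros(shape), affine, modality="PD")


def _canonical_coords(grid: ImageVolume, pose: RigidPose) -> tuple[np.ndarray, ...]:
    """World coordinates of every grid voxel mapped back to the canonical
    (unposed) phantom frame."""
    idx = np.indices(grid.shape, dtype=float)
    ijk = np.stack([a.ravel() for a in idx], axis=1)
    world = grid.index_to_world(ijk)
    inv = pose.transform().inverse()
    canon = inv.apply(world)
    x, y, z = (canon[:, k].reshape(grid.shape) for k in range(3))
    return x, y, z


def _membership(spec: PhantomSpec, side: str,
                x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Boolean membership of canonical-frame coordinates in one hippocampus."""
    xc = -spec.lateral_offset_mm if side == "left" else spec.lateral_offset_mm
    L = spec.length_mm
    u = y + L / 2.0  # AP position, 0 at the posterior tip
    if spec.shape == "ellipsoid":
        a_ap, a_x, a_z = spec.ellipsoid_semi_axes
        return ((x - xc) ** 2 / a_x**2 + (y) ** 2 / a_ap**2 + z**2 / a_z**2) <= 1.0
    csa = spec.csa_profile(np.clip(u, 0.0, L))
    if spec.lesion is not None and spec.lesion.side == side and spec.lesion.atrophy_fraction > 0:
        lo, hi = spec.lesion.band()
        in_band = (u >= lo) & (u <= hi)
        csa = np.where(in_band, csa * (1.0 - spec.lesion.atrophy_fraction), csa)
    # mild circular arc of the centreline in the sagittal (y-z) plane
    s = spec.arc_sagitta_mm
    half = L / 2.0
    radius = (half**2 + s**2) / (2.0 * s) if s > 0 else np.inf
    if s > 0:
        under = np.clip(radius**2 - (u - half) ** 2, 0.0, None)
        zc = np.sqrt(under) - (radius - s)
    else:
        zc = np.zeros_like(u)
    r2 = csa / np.pi
    inside = ((u >= 0) & (u <= L)
              & ((x - xc) ** 2 + (z - zc) ** 2 <= r2))
    return inside


def _rasterise(spec: PhantomSpec, side: str, grid: ImageVolume,
               pose: RigidPose) -> np.ndarray:
    """Fractional in-plane-supersampled rasterisation of one hippocampus.

    Each voxel's value is the fraction of ``antialias**2`` in-plane
    subsample points (at the voxel's coronal-slice centre plane) lying
    inside the shape; this anti-aliasing keeps per-slice fractional areas
    within a fraction of a mm^2 of the analytic cross-section, where pure
    voxel-centre counting aliases by several mm^2.
    """
    x, y, z = _canonical_coords(grid, pose)
    n = max(1, int(spec.antialias))
    if n == 1:
        return _membership(spec, side, x, y, z).astype(float)
    offs = (np.arange(n) + 0.5) / n - 0.5
    inv_rot = np.linalg.inv(pose.transform().matrix)[:3, :3]
    col_x = inv_rot @ grid.affine[:3, 0]  # in-plane grid axes in canonical frame
    col_z = inv_rot @ grid.affine[:3, 2]
    frac = np.zeros(grid.shape)
    for du in offs:
        for dw in offs:
            s = du * col_x + dw * col_z
            frac += _membership(spec, side, x + s[0], y + s[1], z + s[2])
    return frac / (n * n)


def make_mask(spec: PhantomSpec, grid: ImageVolume, side: str = "left",
              posed: bool = True) -> tuple[Segmentation, np.ndarray, np.ndarray]:
    """Rasterise one hippocampus mask onto ``grid``.

    Returns ``(segmentation, positions_mm, truth_csa_mm2)`` where the truth
    profile is the per-coronal-slice fractional in-mask sum times the
    in-plane voxel area of the *unposed* rasterisation (the quantity a
    perfect downstream pipeline should recover), at the AP position of each
    occupied slice.  For a binary mask the fractional sum is the voxel count.
    """
    if spec.shape == "hippocampus" and spec.length_mm > grid.shape[1] * grid.spacing[1]:
        raise GeometryError("phantom extent exceeds the grid's AP field of view")
    pose = spec.pose if posed else RigidPose()
    frac = _rasterise(spec, side, grid, pose)
    if not frac.any():
        raise GeometryError("phantom mask fell entirely outside the grid")
    seg = Segmentation(frac, grid.affine.copy(), side=side)

    # truth from the canonical (identity-pose) rasterisation on the same grid
    if posed and spec.pose != RigidPose():
        frac0 = _rasterise(spec, side, grid, RigidPose())
    else:
        frac0 = frac
    counts = frac0.sum(axis=(0, 2))
    occupied = np.nonzero(counts)[0]
    in_plane = float(grid.spacing[0] * grid.spacing[2])
    # slice centre AP coordinate relative to the posterior tip of the phantom
    slice_y = grid.index_to_world(
        np.stack([np.zeros_like(occupied), occupied, np.zeros_like(occupied)], axis=1)
    )[:, 1]
    positions = slice_y + spec.length_mm / 2.0
    return seg, positions, counts[occupied] * in_plane


def _t2_field(spec: PhantomSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray,
              t2_tissue: float) -> np.ndarray:
    t2 = np.full(x.shape, spec.t2_background)
    for side in ("left", "right"):
        inside = _membership(spec, side, x, y, z)
        t2[inside] = t2_tissue
        if (spec.lesion is not None and spec.lesion.side == side
                and spec.lesion.delta_t2_ms != 0.0):
            lo, hi = spec.lesion.band()
            u = y + spec.length_mm / 2.0
            t2[inside & (u >= lo) & (u <= hi)] += spec.lesion.delta_t2_ms
    return t2


def make_dual_echo(spec: PhantomSpec, grid: ImageVolume | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[ImageVolume, ImageVolume]:
    """Simulate the coronal dual-echo pair S(TE) = S0 exp(-TE/T2) + noise.

    Noise is additive Gaussian on the magnitude signal (sd = ``noise_sd``),
    a deliberate simplification of Rician noise adequate at the simulated
    SNR; both echoes get independent noise.
    """
    te1, te2 = spec.echo_times
    grid = grid or default_dual_echo_grid()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    x, y, z = _canonical_coords(grid, spec.pose)
    t2 = _t2_field(spec, x, y, z, spec.t2_tissue)
    echoes = []
    for te, tag in ((te1, "PD"), (te2, "T2echo")):
        signal = spec.s0 * np.exp(-te / t2)
        if spec.noise_sd > 0:
            signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
        echoes.append(ImageVolume(signal, grid.affine.copy(), modality=tag))
    return echoes[0], echoes[1]


def make_t1_like(spec: PhantomSpec, grid: ImageVolume,
                 rng: np.random.Generator | None = None) -> ImageVolume:
    """T1-like structural volume: textured brain ellipsoid with darker
    hippocampi, so that intensity-based registration has features to lock
    onto outside the hippocampal masks."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    x, y, z = _canonical_coords(grid, spec.pose)
    extent = (np.asarray(grid.shape) * grid.spacing) / 2.0
    a = extent * np.array([0.85, 0.9, 0.85])
    brain = (x / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2 <= 1.0
    # fixed smooth texture (same for every subject) gives registration
    # landmarks; phases are constants, not draws
    tex = (np.cos(2 * np.pi * x / 37.0 + 0.7)
           + np.cos(2 * np.pi * y / 29.0 + 1.9)
           + np.cos(2 * np.pi * z / 41.0 + 0.3)
           + np.cos(2 * np.pi * (x + y) / 53.0)
           + np.cos(2 * np.pi * (y - z) / 47.0))
    data = np.where(brain, 1000.0 + 60.0 * tex, 0.0)
    for side in ("left", "right"):
        data[_membership(spec, side, x, y, z)] = 700.0
    if spec.t1_noise_sd > 0:
        data = data + rng.normal(0.0, spec.t1_noise_sd, size=data.shape)
    return ImageVolume(data, grid.affine.copy(), modality="T1")


def make_subject(spec: PhantomSpec, subject_id: str = "phantom",
                 t1_grid: ImageVolume | None = None,
                 dual_echo_grid: ImageVolume | None = None,
                 with_images: bool = True) -> PhantomSubject:
    """Generate one complete phantom subject from a spec.

    With ``with_images=False`` only masks + ground truth are produced
    (sufficient for profile-level studies; much faster for large cohorts).
    """
    t1_grid = t1_grid or default_t1_grid()
    rng = np.random.default_rng(spec.seed)
    truth_csa: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    masks = {}
    for side in ("left", "right"):
        seg, pos, csa = make_mask(spec, t1_grid, side=side)
        masks[side] = seg
        truth_csa[side] = (pos, csa)
    if with_images:
        t1 = make_t1_like(spec, t1_grid, rng)
        e1, e2 = make_dual_echo(spec, dual_echo_grid, rng)
    else:
        t1 = ImageVolume(np.zeros(t1_grid.shape), t1_grid.affine.copy(), "T1")
        e1 = e2 = None
    truth = PhantomTruth(csa=truth_csa, t2_tissue=spec.t2_tissue,
                         tiv_ml=spec.tiv_ml, pose=spec.pose,
                         lesion=spec.lesion, seed=spec.seed)
    return PhantomSubject(subject_id, t1, e1, e2,
                          masks["left"], masks["right"], truth, spec)


@dataclass(frozen=True)
class PopulationVariability:
    """Between-subject variability of the simulated healthy cohort.

    Defaults keep whole-hippocampus volumes and tissue T2 inside the
    healthy-control calibration bands (2.40-3.39 mL; 108.5-123.8 ms).
    """

    csa_scale_sd: float = 0.05   # multiplicative CSA scale, mean 1
    t2_sd: float = 3.0           # ms, additive tissue-T2 offset
    tiv_sd: float = 120.0        # mL
    max_rotation_deg: float = 12.0
    max_translation_mm: float = 5.0


def make_population(n: int, spec_template: PhantomSpec | None = None,
                    variability: PopulationVariability | None = None,
                    seed: int = 0, with_images: bool = True,
                    id_prefix: str = "sub") -> list[PhantomSubject]:
    """Draw ``n`` independent phantom subjects around a template spec."""
    if n < 2:
        raise ValueError("a population needs n >= 2 subjects")
    spec_template = spec_template or PhantomSpec()
    var = variability or PopulationVariability()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        scale = max(0.1, 1.0 + rng.normal(0.0, var.csa_scale_sd))
        base = spec_template.csa_profile
        prof = replace(
            base,
            csa_tip=base.csa_tip * scale,
            csa_body=base.csa_body * scale,
            body_drift=base.body_drift * scale,
            csa_peak=base.csa_peak * scale,
        )
        t2 = spec_template.t2_tissue + rng.normal(0.0, var.t2_sd)
        tiv = max(800.0, spec_template.tiv_ml + rng.normal(0.0, var.tiv_sd))
        angles = tuple(rng.uniform(-var.max_rotation_deg, var.max_rotation_deg, 3))
        shifts = tuple(rng.uniform(-var.max_translation_mm, var.max_translation_mm, 3))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(spec_template, csa_profile=prof, t2_tissue=t2,
                       tiv_ml=tiv, pose=RigidPose(angles, shifts), seed=sub_seed)
        subjects.append(make_subject(spec, subject_id=f"{id_prefix}{i:03d}",
                                     with_images=with_images))
    return subjects


def write_subject(subject: PhantomSubject, out_dir: str | Path) -> Path:
    """Write one subject's volumes and a truth JSON under ``out_dir``."""
    out = Path(out_dir) / subject.subject_id
    out.mkdir(parents=True, exist_ok=True)
    save_volume(subject.t1_like, out / "t1.nii.gz")
    if subject.echo1 is not None and subject.echo2 is not None:
        save_volume(subject.echo1, out / "echo1.nii.gz")
        save_volume(subject.echo2, out / "echo2.nii.gz")
    save_segmentation(subject.mask_left, out / "mask_left.nii.gz")
    save_segmentation(subject.mask_right, out / "mask_right.nii.gz")
    truth = subject.truth
    payload = {
        "subject_id": subject.subject_id,
        "tiv_ml": truth.tiv_ml,
        "t2_tissue_ms": truth.t2_tissue,
        "seed": truth.seed,
        "pose": {"angles_deg": list(truth.pose.angles_deg),
                 "translation_mm": list(truth.pose.translation_mm)},
        "lesion": asdict(truth.lesion) if truth.lesion else None,
        "echo_times_ms": list(subject.spec.echo_times),
        "csa": {side: {"positions_mm": np.asarray(p).tolist(),
                       "csa_mm2": np.asarray(c).tolist()}
                for side, (p, c) in truth.csa.items()},
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
    return out
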