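"""End-to-end profiling pipeline.

Stages mirror the processing chain the package implements:

1. group-template construction from the healthy controls (PCA long-axis
   reorientation, then iterated affine registration to the evolving mean),
   with groupwise majority hippocampal masks and the AP distance map;
2. registration of every subject to the template with the hippocampi
   excluded from the similarity (cost-function masking), and propagation
   of the distance map into subject T1 and dual-echo spaces;
3. normative database: kernel mu/sigma of the control CSA and qT2 profiles
   at 1-mm steps;
4. patient-group average profiles;
5. individual comparison against the normative range, region partitioning
   and metrics, pointwise group tests, per-point percent-abnormal maps.

The pipeline is deterministic: identical inputs and configuration yield
byte-identical CSV/JSON outputs, recorded in a manifest with input
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import alignment, normstats, profiling, relaxometry
from .image_io import (
    EmptyInputError,
    ImageVolume,
    Segmentation,
    Transform,
    load_segmentation,
    load_volume,
    resample,
    resample_segmentation,
)
from .phantom import PhantomSubject

log = logging.getLogger("hippoprof")

SIDES = ("left", "right")


@dataclass
class PipelineConfig:
    """All tunable constants of a profiling run."""

    echo_times: tuple[float, float] = (30.0, 119.0)  # ms
    z: float = 1.96
    grid_step: float = 1.0            # mm
    slope_threshold: float = 2.0      # mm^2/mm body-stability rule
    alpha: float = 0.01
    bandwidth: float = 2.0            # mm kernel bandwidth
    tiv_ref_ml: float | None = None   # default: control-cohort mean TIV
    n_affine: int = 10
    registration_iterations: int = 100
    min_qt2_voxels: int = 5
    pv_threshold: float = 0.99
    min_profiles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("z", "grid_step", "slope_threshold", "alpha", "bandwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


@dataclass
class SubjectData:
    """One subject's inputs, in memory."""

    subject_id: str
    t1: ImageVolume
    mask_left: Segmentation
    mask_right: Segmentation
    tiv_ml: float
    echo1: ImageVolume | None = None
    echo2: ImageVolume | None = None
    group: str = "control"            # "control" or a patient-group label

    @classmethod
    def from_phantom(cls, subject: PhantomSubject, group: str = "control"
                     ) -> "SubjectData":
        return cls(subject_id=subject.subject_id, t1=subject.t1_like,
                   mask_left=subject.mask_left, mask_right=subject.mask_right,
                   tiv_ml=subject.truth.tiv_ml, echo1=subject.echo1,
                   echo2=subject.echo2, group=group)

    @classmethod
    def from_directory(cls, path: str | Path, tiv_ml: float,
                       group: str = "control") -> "SubjectData":
        """Load ``t1.nii(.gz)``, ``mask_left``/``mask_right`` and optional
        ``echo1``/``echo2`` NIfTIs from one subject directory."""
        path = Path(path)

        def find(stem):
            for suffix in (".nii.gz", ".nii"):
                p = path / f"{stem}{suffix}"
                if p.exists():
                    return p
            return None

        t1 = load_volume(find("t1"), "T1")
        e1p, e2p = find("echo1"), find("echo2")
        return cls(
            subject_id=path.name,
            t1=t1,
            mask_left=load_segmentation(find("mask_left"), "left"),
            mask_right=load_segmentation(find("mask_right"), "right"),
            tiv_ml=tiv_ml,
            echo1=load_volume(e1p, "PD") if e1p else None,
            echo2=load_volume(e2p, "T2echo") if e2p else None,
            group=group,
        )


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    transform: Transform                       # subject world -> template world
    csa: dict[str, profiling.Profile]
    qt2: dict[str, profiling.Profile | None]
    qt2_slice_volumes: dict[str, np.ndarray | None]
    metrics: dict[str, profiling.SubjectMetrics] = field(default_factory=dict)
    reports: dict[str, dict[str, normstats.AbnormalityReport]] = field(
        default_factory=dict)
    error: str | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    template: ImageVolume
    template_masks: dict[str, Segmentation]
    distance_map: alignment.DistanceMap
    tiv_ref_ml: float
    subjects: dict[str, SubjectResult]
    normative: dict[tuple[str, str], normstats.NormativeModel]
    group_models: dict[tuple[str, str, str], normstats.NormativeModel]
    pointwise: dict[tuple[str, str, str], normstats.PointwiseTestResult]
    partitions: dict[str, profiling.RegionPartition]
    percent_abnormal: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]]
    failures: dict[str, str]


def _reorient(sub: SubjectData) -> Transform:
    return alignment.reorient_to_ap(sub.t1, sub.mask_left, sub.mask_right)


def build_template_stage(controls: Sequence[SubjectData],
                         config: PipelineConfig,
                         reference: ImageVolume | None = None):
    """Stage 1: reorient controls, build the mean template, groupwise masks
    and the distance map."""
    reoriented, reorients = [], []
    ref = reference or controls[0].t1
    for sub in controls:
        r = _reorient(sub)
        reorients.append(r)
        reoriented.append(resample(sub.t1, r, ref))
    template, transforms = alignment.build_group_template(
        reoriented, n_affine=config.n_affine,
        iterations=config.registration_iterations, reference=ref)
    full = [t.compose(r) for t, r in zip(transforms, reorients)]
    masks = {}
    for side in SIDES:
        segs = [
            resample_segmentation(getattr(s, f"mask_{side}"), t, template,
                                  interp="linear")
            for s, t in zip(controls, full)
        ]
        masks[side] = alignment.majority_mask(segs, threshold=0.5)
    dmap = alignment.build_distance_map(template)
    return template, masks, dmap, full


def _exclusion_mask(masks: dict[str, Segmentation]) -> Segmentation:
    both = np.maximum(masks["left"].data, masks["right"].data)
    return Segmentation(both, masks["left"].affine.copy(), side="left")


def csa_via_template(seg: Segmentation, transform: Transform,
                     dmap: alignment.DistanceMap, template: ImageVolume,
                     tiv_ml: float, tiv_ref_ml: float,
                     subject_id: str = "", grid_step: float = 1.0
                     ) -> profiling.Profile:
    """CSA profile of a subject mask through a subject->template transform.

    The mask is resampled through the *rigid part* of the transform onto
    the AP-aligned template grid (rigid reorientation preserves areas, so
    per-slice sums remain true cross-sections), while AP positions come
    from the distance map propagated through the residual affine — exactly
    the template-to-subject location mapping.
    """
    t_rigid = transform.rigid_part()
    mask_r = resample_segmentation(seg, t_rigid, template, interp="linear")
    residual = transform.compose(t_rigid.inverse())  # reoriented -> template
    prop = alignment.propagate_distance_map(dmap, residual.inverse(), template)
    table = alignment.slice_distance_table(prop, mask_r)
    return profiling.csa_profile(mask_r, table, tiv_ml, tiv_ref_ml,
                                 subject_id=subject_id, grid_step=grid_step)


def profile_subject(sub: SubjectData, template: ImageVolume,
                    exclusion: Segmentation, dmap: alignment.DistanceMap,
                    tiv_ref_ml: float, config: PipelineConfig,
                    transform: Transform | None = None) -> SubjectResult:
    """Stage 2 for one subject: register, propagate distances, profile."""
    if transform is None:
        r = _reorient(sub)
        t1_reor = resample(sub.t1, r, template)
        reg = alignment.register_subject(
            t1_reor, template, exclusion_mask=exclusion,
            iterations=config.registration_iterations)
        transform = reg.transform.compose(r)
    inv = transform.inverse()
    csa, qt2, qvols = {}, {}, {}
    qt2_result = None
    if sub.echo1 is not None and sub.echo2 is not None:
        qt2_result = relaxometry.fit_qt2(sub.echo1, sub.echo2,
                                         *config.echo_times)
        prop_de = alignment.propagate_distance_map(dmap, inv, sub.echo1)
    for side in SIDES:
        seg = getattr(sub, f"mask_{side}")
        csa[side] = csa_via_template(seg, transform, dmap, template,
                                     sub.tiv_ml, tiv_ref_ml,
                                     subject_id=sub.subject_id,
                                     grid_step=config.grid_step)
        qt2[side] = None
        qvols[side] = None
        if qt2_result is not None:
            try:
                summary = relaxometry.masked_qt2(
                    qt2_result, seg, pv_threshold=config.pv_threshold)
                seg_de = resample_segmentation(seg, Transform.identity(),
                                               sub.echo1, interp="linear")
                table_de = alignment.slice_distance_table(prop_de, seg_de)
                qt2[side], qvols[side] = profiling.qt2_profile(
                    summary, table_de, side=side, subject_id=sub.subject_id,
                    min_valid_voxels=config.min_qt2_voxels)
            except EmptyInputError as exc:
                log.warning("%s %s: no usable qT2 (%s)", sub.subject_id,
                            side, exc)
    return SubjectResult(subject_id=sub.subject_id, group=sub.group,
                         transform=transform, csa=csa, qt2=qt2,
                         qt2_slice_volumes=qvols)


def run_pipeline(subjects: Sequence[SubjectData], config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run all five stages; per-subject failures are isolated and logged."""
    controls = [s for s in subjects if s.group == "control"]
    patients = [s for s in subjects if s.group != "control"]
    if len(controls) < 2:
        raise EmptyInputError("pipeline needs >= 2 control subjects")

    template, masks, dmap, control_transforms = build_template_stage(
        controls, config)
    exclusion = _exclusion_mask(masks)
    tiv_ref = config.tiv_ref_ml or float(np.mean([s.tiv_ml for s in controls]))

    results: dict[str, SubjectResult] = {}
    failures: dict[str, str] = {}
    for sub, t in list(zip(controls, control_transforms)) + [
            (p, None) for p in patients]:
        try:
            results[sub.subject_id] = profile_subject(
                sub, template, exclusion, dmap, tiv_ref, config, transform=t)
        except Exception as exc:  # fault isolation: skip, log, continue
            log.error("subject %s failed: %s", sub.subject_id, exc)
            failures[sub.subject_id] = f"{type(exc).__name__}: {exc}"

    control_ids = [s.subject_id for s in controls if s.subject_id in results]
    patient_groups = sorted({s.group for s in patients})

    normative: dict[tuple[str, str], normstats.NormativeModel] = {}
    partitions: dict[str, profiling.RegionPartition] = {}
    for side in SIDES:
        csa_profiles = [results[i].csa[side] for i in control_ids]
        normative[("csa", side)] = normstats.build_normative(
            csa_profiles, bandwidth=config.bandwidth, z=config.z,
            grid_step=config.grid_step,
            min_support=min(normstats.MIN_SUPPORT_DEFAULT, len(csa_profiles)),
            min_profiles=min(config.min_profiles, len(csa_profiles)))
        qt2_profiles = [results[i].qt2[side] for i in control_ids
                        if results[i].qt2[side] is not None]
        if len(qt2_profiles) >= 2:
            normative[("qt2", side)] = normstats.build_normative(
                qt2_profiles, bandwidth=config.bandwidth, z=config.z,
                grid_step=config.grid_step,
                min_support=min(normstats.MIN_SUPPORT_DEFAULT,
                                len(qt2_profiles)),
                min_profiles=min(config.min_profiles, len(qt2_profiles)))
        m = normative[("csa", side)]
        partitions[side] = profiling.partition_regions(
            m.grid, m.mu, side=side, slope_threshold=config.slope_threshold)

    group_models = {}
    pointwise = {}
    for grp in patient_groups:
        ids = [s.subject_id for s in patients
               if s.group == grp and s.subject_id in results]
        for side in SIDES:
            profs = [results[i].csa[side] for i in ids]
            if len(profs) >= 2:
                group_models[(grp, "csa", side)] = \
                    normstats.group_average_profiles(
                        profs, bandwidth=config.bandwidth, z=config.z)
                pointwise[(grp, "csa", side)] = normstats.group_pointwise_test(
                    [results[i].csa[side] for i in control_ids], profs,
                    alpha=config.alpha)

    pct = {}
    for sub_id, res in results.items():
        for side in SIDES:
            res.metrics[side] = profiling.region_metrics(
                res.csa[side], res.qt2[side], res.qt2_slice_volumes[side],
                partitions[side],
                tiv_ml=next(s.tiv_ml for s in subjects
                            if s.subject_id == sub_id),
                subject_id=sub_id)
            res.reports[side] = {}
            for modality in ("csa", "qt2"):
                model = normative.get((modality, side))
                prof = res.csa[side] if modality == "csa" else res.qt2[side]
                if model is None or prof is None:
                    continue
                res.reports[side][modality] = normstats.compare_individual(
                    prof, model)
    for grp in ["control"] + patient_groups:
        ids = [i for i, r in results.items() if r.group == grp]
        for side in SIDES:
            for modality in ("csa", "qt2"):
                reps = [results[i].reports[side][modality] for i in ids
                        if modality in results[i].reports[side]]
                if reps:
                    pct[(grp, modality, side)] = normstats.percent_abnormal(reps)

    out = PipelineResult(config=config, template=template,
                         template_masks=masks, distance_map=dmap,
                         tiv_ref_ml=tiv_ref, subjects=results,
                         normative=normative, group_models=group_models,
                         pointwise=pointwise, partitions=partitions,
                         percent_abnormal=pct, failures=failures)
    if out_dir is not None:
        write_outputs(out, subjects, Path(out_dir))
    return out


# ---------------------------------------------------------------------------
# serialization

def _profile_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for sub_id, res in result.subjects.items():
        for side in SIDES:
            for modality in ("csa", "qt2"):
                prof = res.csa[side] if modality == "csa" else res.qt2[side]
                if prof is None:
                    continue
                for x, v in zip(prof.positions, prof.values):
                    rows.append((sub_id, res.group, side, modality,
                                 float(x), float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "side",
                                       "modality", "position_mm", "value"])


def _model_frame(models: dict) -> pd.DataFrame:
    rows = []
    for key, m in models.items():
        tag = "/".join(key)
        for x, mu, sd, ne in zip(m.grid, m.mu, m.sigma, m.n_eff):
            rows.append((tag, m.modality, m.side, float(x), float(mu),
                         float(sd), float(ne)))
    return pd.DataFrame(rows, columns=["model", "modality", "side",
                                       "position_mm", "mu", "sigma", "n_eff"])


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def write_outputs(result: PipelineResult, subjects: Sequence[SubjectData],
                  out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _profile_frame(result).to_csv(out_dir / "profiles.csv", index=False,
                                  float_format="%.6g")
    _model_frame(result.normative).to_csv(out_dir / "normative.csv",
                                          index=False, float_format="%.6g")
    if result.group_models:
        _model_frame(result.group_models).to_csv(
            out_dir / "group_models.csv", index=False, float_format="%.6g")
    metrics = {}
    for sub_id, res in result.subjects.items():
        metrics[sub_id] = {
            side: {
                "tiv_ml": res.metrics[side].tiv_ml,
                "whole_volume_ml": res.metrics[side].whole_volume_ml,
                "region_volumes_ml": res.metrics[side].region_volumes_ml,
                "whole_qt2_ms": res.metrics[side].whole_qt2_ms,
                "region_qt2_ms": res.metrics[side].region_qt2_ms,
                "fraction_abnormal": {
                    m: res.reports[side][m].fraction_abnormal
                    for m in res.reports[side]},
            } for side in SIDES}
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2,
                                                     sort_keys=True,
                                                     allow_nan=True))
    partitions = {side: {"tail_body_mm": p.tail_body_mm,
                         "body_head_mm": p.body_head_mm,
                         "lengths_mm": p.lengths,
                         "degenerate": p.degenerate}
                  for side, p in result.partitions.items()}
    (out_dir / "regions.json").write_text(json.dumps(partitions, indent=2,
                                                     sort_keys=True))
    manifest = {
        "config": json.loads(result.config.to_json()),
        "tiv_ref_ml": result.tiv_ref_ml,
        "failures": result.failures,
        "inputs": {s.subject_id: {"t1": _checksum(s.t1.data),
                                  "mask_left": _checksum(s.mask_left.data),
                                  "mask_right": _checksum(s.mask_right.data),
                                  "tiv_ml": s.tiv_ml,
                                  "group": s.group}
                   for s in subjects},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
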