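"""Fit a voxelwise qT2 map from a dual-echo pair and summarise it.

The two-point estimator qT2 = (TE2-TE1)/ln(S1/S2) is exact on noiseless
mono-exponential data; with the phantom's default noise the masked mean
lands within a millisecond or two of the simulated tissue T2.  Partial
volume voxels (mask fraction < 0.99 on the dual-echo grid) are excluded.
"""

from hippoprof import PhantomSpec, fit_qt2, make_subject, masked_qt2

subject = make_subject(PhantomSpec(seed=21, t2_tissue=112.0),
                       subject_id="demo")
result = fit_qt2(subject.echo1, subject.echo2, te1=30.0, te2=119.0)
print(f"qT2 map: {int(result.valid.sum())} valid voxels, "
      f"{result.excluded_voxel_count} excluded (non-decaying signal, "
      f"noise, or CSF-level qT2)")

summary = masked_qt2(result, subject.mask_left)
print(f"left hippocampus mean qT2 {summary.mean_ms:.1f} ms "
      f"(simulated tissue T2 = 112.0 ms) over {summary.n_voxels_used} "
      f"voxels; {summary.pv_excluded_count} partial-volume voxels dropped")
print("per-slice means (ms):",
      [f"{m:.1f}" for m in summary.slice_means_ms if m == m])
# Healthy-control hippocampal qT2 spans roughly 108-124 ms at 3 T; values
# above the normative band at a slice indicate T2-elevated tissue there.
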