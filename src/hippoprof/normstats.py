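"""Normative modelling and statistics for AP profiles.

The normative model captures, at 1-mm steps along the AP axis, the local
mean mu(x) and standard deviation sigma(x) of a healthy-control cohort's
CSA or qT2 profiles, estimated with a Gaussian-kernel local weighted mean
and weighted SD (Nadaraya-Watson regression along the AP coordinate;
bandwidth default 2 mm).  The normal range at each position is
mu +/- z sigma with z = 1.96.

Individual comparison is one-sided, matching the clinical signs of
hippocampal sclerosis: a point is *atrophic* when CSA < mu - z sigma and
*T2-elevated* when qT2 > mu + z sigma.  Group comparison runs a Welch
two-sample t-test at every grid point with Bonferroni correction over the
number of tested points; regional metrics use alpha / 3 for the three
regions.  Scan-rescan variability applies the same kernel machinery to
per-point differences of repeated measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .image_io import EmptyInputError
from .profiling import Profile

__all__ = [
    "NormativeModel",
    "AbnormalityReport",
    "PointwiseTestResult",
    "build_normative",
    "compare_individual",
    "group_pointwise_test",
    "region_test",
    "group_average_profiles",
    "scan_rescan_variability",
    "percent_abnormal",
    "whole_measure_flag",
]

Z_DEFAULT = 1.96
BANDWIDTH_DEFAULT = 2.0   # mm
MIN_SUPPORT_DEFAULT = 10.0  # minimum kernel-weighted sample count per point


class SupportWarning(UserWarning):
    """The requested extent was truncated for lack of support."""


@dataclass
class NormativeModel:
    """Local mean/SD of a cohort's profiles on a uniform 1-mm AP grid."""

    side: Literal["left", "right"]
    modality: Literal["csa", "qt2"]
    grid: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    n_eff: np.ndarray
    z: float = Z_DEFAULT
    bandwidth: float = BANDWIDTH_DEFAULT

    @property
    def lower(self) -> np.ndarray:
        return self.mu - self.z * self.sigma

    @property
    def upper(self) -> np.ndarray:
        return self.mu + self.z * self.sigma

    def interp(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) linearly interpolated at arbitrary AP positions."""
        pos = np.asarray(positions, dtype=float)
        mu = np.interp(pos, self.grid, self.mu, left=np.nan, right=np.nan)
        sd = np.interp(pos, self.grid, self.sigma, left=np.nan, right=np.nan)
        return mu, sd


def _pool_samples(profiles: Sequence[Profile]) -> tuple[np.ndarray, np.ndarray]:
    xs, vs = [], []
    for p in profiles:
        ok = np.isfinite(p.values)
        xs.append(p.positions[ok])
        vs.append(p.values[ok])
    return np.concatenate(xs), np.concatenate(vs)


def _lattice_moments(values: np.ndarray, grid: np.ndarray, bandwidth: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kernel-smoothed cross-subject moments on a shared position lattice.

    ``values`` is (subjects, positions) with NaN outside each subject's
    support.  At every lattice position the cross-subject mean and
    population SD are taken first; the Gaussian kernel (peak 1) then
    smooths both along the AP axis, weighting each position by its subject
    count.  Smoothing therefore never mixes the mean's AP trend into the
    dispersion estimate: identical subjects give sigma identically zero,
    and as bandwidth -> 0 the estimator degenerates to the per-position
    sample mean and SD.  Returns (mu, sigma, n_eff).
    """
    h = max(bandwidth, 1e-9)
    counts = np.isfinite(values).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        colmean = np.nanmean(values, axis=0)
        colvar = np.nanvar(values, axis=0)
    colmean = np.where(counts > 0, colmean, 0.0)
    colvar = np.where(counts > 0, colvar, 0.0)
    d = grid[None, :] - grid[:, None]
    wc = np.exp(-0.5 * (d / h) ** 2) * counts[None, :]
    sw = wc.sum(axis=1)
    mu = _local_linear(wc, d, colmean)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (wc @ colvar) / sw
    return mu, np.sqrt(np.clip(var, 0.0, None)), sw


def _local_linear(w: np.ndarray, d: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Local-linear kernel regression estimate.

    ``w`` are kernel weights (targets x sources), ``d`` the signed source
    offsets from each target, ``v`` the source values.  Unlike the plain
    weighted mean, the first-order fit is free of boundary bias at the
    profile tips, where the one-sided window would otherwise drag the mean
    up the slope.  Falls back to the weighted mean where the design is
    degenerate (effectively a single support position).
    """
    s0 = w.sum(axis=1)
    s1 = (w * d).sum(axis=1)
    s2 = (w * d * d).sum(axis=1)
    denom = s0 * s2 - s1**2
    b = w * (s2[:, None] - d * s1[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        ll = (b @ v) / denom
        nw = (w @ v) / s0
    scale = np.maximum(s0 * s2, 1e-30)
    return np.where(denom / scale > 1e-9, ll, nw)


def _scattered_moments(xs: np.ndarray, vs: np.ndarray, grid: np.ndarray,
                       bandwidth: float
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kernel moments for samples at scattered positions (discrete slices).

    The local mean is the Nadaraya-Watson estimate; the dispersion is the
    kernel-weighted spread of *residuals* about the local mean evaluated at
    each sample's own position, so the mean's AP trend does not inflate
    sigma.  Returns (mu, sigma, n_eff) with the kernel peak-1 convention.
    """
    h = max(bandwidth, 1e-9)

    def fit(points):
        d = xs[None, :] - points[:, None]
        w = np.exp(-0.5 * (d / h) ** 2)
        return _local_linear(w, d, vs), w, w.sum(axis=1)

    mu, w, sw = fit(grid)
    m_at_samples, _, _ = fit(xs)
    resid = vs - m_at_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (w * resid[None, :] ** 2).sum(axis=1) / sw
    return mu, np.sqrt(np.clip(var, 0.0, None)), sw


def build_normative(profiles: Sequence[Profile], bandwidth: float = BANDWIDTH_DEFAULT,
                    grid_step: float = 1.0, z: float = Z_DEFAULT,
                    min_support: float = MIN_SUPPORT_DEFAULT,
                    min_profiles: int = 10) -> NormativeModel:
    """Kernel-weighted normative mu(x), sigma(x) from control profiles.

    At each grid point g the Gaussian kernel weight of sample (x, v) is
    ``exp(-(x - g)^2 / (2 h^2))`` (peak 1); mu is the weighted mean,
    sigma the weighted (population) SD, and n_eff the summed weights.
    Grid points with ``n_eff < min_support`` are dropped, with a warning
    when this truncates the requested extent.
    """
    if len(profiles) < min_profiles:
        raise EmptyInputError(
            f"normative model needs >= {min_profiles} profiles, got {len(profiles)}")
    sides = {p.side for p in profiles}
    modalities = {p.modality for p in profiles}
    if len(sides) > 1 or len(modalities) > 1:
        raise ValueError("one side and one modality per normative model")
    lo = min(p.support[0] for p in profiles)
    hi = max(p.support[1] for p in profiles)
    start = np.ceil(lo / grid_step) * grid_step
    grid = start + grid_step * np.arange(int(np.floor((hi - start) / grid_step)) + 1)
    if all(p.sampling == "continuous-1mm" for p in profiles):
        values = np.vstack([p.interp(grid) for p in profiles])
        mu, sigma, sw = _lattice_moments(values, grid, bandwidth)
    else:
        xs, vs = _pool_samples(profiles)
        mu, sigma, sw = _scattered_moments(xs, vs, grid, bandwidth)
    keep = sw >= min_support
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} grid points dropped for n_eff < {min_support}",
            SupportWarning)
    if not keep.any():
        raise EmptyInputError("no grid point reaches the minimum support")
    return NormativeModel(side=profiles[0].side, modality=profiles[0].modality,
                          grid=grid[keep], mu=mu[keep], sigma=sigma[keep],
                          n_eff=sw[keep], z=z, bandwidth=bandwidth)


@dataclass
class AbnormalityReport:
    """One-sided per-point comparison of a subject profile to the norm."""

    side: Literal["left", "right"]
    modality: Literal["csa", "qt2"]
    subject_id: str
    positions: np.ndarray          # points actually compared
    values: np.ndarray
    flags: np.ndarray              # True = abnormal (low CSA / high qT2)
    fraction_abnormal: float

    @property
    def abnormal_positions(self) -> np.ndarray:
        return self.positions[self.flags]


def compare_individual(profile: Profile, model: NormativeModel
                       ) -> AbnormalityReport:
    """Flag profile points outside the one-sided normal range.

    CSA (continuous) profiles are compared at every supported model grid
    point; qT2 (discrete slice) profiles are compared at their own slice
    positions against the model interpolated there.  The abnormal direction
    is low for CSA and high for qT2.
    """
    if profile.side != model.side or profile.modality != model.modality:
        raise ValueError("profile and model must share side and modality")
    if profile.sampling == "continuous-1mm":
        pos = model.grid
        vals = profile.interp(pos)
        mu, sd = model.mu, model.sigma
    else:
        pos = profile.positions
        vals = profile.values
        mu, sd = model.interp(pos)
    ok = np.isfinite(vals) & np.isfinite(mu) & np.isfinite(sd)
    if not ok.any():
        raise EmptyInputError("profile and model supports do not overlap")
    pos, vals, mu, sd = pos[ok], vals[ok], mu[ok], sd[ok]
    if model.modality == "csa":
        flags = vals < mu - model.z * sd
    else:
        flags = vals > mu + model.z * sd
    return AbnormalityReport(
        side=model.side, modality=model.modality,
        subject_id=profile.subject_id,
        positions=pos, values=vals, flags=flags,
        fraction_abnormal=float(flags.mean()),
    )


@dataclass
class PointwiseTestResult:
    """Welch t-test per AP grid point with Bonferroni control."""

    grid: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float
    n_tests: int
    skipped: np.ndarray            # points with a group size < 2

    @property
    def fraction_significant(self) -> float:
        tested = ~self.skipped
        return float(self.significant[tested].mean()) if tested.any() else 0.0


def _stack_on_grid(profiles: Sequence[Profile], grid: np.ndarray) -> np.ndarray:
    return np.vstack([p.interp(grid) for p in profiles])


def common_grid(profiles: Sequence[Profile], step: float = 1.0) -> np.ndarray:
    """Uniform grid covering the intersection of the profiles' supports."""
    lo = max(p.support[0] for p in profiles)
    hi = min(p.support[1] for p in profiles)
    if hi < lo:
        raise EmptyInputError("profiles have no common support")
    start = np.ceil(lo / step) * step
    return start + step * np.arange(int(np.floor((hi - start) / step)) + 1)


def group_pointwise_test(controls: Sequence[Profile],
                         patients: Sequence[Profile],
                         alpha: float = 0.01,
                         grid: np.ndarray | None = None
                         ) -> PointwiseTestResult:
    """Two-sided Welch t-test at every 1-mm point, Bonferroni-corrected.

    All profiles are linearly interpolated to the common grid; the
    Bonferroni denominator is the number of points where both groups have
    at least two observations.
    """
    if grid is None:
        grid = common_grid(list(controls) + list(patients))
    a = _stack_on_grid(controls, grid)
    b = _stack_on_grid(patients, grid)
    na = np.isfinite(a).sum(axis=0)
    nb = np.isfinite(b).sum(axis=0)
    skipped = (na < 2) | (nb < 2)
    t = np.full(grid.shape, np.nan)
    p = np.full(grid.shape, np.nan)
    if (~skipped).any():
        res = stats.ttest_ind(a[:, ~skipped], b[:, ~skipped],
                              equal_var=False, nan_policy="omit", axis=0)
        t[~skipped] = res.statistic
        p[~skipped] = res.pvalue
    n_tests = int((~skipped).sum())
    if n_tests == 0:
        raise EmptyInputError("no grid point has two observations per group")
    significant = np.zeros(grid.shape, dtype=bool)
    significant[~skipped] = p[~skipped] < alpha / n_tests
    return PointwiseTestResult(grid=grid, t=t, p=p, significant=significant,
                               alpha=alpha, n_tests=n_tests, skipped=skipped)


def region_test(control_values: dict[str, np.ndarray],
                patient_values: dict[str, np.ndarray],
                alpha: float = 0.01) -> dict[str, dict]:
    """Welch t-tests on regional metrics at alpha / number of regions."""
    regions = list(control_values)
    thr = alpha / len(regions)
    out = {}
    for name in regions:
        a = np.asarray(control_values[name], dtype=float)
        b = np.asarray(patient_values[name], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            out[name] = {"t": np.nan, "p": np.nan, "significant": False,
                         "skipped": True}
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        out[name] = {"t": float(res.statistic), "p": float(res.pvalue),
                     "significant": bool(res.pvalue < thr), "skipped": False}
    return out


def group_average_profiles(group: Sequence[Profile],
                           bandwidth: float = BANDWIDTH_DEFAULT,
                           **kwargs) -> NormativeModel:
    """Mean profile + band for a (patient) group: the same kernel
    machinery as the normative model, with a lower profile-count floor."""
    if len(group) < 2:
        raise EmptyInputError("group averages need >= 2 profiles")
    return build_normative(group, bandwidth=bandwidth,
                           min_profiles=2, **kwargs)


def scan_rescan_variability(pairs: Sequence[tuple[Profile, Profile]],
                            bandwidth: float = BANDWIDTH_DEFAULT,
                            grid_step: float = 1.0) -> NormativeModel:
    """Kernel SD of scan-rescan differences per AP point.

    Each subject's two profiles are differenced at their common grid
    points; the returned model's sigma(x) is the kernel-weighted SD of
    those differences (its mu should hover near zero for unbiased repeats).
    """
    if len(pairs) < 5:
        raise EmptyInputError("scan-rescan estimation needs >= 5 pairs")
    xs_all, vs_all = [], []
    extents = []
    for first, second in pairs:
        if first.side != second.side or first.modality != second.modality:
            raise ValueError("pair members must share side and modality")
        try:
            grid = common_grid([first, second], step=grid_step)
        except EmptyInputError:
            continue  # mismatched supports: pair contributes nothing
        d = first.interp(grid) - second.interp(grid)
        ok = np.isfinite(d)
        if not ok.any():
            continue
        xs_all.append(grid[ok])
        vs_all.append(d[ok])
        extents.append((grid[ok][0], grid[ok][-1]))
    if len(xs_all) < 5:
        raise EmptyInputError("fewer than 5 usable scan-rescan pairs")
    lo = min(e[0] for e in extents)
    hi = max(e[1] for e in extents)
    start = np.ceil(lo / grid_step) * grid_step
    grid = start + grid_step * np.arange(int(np.floor((hi - start) / grid_step)) + 1)
    values = np.full((len(xs_all), len(grid)), np.nan)
    for row, (x, v) in enumerate(zip(xs_all, vs_all)):
        values[row] = np.interp(grid, x, v, left=np.nan, right=np.nan)
    mu, sigma, sw = _lattice_moments(values, grid, bandwidth)
    keep = sw >= MIN_SUPPORT_DEFAULT
    if not keep.any():
        raise EmptyInputError("no grid point reaches the minimum support")
    first = pairs[0][0]
    return NormativeModel(side=first.side, modality=first.modality,
                          grid=grid[keep], mu=mu[keep], sigma=sigma[keep],
                          n_eff=sw[keep], z=Z_DEFAULT, bandwidth=bandwidth)


def percent_abnormal(reports: Sequence[AbnormalityReport]) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of individuals flagged abnormal at each AP point.

    Returns ``(positions, fraction)`` over the union of report grids; at
    each point the denominator counts only individuals with data there.
    """
    if not reports:
        raise EmptyInputError("no reports given")
    positions = np.unique(np.concatenate([r.positions for r in reports]))
    flagged = np.zeros(positions.shape)
    counted = np.zeros(positions.shape)
    for r in reports:
        idx = np.searchsorted(positions, r.positions)
        counted[idx] += 1
        flagged[idx] += r.flags
    with np.errstate(invalid="ignore"):
        frac = np.where(counted > 0, flagged / np.maximum(counted, 1), np.nan)
    return positions, frac


def whole_measure_flag(value: float, control_values: Sequence[float],
                       direction: Literal["low", "high"],
                       z: float = Z_DEFAULT) -> bool:
    """Whole-hippocampus flag: value outside mean +/- z SD of controls."""
    c = np.asarray(control_values, dtype=float)
    mu, sd = float(c.mean()), float(c.std(ddof=0))
    if direction == "low":
        return bool(value < mu - z * sd)
    return bool(value > mu + z * sd)
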