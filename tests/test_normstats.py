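"""Normative model, individual/group comparison, rescan variability."""

import numpy as np
import pytest

from hippoprof import (
    EmptyInputError,
    Profile,
    build_normative,
    compare_individual,
    group_average_profiles,
    group_pointwise_test,
    percent_abnormal,
    scan_rescan_variability,
    whole_measure_flag,
)
from hippoprof.normstats import region_test

GRID = np.arange(0.0, 47.0)


def mu0(x):
    """Smooth hippocampus-like CSA curve."""
    return 55.0 + 25.0 * np.exp(-0.5 * ((x - 33.0) / 6.0) ** 2) \
        - 40.0 * np.exp(-0.5 * (x / 6.0) ** 2)


def gaussian_cohort(n, sigma=5.0, shift=0.0, seed=0, grid=GRID):
    rng = np.random.default_rng(seed)
    return [
        Profile(grid,
                np.clip(mu0(grid) + shift + rng.normal(0.0, sigma, len(grid)),
                        0.01, None),
                modality="csa", subject_id=f"s{i}")
        for i in range(n)
    ]


class TestBuildNormative:
    def test_identical_profiles_zero_sigma(self):
        profs = [Profile(GRID, mu0(GRID), modality="csa")] * 12
        model = build_normative(profs)
        assert np.allclose(model.sigma, 0.0, atol=1e-9)
        # mu reproduces the common profile up to the kernel's smoothing
        # bias, bounded by h^2 sup|f''| / 2 on interior points
        interior = (model.grid >= 6) & (model.grid <= 40)
        bias_bound = 0.5 * model.bandwidth**2 * 1.3
        assert np.max(np.abs(model.mu[interior]
                             - mu0(model.grid[interior]))) < bias_bound
        assert model.z == 1.96

    def test_identical_linear_profiles_reproduce_mu_exactly_interior(self):
        grid = np.arange(0.0, 40.0)
        vals = 20.0 + 1.5 * grid
        profs = [Profile(grid, vals, modality="csa")] * 12
        model = build_normative(profs)
        interior = (model.grid >= 8) & (model.grid <= 31)
        # symmetric kernel is exact on linear trends away from the edges
        assert np.allclose(model.mu[interior], (20.0 + 1.5 * model.grid)[interior],
                           atol=0.01)
        assert np.allclose(model.sigma, 0.0, atol=1e-9)

    def test_parameter_recovery_at_n_111(self):
        model = build_normative(gaussian_cohort(111, sigma=5.0, seed=1))
        interior = (model.grid >= 8) & (model.grid <= 39)
        # local kernel mean ~ mu0 up to smoothing bias + sampling noise
        assert np.max(np.abs(model.mu[interior] - mu0(model.grid[interior]))) < 2.0
        assert np.all(np.abs(model.sigma[interior] - 5.0) < 0.15 * 5.0)

    def test_small_bandwidth_degenerates_to_pointwise_moments(self):
        profs = gaussian_cohort(30, sigma=4.0, seed=2)
        model = build_normative(profs, bandwidth=1e-4, min_support=5)
        stack = np.vstack([p.values for p in profs])
        idx = np.searchsorted(GRID, model.grid)
        assert np.allclose(model.mu, stack.mean(axis=0)[idx], atol=1e-6)
        assert np.allclose(model.sigma, stack.std(axis=0, ddof=0)[idx],
                           atol=1e-6)

    def test_too_few_profiles_rejected(self):
        with pytest.raises(EmptyInputError):
            build_normative(gaussian_cohort(5))

    def test_band_contains_95_percent_of_heldout_points(self):
        model = build_normative(gaussian_cohort(111, seed=3))
        held = gaussian_cohort(111, seed=4)
        inside = []
        for p in held:
            v = p.interp(model.grid)
            inside.append((v >= model.lower) & (v <= model.upper))
        frac = np.mean(inside)
        assert abs(frac - 0.95) < 0.02


class TestCompareIndividual:
    def test_profile_at_mu_has_no_flags(self):
        model = build_normative(gaussian_cohort(50, seed=5))
        prof = Profile(model.grid, model.mu, modality="csa")
        rep = compare_individual(prof, model)
        assert not rep.flags.any()
        assert rep.fraction_abnormal == 0.0

    def test_two_sigma_deficit_flags_everything(self):
        model = build_normative(gaussian_cohort(50, seed=6))
        prof = Profile(model.grid,
                       np.clip(model.mu - 2.5 * model.sigma, 0.01, None),
                       modality="csa")
        rep = compare_individual(prof, model)
        assert rep.fraction_abnormal == 1.0

    def test_flags_invariant_under_common_offset(self):
        model = build_normative(gaussian_cohort(50, seed=7))
        rng = np.random.default_rng(8)
        vals = model.mu + rng.normal(0, 1.5 * model.sigma)
        prof = Profile(model.grid, np.clip(vals, 0.01, None), modality="csa")
        rep1 = compare_individual(prof, model)
        shifted_model = build_normative(
            [Profile(p.positions, p.values + 30.0, modality="csa")
             for p in gaussian_cohort(50, seed=7)])
        rep2 = compare_individual(
            Profile(prof.positions, prof.values + 30.0, modality="csa"),
            shifted_model)
        assert np.array_equal(rep1.flags, rep2.flags)

    def test_qt2_flags_high_tail_at_slice_positions(self):
        profs = [Profile(GRID, np.full(len(GRID), 115.0)
                         + np.random.default_rng(i).normal(0, 3.0, len(GRID)),
                         modality="qt2") for i in range(40)]
        model = build_normative(profs)
        pts = Profile([10.0, 22.5, 34.0], [116.0, 140.0, 114.0],
                      modality="qt2", sampling="discrete-slice")
        rep = compare_individual(pts, model)
        assert list(rep.flags) == [False, True, False]

    def test_disjoint_supports_rejected(self):
        model = build_normative(gaussian_cohort(20, seed=9))
        prof = Profile(np.arange(200.0, 220.0), np.full(20, 50.0),
                       modality="csa")
        with pytest.raises(EmptyInputError):
            compare_individual(prof, model)


class TestGroupTests:
    def test_null_familywise_error_controlled(self):
        """200-rep null simulation: Bonferroni keeps FWER near alpha."""
        rng = np.random.default_rng(11)
        grid = np.arange(40.0)
        n_rej = 0
        reps = 200
        for _ in range(reps):
            a = [Profile(grid, rng.normal(100, 10, 40), modality="csa")
                 for _ in range(30)]
            b = [Profile(grid, rng.normal(100, 10, 40), modality="csa")
                 for _ in range(30)]
            res = group_pointwise_test(a, b, alpha=0.01)
            n_rej += res.significant.any()
        se = np.sqrt(0.01 * 0.99 / reps)
        assert n_rej / reps <= 0.01 + 3 * se

    def test_strong_band_effect_detected(self):
        rng = np.random.default_rng(12)
        grid = np.arange(40.0)
        band = (grid >= 15) & (grid < 25)
        hits = 0
        for _ in range(20):
            a = [Profile(grid, rng.normal(100, 10, 40), modality="csa")
                 for _ in range(30)]
            b = [Profile(grid, rng.normal(100, 10, 40) - 30.0 * band,
                         modality="csa") for _ in range(30)]
            res = group_pointwise_test(a, b, alpha=0.01)
            hits += res.significant[band].all()
        assert hits >= 19

    def test_bonferroni_monotone_in_grid_size(self):
        rng = np.random.default_rng(13)
        grid = np.arange(60.0)
        a = [Profile(grid, rng.normal(100, 10, 60), modality="csa")
             for _ in range(25)]
        b = [Profile(grid, rng.normal(95, 10, 60), modality="csa")
             for _ in range(25)]
        small = group_pointwise_test(a, b, grid=grid[:30])
        large = group_pointwise_test(a, b, grid=grid)
        assert small.significant[:30].sum() >= large.significant[:30].sum()

    def test_region_variant_uses_alpha_over_three(self):
        rng = np.random.default_rng(14)
        ctrl = {r: rng.normal(1.0, 0.1, 40) for r in ("tail", "body", "head")}
        pat = {r: rng.normal(1.0, 0.1, 40) for r in ("tail", "body", "head")}
        pat["head"] = pat["head"] - 0.3
        out = region_test(ctrl, pat, alpha=0.01)
        assert out["head"]["significant"]
        assert not out["tail"]["significant"]
        # borderline p between .01/3 and .01 must NOT be significant
        assert all(v["p"] < 0.01 / 3 for v in out.values()
                   if v["significant"])


class TestGroupAverages:
    def test_single_subject_group_rejected(self):
        with pytest.raises(EmptyInputError):
            group_average_profiles(gaussian_cohort(1))

    def test_control_group_reproduces_normative(self):
        profs = gaussian_cohort(30, seed=15)
        assert np.allclose(group_average_profiles(profs).mu,
                           build_normative(profs).mu)

    def test_group_shift_recovered(self):
        base = build_normative(gaussian_cohort(60, seed=16))
        shifted = group_average_profiles(
            gaussian_cohort(60, shift=-12.0, seed=17))
        common = np.intersect1d(base.grid, shifted.grid)
        d = (shifted.interp(common)[0] - base.interp(common)[0])
        interior = (common > 5) & (common < 41)
        assert np.allclose(d[interior], -12.0, atol=2.0)


class TestScanRescan:
    def _pairs(self, n=20, noise=0.0, seed=18):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            truth = mu0(GRID) + rng.normal(0, 5.0, 1)
            a = Profile(GRID, truth + rng.normal(0, noise, len(GRID))
                        if noise else truth.copy(), modality="csa")
            b = Profile(GRID, truth + rng.normal(0, noise, len(GRID))
                        if noise else truth.copy(), modality="csa")
            out.append((a, b))
        return out

    def test_identical_repeats_zero_variability(self):
        model = scan_rescan_variability(self._pairs(noise=0.0))
        assert np.allclose(model.sigma, 0.0, atol=1e-9)

    def test_iid_noise_gives_sqrt_two_sigma(self):
        s = 3.0
        model = scan_rescan_variability(self._pairs(n=20, noise=s, seed=19))
        interior = (model.grid > 5) & (model.grid < 41)
        est = model.sigma[interior].mean()
        assert abs(est - s * np.sqrt(2)) <= 0.2 * s * np.sqrt(2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(EmptyInputError):
            scan_rescan_variability(self._pairs(n=3))


class TestPercentAbnormal:
    def test_control_cohort_flag_rate_near_two_and_a_half_percent(self):
        model = build_normative(gaussian_cohort(111, seed=20))
        held = gaussian_cohort(111, seed=21)
        reports = [compare_individual(p, model) for p in held]
        pos, frac = percent_abnormal(reports)
        interior = (pos > 5) & (pos < 41)
        assert abs(np.nanmean(frac[interior]) - 0.025) < 0.012

    def test_universal_deficit_flags_everyone(self):
        model = build_normative(gaussian_cohort(30, seed=22))
        reports = []
        for _ in range(10):
            prof = Profile(model.grid,
                           np.clip(model.mu - 3.5 * model.sigma - 1.0,
                                   0.01, None), modality="csa")
            reports.append(compare_individual(prof, model))
        _, frac = percent_abnormal(reports)
        assert np.all(frac == 1.0)

    def test_empty_report_list_rejected(self):
        with pytest.raises(EmptyInputError):
            percent_abnormal([])


class TestWholeFlags:
    def test_directional_thresholds(self):
        controls = np.r_[np.full(50, 2.9) + np.linspace(-0.3, 0.3, 50)]
        assert whole_measure_flag(2.0, controls, "low")
        assert not whole_measure_flag(2.9, controls, "low")
        assert whole_measure_flag(3.8, controls, "high")
        assert not whole_measure_flag(2.9, controls, "high")
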