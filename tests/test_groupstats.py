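import numpy as np
import pytest
from scipy import stats

from paindecode import groupstats as GS
from paindecode.cohort import load_reference_demographics


class TestTwoSampleTMap:
    def test_identical_groups_give_zero_t(self, rng):
        A = rng.standard_normal((5, 40))
        tmap = GS.two_sample_tmap(A, A.copy())
        np.testing.assert_allclose(tmap.t, 0.0, atol=1e-12)
        assert not tmap.significant.any()

    def test_hand_computed_single_voxel(self):
        tmap = GS.two_sample_tmap(np.array([[1.0], [2.0], [3.0]]),
                                  np.array([[4.0], [5.0], [6.0]]))
        assert tmap.t[0] == pytest.approx(-3.674, abs=1e-3)
        assert tmap.dof == 4

    def test_zero_variance_voxel_masked_with_warning(self, rng):
        A = rng.standard_normal((4, 3))
        B = rng.standard_normal((4, 3))
        A[:, 1] = B[:, 1] = 2.0
        with pytest.warns(UserWarning, match="zero pooled variance"):
            tmap = GS.two_sample_tmap(A, B)
        assert not tmap.valid[1]
        assert np.isnan(tmap.t[1])

    def test_sign_antisymmetry(self, rng):
        A = rng.standard_normal((6, 30))
        B = rng.standard_normal((7, 30)) + 0.3
        t1 = GS.two_sample_tmap(A, B).t
        t2 = GS.two_sample_tmap(B, A).t
        np.testing.assert_allclose(t1, -t2, atol=1e-12)

    def test_cross_check_against_scipy(self, rng):
        A = rng.standard_normal((9, 25))
        B = rng.standard_normal((11, 25)) + 0.4
        tmap = GS.two_sample_tmap(A, B)
        ref_t, ref_p = stats.ttest_ind(A, B, axis=0)
        np.testing.assert_allclose(tmap.t, ref_t, atol=1e-10)
        np.testing.assert_allclose(tmap.p, ref_p, atol=1e-10)


class TestFDR:
    def test_all_ones_flag_nothing(self):
        flags, thr = GS.fdr_threshold(np.ones(10))
        assert not flags.any() and thr == 0.0

    def test_step_up_example(self):
        flags, thr = GS.fdr_threshold([0.001, 0.011, 0.021, 0.8], q=0.05)
        np.testing.assert_array_equal(flags, [True, True, True, False])
        assert thr == pytest.approx(0.021)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=50) ** 2
        flags, _ = GS.fdr_threshold(p)
        perm = rng.permutation(50)
        flags_perm, _ = GS.fdr_threshold(p[perm])
        np.testing.assert_array_equal(flags_perm, flags[perm])

    def test_matches_direct_step_up_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=30)
            flags, _ = GS.fdr_threshold(p, q=0.1)
            # oracle: literal Benjamini-Hochberg definition
            order = np.argsort(p)
            m = p.size
            below = np.flatnonzero(p[order] <= 0.1 * np.arange(1, m + 1) / m)
            expect = np.zeros(m, dtype=bool)
            if below.size:
                expect[order[: below.max() + 1]] = True
            np.testing.assert_array_equal(flags, expect)

    def test_false_flag_rate_controlled_on_uniform_null(self, rng):
        rates = []
        for _ in range(200):
            p = rng.uniform(size=500)
            flags, _ = GS.fdr_threshold(p, q=0.05)
            rates.append(flags.mean())
        assert np.mean(rates) <= 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            GS.fdr_threshold([])


class TestWeightedContrast:
    def test_unit_weights_equal_unweighted(self, rng):
        X = rng.standard_normal((10, 20))
        y = np.repeat([1, 0], 5)
        w = np.ones(10)
        t1 = GS.weighted_contrast_tmap(X, w, y).t
        t2 = GS.two_sample_tmap(X[y == 1], X[y == 0]).t
        np.testing.assert_array_equal(t1, t2)

    def test_matches_direct_recomputation(self, rng):
        X = rng.standard_normal((12, 15))
        y = np.repeat([1, 0], 6)
        w = rng.uniform(0.5, 2.0, 12)
        t1 = GS.weighted_contrast_tmap(X, w, y).t
        t2 = GS.two_sample_tmap((X * w[:, None])[y == 1],
                                (X * w[:, None])[y == 0]).t
        np.testing.assert_array_equal(t1, t2)

    def test_missing_or_invalid_weights_rejected(self, rng):
        X = rng.standard_normal((6, 5))
        y = np.repeat([1, 0], 3)
        with pytest.raises(ValueError):
            GS.weighted_contrast_tmap(X, np.ones(5), y)
        with pytest.raises(ValueError):
            GS.weighted_contrast_tmap(X, [1, 1, np.nan, 1, 1, 1], y)


class TestDurationCorrelation:
    def test_independent_signal_near_zero(self, rng):
        X = rng.standard_normal((13, 40))
        dur = rng.uniform(0.5, 5.0, 13)
        tmap = GS.duration_correlation_map(X, dur)
        assert not tmap.significant.any()
        assert np.abs(tmap.t[tmap.valid]).max() < 6

    def test_perfect_linear_voxel_guarded(self, rng):
        dur = np.linspace(0.5, 5.0, 10)
        X = rng.standard_normal((10, 5))
        X[:, 2] = 2.0 * dur
        tmap = GS.duration_correlation_map(X, dur)
        assert np.isfinite(tmap.t[2])
        assert tmap.t[2] > 1e10

    def test_constant_durations_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            GS.duration_correlation_map(rng.standard_normal((5, 4)),
                                        np.ones(5))

    def test_planted_slope_found(self, rng):
        found = 0
        for _ in range(20):
            dur = rng.uniform(0.5, 5.0, 13)
            X = rng.standard_normal((13, 60))
            X[:, 7] += 1.5 * (dur - dur.mean())
            tmap = GS.duration_correlation_map(X, dur)
            found += int(np.argmax(np.abs(tmap.t))) == 7
        assert found >= 18


class TestSmallVolumeCorrection:
    def test_single_voxel_sphere_is_single_test(self, small_mask, rng):
        n = small_mask.n_voxels
        tmap = GS.two_sample_tmap(rng.standard_normal((6, n)),
                                  rng.standard_normal((6, n)))
        center = small_mask.coords_mm[10]
        inside, flags = GS.small_volume_correction(tmap, small_mask, center,
                                                   radius_mm=0.5)
        assert inside.tolist() == [10]
        assert flags.size == 1

    def test_membership_matches_brute_force(self, small_mask, rng):
        n = small_mask.n_voxels
        tmap = GS.two_sample_tmap(rng.standard_normal((6, n)),
                                  rng.standard_normal((6, n)))
        center = np.array([-10.0, -10.0, -10.0])
        inside, _ = GS.small_volume_correction(tmap, small_mask, center,
                                               radius_mm=8.0)
        expect = [i for i in range(n)
                  if np.sum((small_mask.coords_mm[i] - center) ** 2) <= 64.0]
        assert sorted(inside.tolist()) == expect

    def test_svc_flags_cover_restricted_global_flags(self, small_mask, rng):
        # put the smallest p-values inside the sphere: whatever the global
        # FDR flags there, the sphere-restricted test flags at least as much
        n = small_mask.n_voxels
        A = rng.standard_normal((8, n))
        B = rng.standard_normal((8, n))
        center = small_mask.coords_mm[0]
        d2 = ((small_mask.coords_mm - center) ** 2).sum(axis=1)
        sphere = d2 <= 36.0
        A[:, sphere] += 2.5
        tmap = GS.two_sample_tmap(A, B)
        inside, flags = GS.small_volume_correction(tmap, small_mask, center,
                                                   radius_mm=6.0)
        global_flags = tmap.significant[inside]
        assert np.all(flags[global_flags])

    def test_empty_sphere_rejected(self, small_mask, rng):
        n = small_mask.n_voxels
        tmap = GS.two_sample_tmap(rng.standard_normal((4, n)),
                                  rng.standard_normal((4, n)))
        with pytest.raises(ValueError, match="sphere"):
            GS.small_volume_correction(tmap, small_mask, (500.0, 0.0, 0.0))


class TestWilcoxon:
    def test_identical_samples_p_near_one(self):
        w, p = GS.wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_exact_enumeration_example(self):
        w, p = GS.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_reference_thresholds_not_significant(self):
        ref = load_reference_demographics()
        ch = ref.loc[ref.group == "chronic", "threshold_mA"]
        nc = ref.loc[ref.group == "normal", "threshold_mA"]
        _, p = GS.wilcoxon_rank_sum(ch, nc)
        assert p > 0.1

    def test_exact_and_normal_paths_agree(self, rng):
        diffs = []
        for _ in range(30):
            a = rng.normal(size=6)
            b = rng.normal(loc=0.5, size=6)
            _, p_exact = GS.wilcoxon_rank_sum(a, b)
            _, p_norm = GS.wilcoxon_rank_sum(a, b, exact_max_n=0)
            diffs.append(abs(p_exact - p_norm))
        assert np.mean(diffs) < 0.02 and max(diffs) < 0.06

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            GS.wilcoxon_rank_sum([], [1.0])


class TestKSNormality:
    def test_statistic_matches_brute_force(self, rng):
        x = rng.normal(2.0, 3.0, size=20)
        d, _ = GS.ks_normality(x)
        xs = np.sort(x)
        mu, sd = xs.mean(), xs.std(ddof=1)
        sup = 0.0
        n = xs.size
        for i, v in enumerate(xs):
            c = stats.norm.cdf(v, mu, sd)
            sup = max(sup, abs((i + 1) / n - c), abs(c - i / n))
        assert d == pytest.approx(sup, abs=1e-12)

    def test_normal_data_usually_not_rejected(self, rng):
        rejected = 0
        for i in range(20):
            x = rng.normal(size=26)
            _, p = GS.ks_normality(x, n_mc=400, seed=i)
            rejected += p < 0.05
        assert rejected <= 4

    def test_bimodal_data_rejected(self, rng):
        rejected = 0
        for i in range(20):
            x = np.r_[np.zeros(13), np.ones(13)] + 0.01 * \
                rng.standard_normal(26)
            _, p = GS.ks_normality(x, n_mc=400, seed=i)
            rejected += p < 0.05
        assert rejected >= 18

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            GS.ks_normality([1.0, 2.0])


class TestPower:
    def test_null_power_equals_alpha(self):
        assert GS.power_two_proportions(0.5, 0.5, 13) == pytest.approx(
            0.05, abs=1e-3)

    def test_study_power_rounds_to_100(self):
        power = GS.power_two_proportions(0.923, 0.077, 13)
        assert round(100 * power) == 100

    def test_monotone_in_effect_and_n(self):
        p_small = GS.power_two_proportions(0.55, 0.45, 50)
        p_big = GS.power_two_proportions(0.7, 0.3, 50)
        assert p_big > p_small
        assert GS.power_two_proportions(0.6, 0.4, 100) > \
            GS.power_two_proportions(0.6, 0.4, 30)

    def test_matches_simulation_oracle(self, rng):
        p1, p2, n = 0.6, 0.4, 50
        power = GS.power_two_proportions(p1, p2, n)
        reject = 0
        reps = 20000
        z = stats.norm.ppf(0.975)
        k1 = rng.binomial(n, p1, reps)
        k2 = rng.binomial(n, p2, reps)
        ph1, ph2 = k1 / n, k2 / n
        pbar = (k1 + k2) / (2 * n)
        se = np.sqrt(2 * pbar * (1 - pbar) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = np.abs(ph1 - ph2) / se
        reject = np.mean(zstat > z)
        # the normal approximation is good to a few points at this n
        assert abs(power - reject) < 0.04

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            GS.power_two_proportions(0.0, 0.5, 13)


class TestMotion:
    def make_traces(self, rng, n_sub, scale=1.0, n_scan=40):
        steps = scale * rng.standard_normal((n_sub, n_scan, 6)) * 0.05
        return np.cumsum(steps, axis=1)

    def test_identical_traces_zero_t(self, rng):
        a = self.make_traces(rng, 5)
        t, p = GS.motion_summary_test(a, a.copy())
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_scaled_group_detected_on_all_parameters(self, rng):
        a = self.make_traces(rng, 10)
        b = self.make_traces(rng, 10, scale=3.0)
        t, p = GS.motion_summary_test(a, b)
        assert (p < 0.05).all()
        t2, p2 = GS.motion_summary_test(a, b, use="total_deviation")
        assert (p2 < 0.05).all()

    def test_null_rejection_rate_nominal(self, rng):
        rejections = []
        for _ in range(40):
            a = self.make_traces(rng, 8)
            b = self.make_traces(rng, 8)
            _, p = GS.motion_summary_test(a, b)
            rejections.extend(p < 0.05)
        assert np.mean(rejections) <= 0.10

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            GS.motion_summary_test(self.make_traces(rng, 4, n_scan=30),
                                   self.make_traces(rng, 4, n_scan=20))


class TestReferenceDemographics:
    def test_threshold_and_age_statistics(self):
        ref = load_reference_demographics()
        ch = ref[ref.group == "chronic"]
        nc = ref[ref.group == "normal"]
        assert ch["threshold_mA"].mean() == pytest.approx(0.819, abs=5e-4)
        assert nc["threshold_mA"].mean() == pytest.approx(0.662, abs=5e-4)
        assert ch["threshold_mA"].median() == pytest.approx(0.75)
        assert nc["threshold_mA"].median() == pytest.approx(0.6)
        males = ref[ref.sex == "M"]
        assert males["threshold_mA"].median() == pytest.approx(0.9)
        assert ch["age"].mean() == pytest.approx(51.8, abs=0.05)
        assert nc["age"].mean() == pytest.approx(48.7, abs=0.05)
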