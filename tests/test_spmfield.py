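"""1D SPM: F fields, smoothness, RFT threshold, permutation oracle,
clusters."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import smooth_gaussian_curves
from ecctrain._mixedanova import mixed_anova_2x2_arrays, mixed_anova_residuals
from ecctrain.spmfield import (
    CurveSet,
    anova_field,
    estimate_fwhm,
    permutation_threshold,
    rft_critical_threshold,
    spm_anova,
    suprathreshold_clusters,
)


def brute_force_mixed_anova(y, group):
    """Independent split-plot sums-of-squares oracle (balanced groups).

    y: (N, 2) pre/post values; returns F for group, time, interaction via
    the textbook cell-sum decomposition with subject as random block.
    """
    group = np.asarray(group)
    levels = np.unique(group)
    n = int((group == levels[0]).sum())
    assert n == int((group == levels[1]).sum()), "oracle assumes balance"
    N = 2 * n
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    subj_means = y.mean(axis=1)
    group_means = np.array([y[group == g].mean() for g in levels])
    time_means = y.mean(axis=0)
    cell_means = np.array([y[group == g].mean(axis=0) for g in levels])
    ss_group = 2 * n * ((group_means - grand) ** 2).sum()
    ss_subj_within = 2 * ((subj_means - np.repeat(group_means, n)) ** 2).sum()
    ss_time = N * ((time_means - grand) ** 2).sum()
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_int = ss_cells - ss_group - ss_time
    ss_err = ss_total - ss_group - ss_subj_within - ss_time - ss_int
    df_between, df_within = N - 2, N - 2
    return {
        "group": (ss_group / 1) / (ss_subj_within / df_between),
        "time": (ss_time / 1) / (ss_err / df_within),
        "interaction": (ss_int / 1) / (ss_err / df_within),
    }


class TestAnovaField:
    def test_identical_curves_give_zero_f_everywhere(self):
        pre = np.tile(np.linspace(0, 1, 101), (8, 1))
        cs = CurveSet(pre=pre, post=pre.copy(),
                      group=np.array(["a"] * 4 + ["b"] * 4))
        for r in anova_field(cs).values():
            assert np.allclose(r.F, 0.0)

    def test_scalar_case_equals_brute_force_oracle(self, rng):
        for _ in range(20):
            n = 4
            pre = rng.normal(10, 2, 2 * n)
            post = pre + rng.normal(1, 1, 2 * n)
            group = np.array(["a"] * n + ["b"] * n)
            mine = mixed_anova_2x2_arrays(pre, post, group)
            oracle = brute_force_mixed_anova(
                np.column_stack([pre, post]), group
            )
            for eff in ("group", "time", "interaction"):
                assert mine[eff]["F"][0] == pytest.approx(
                    oracle[eff], abs=1e-10, rel=1e-10
                )

    def test_pure_time_effect_loads_on_time_not_interaction(self, rng):
        n = 10
        pre = smooth_gaussian_curves(rng, 2 * n)
        post = pre + 1.0 + 0.05 * smooth_gaussian_curves(rng, 2 * n)
        cs = CurveSet(pre=pre, post=post, group=np.array(["a"] * n + ["b"] * n))
        res = anova_field(cs)
        assert res["time"].F.min() > res["interaction"].F.max()

    def test_constant_shift_invariance(self, rng):
        n = 6
        pre = smooth_gaussian_curves(rng, 2 * n)
        post = pre + smooth_gaussian_curves(rng, 2 * n)
        group = np.array(["a"] * n + ["b"] * n)
        r1 = mixed_anova_2x2_arrays(pre, post, group)
        r2 = mixed_anova_2x2_arrays(pre + 7.5, post + 7.5, group)
        for eff in r1:
            assert np.allclose(r1[eff]["F"], r2[eff]["F"], atol=1e-9)

    def test_unbalanced_subjects_rejected_via_frame(self):
        import pandas as pd

        rows = []
        for s, g in [("s1", "a"), ("s2", "a"), ("s3", "b")]:
            rows.append((s, g, "pre", 1.0))
            if s != "s3":
                rows.append((s, g, "post", 2.0))
        df = pd.DataFrame(rows, columns=["subject", "group", "time", "y"])
        with pytest.raises(ValueError, match="s3"):
            CurveSet.from_frame(df, ["y"])


class TestFwhm:
    def test_recovery_of_known_smoothness(self, rng):
        for w in (5.0, 10.0, 20.0):
            est = [
                estimate_fwhm(smooth_gaussian_curves(rng, 20, 101, w))
                for _ in range(200)
            ]
            assert np.mean(est) == pytest.approx(w, rel=0.15)

    def test_white_noise_stable_across_seeds(self, rng):
        est = [estimate_fwhm(rng.standard_normal((20, 101)))
               for _ in range(100)]
        assert np.std(est) / np.mean(est) < 0.2

    def test_perfectly_smooth_residuals_flagged_infinite(self):
        flat = np.outer(np.array([1.0, -2.0, 3.0]), np.ones(101))
        with pytest.warns(UserWarning, match="infinite smoothness"):
            assert np.isinf(estimate_fwhm(flat))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            estimate_fwhm(np.zeros((5, 101)))


class TestRftThreshold:
    def test_infinite_smoothness_limit_is_scalar_quantile(self):
        df = (1, 23)
        thr = rft_critical_threshold(df, float("inf"), 101, 0.05)
        assert thr == pytest.approx(sps.f.isf(0.05, *df), abs=1e-9)

    def test_monotone_in_resels(self):
        df = (1, 23)
        thrs = [rft_critical_threshold(df, w, 101, 0.05)
                for w in (50.0, 20.0, 10.0, 5.0)]
        assert np.all(np.diff(thrs) > 0)
        assert thrs[0] > sps.f.isf(0.05, *df)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            rft_critical_threshold((1, 23), 10.0, 101, 1.5)

    def test_familywise_error_calibrated_on_null_fields(self, rng):
        # moderate replication here; the acceptance suite runs the full one
        n0, n1, Q = 14, 11, 101
        group = np.array(["i"] * n0 + ["c"] * n1)
        hits = 0
        reps = 500
        for _ in range(reps):
            pre = smooth_gaussian_curves(rng, n0 + n1, Q, 10.0)
            post = smooth_gaussian_curves(rng, n0 + n1, Q, 10.0)
            res = mixed_anova_2x2_arrays(pre, post, group)
            fw = estimate_fwhm(mixed_anova_residuals(pre, post, group))
            thr = rft_critical_threshold(res["interaction"]["df"], fw, Q)
            hits += res["interaction"]["F"].max() > thr
        # 95% binomial interval around 0.05 at 500 reps is ~ +-0.02
        assert hits / reps == pytest.approx(0.05, abs=0.025)


class TestPermutation:
    def _curves(self, rng, n0=8, n1=8):
        pre = smooth_gaussian_curves(rng, n0 + n1)
        post = smooth_gaussian_curves(rng, n0 + n1)
        return CurveSet(pre=pre, post=post,
                        group=np.array(["a"] * n0 + ["b"] * n1))

    def test_exact_enumeration_small_groups(self, rng):
        cs = self._curves(rng, 3, 3)
        # 20 distinct group splits: exact enumeration equals a huge MC run
        exact = permutation_threshold(cs, "interaction", n_perm=25, seed=0)
        mc = permutation_threshold(cs, "interaction", n_perm=20000, seed=1)
        assert exact == pytest.approx(mc, rel=0.05)

    def test_fixed_seed_reproducible(self, rng):
        cs = self._curves(rng, 10, 9)
        t1 = permutation_threshold(cs, "interaction", n_perm=300, seed=42)
        t2 = permutation_threshold(cs, "interaction", n_perm=300, seed=42)
        assert t1 == t2

    def test_rft_and_permutation_agree_on_smooth_nulls(self, rng):
        n0 = n1 = 13
        pre = smooth_gaussian_curves(rng, n0 + n1, 101, 12.0)
        post = smooth_gaussian_curves(rng, n0 + n1, 101, 12.0)
        cs = CurveSet(pre=pre, post=post,
                      group=np.array(["a"] * n0 + ["b"] * n1))
        pt = permutation_threshold(cs, "interaction", n_perm=2000, seed=3)
        fw = estimate_fwhm(mixed_anova_residuals(pre, post, cs.group))
        rt = rft_critical_threshold((1, n0 + n1 - 2), fw, 101)
        assert pt == pytest.approx(rt, rel=0.10)

    def test_time_effect_sign_flip_scheme(self, rng):
        cs = self._curves(rng, 4, 4)
        thr = permutation_threshold(cs, "time", n_perm=300, seed=5)
        assert thr > 0


class TestClusters:
    def test_below_threshold_empty(self):
        assert suprathreshold_clusters(np.ones(101), 2.0) == []

    def test_single_bump_spans_expected_nodes(self):
        F = np.zeros(101)
        F[30:61] = 5.0
        [(a, b, m)] = suprathreshold_clusters(F, 2.0)
        assert (a, b) == (30, 61)
        assert m == 5.0

    def test_zero_threshold_single_full_cluster(self):
        F = np.abs(np.sin(np.linspace(0.1, 3.0, 101))) + 0.1
        [(a, b, _)] = suprathreshold_clusters(F, 0.0)
        assert (a, b) == (0, 101)


class TestEndToEnd:
    def test_injected_interaction_cluster_overlaps_true_interval(self, rng):
        # rightward-shift-like effect concentrated on nodes 30..60 for the
        # intervention group only
        n0, n1, Q = 14, 11, 101
        group = np.array(["i"] * n0 + ["c"] * n1)
        hits = 0
        reps = 25
        bump = np.zeros(Q)
        bump[30:61] = np.hanning(31) * 2.0
        for _ in range(reps):
            pre = smooth_gaussian_curves(rng, n0 + n1, Q, 10.0)
            post = smooth_gaussian_curves(rng, n0 + n1, Q, 10.0)
            post[:n0] += bump
            cs = CurveSet(pre=pre, post=post, group=group)
            res = spm_anova(cs)["interaction"]
            for a, b, _ in res.clusters:
                if a < 61 and b > 30:
                    hits += 1
                    break
        assert hits / reps > 0.9

    def test_spm_anova_full_pipeline_fields(self, rng):
        cs = CurveSet(
            pre=smooth_gaussian_curves(rng, 12),
            post=smooth_gaussian_curves(rng, 12),
            group=np.array(["a"] * 6 + ["b"] * 6),
        )
        res = spm_anova(cs)
        for r in res.values():
            assert r.F.shape == (101,)
            assert np.all(r.F >= 0)
            assert r.F_critical > sps.f.isf(0.05, *r.df) - 1e-9
            assert r.resels == pytest.approx(100.0 / r.fwhm)
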