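"""Cohort statistics: outlier exclusion, mixed ANOVA/MANOVA, paired tests,
effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ecctrain.stats import (
    cohens_d_paired,
    manova_mixed,
    mixed_anova_2x2,
    paired_t,
    partial_eta_sq,
    zscore_exclude,
)
from ecctrain.synth import CohortSpec, simulate_cohort


def _table(pre, post, group, parameter="p"):
    n = len(pre)
    return pd.DataFrame({
        "subject": [f"s{i}" for i in range(n)],
        "group": group,
        "parameter": parameter,
        "pre": pre,
        "post": post,
    })


class TestZscoreExclude:
    def test_single_outlier_excluded(self):
        x = [0.0] * 9 + [100.0]
        keep = zscore_exclude(x)
        assert keep.sum() == 9
        assert not keep[-1]

    def test_one_to_ten_all_kept(self):
        keep = zscore_exclude(np.arange(1.0, 11.0))
        assert keep.all()          # max |z| ~ 1.49 < 2.5

    def test_constant_values_warn_and_keep(self):
        with pytest.warns(UserWarning, match="zero standard deviation"):
            assert zscore_exclude(np.full(5, 3.0)).all()

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            zscore_exclude([1.0, 2.0])


class TestMixedAnova:
    def test_zero_noise_zero_effect_gives_zero_f(self):
        pre = np.full(8, 10.0)
        tab = _table(pre, pre, ["a"] * 4 + ["b"] * 4)
        res = mixed_anova_2x2(tab, "p")
        for r in res.values():
            assert r.statistic == 0.0
            assert r.effect_size == 0.0

    def test_matches_pingouin_oracle_balanced(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(10):
            n = 4
            pre = rng.normal(10, 2, 2 * n)
            post = pre + rng.normal(1, 1, 2 * n)
            group = ["a"] * n + ["b"] * n
            res = mixed_anova_2x2(_table(pre, post, group), "p")
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(2 * n), 2),
                "group": np.repeat(group, 2),
                "time": ["pre", "post"] * 2 * n,
                "y": np.column_stack([pre, post]).ravel(),
            })
            ora = pg.mixed_anova(long, dv="y", within="time",
                                 subject="subject", between="group")
            ora = dict(zip(ora["Source"], ora["F"]))
            assert res["group"].statistic == pytest.approx(ora["group"], rel=1e-9)
            assert res["time"].statistic == pytest.approx(ora["time"], rel=1e-9)
            assert res["interaction"].statistic == pytest.approx(
                ora["Interaction"], rel=1e-9
            )

    def test_power_on_generated_effect(self):
        rejections = 0
        for seed in range(40):
            df = simulate_cohort(CohortSpec(
                n_intervention=60, n_control=60,
                baseline_means={"p": 40.0}, effect_pct={"p": 15.0},
                between_subject_sd=8.0, within_subject_sd=2.0, seed=seed,
            ))
            res = mixed_anova_2x2(df, "p")
            rejections += res["interaction"].p < 0.001
        assert rejections / 40 > 0.95

    def test_missing_cell_rejected(self):
        tab = _table([1.0, 2, 3, 4], [2.0, 3, np.nan, 5], ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="missing"):
            mixed_anova_2x2(tab, "p")


class TestManova:
    def _two_dv_table(self, rng, n0=8, n1=7):
        N = n0 + n1
        groups = ["intervention"] * n0 + ["control"] * n1
        frames = []
        for p in ("x", "y"):
            pre = rng.normal(10, 2, N)
            post = pre + rng.normal(1, 1.5, N)
            frames.append(_table(pre, post, groups, p))
        return pd.concat(frames, ignore_index=True)

    def test_single_dv_reduces_to_univariate_anova(self, rng):
        tab = self._two_dv_table(rng)
        res = manova_mixed(tab, ["x"])
        uni = mixed_anova_2x2(tab, "x")
        assert res["interaction"].statistic == pytest.approx(
            uni["interaction"].statistic, rel=1e-10
        )
        assert res["interaction"].effect_size == pytest.approx(
            uni["interaction"].effect_size, rel=1e-10
        )

    def test_published_lambda_effect_size_identity(self):
        # single-df effect: multivariate eta_p^2 = 1 - lambda
        assert 1.0 - 0.691 == pytest.approx(0.309, abs=1e-12)
        from ecctrain.stats import wilks_to_f

        F, df, s = wilks_to_f(0.691, 2, 1, 23)
        assert s == 1.0
        assert df == (2.0, 22.0)
        # the printed omnibus F(2,22)=4.92 at lambda=.691
        assert F == pytest.approx(4.92, abs=0.01)

    def test_wilks_matches_statsmodels_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.multivariate.manova")
        tab = self._two_dv_table(rng)
        res = manova_mixed(tab, ["x", "y"])
        wide = tab.pivot_table(index=["subject", "group"],
                               columns="parameter", values=["pre", "post"])
        d = (wide["post"] - wide["pre"]).reset_index()
        d["g"] = (d["group"] == "intervention").astype(float)
        mv = sm.MANOVA.from_formula("x + y ~ g", data=d)
        lam = mv.mv_test().results["g"]["stat"].loc["Wilks' lambda", "Value"]
        assert res["interaction"].wilks_lambda == pytest.approx(
            float(lam), abs=1e-10
        )

    def test_group_smaller_than_dv_count_rejected(self, rng):
        tab = self._two_dv_table(rng, n0=2, n1=8)
        with pytest.raises(ValueError, match="exceed"):
            manova_mixed(tab, ["x", "y"])


class TestPairedT:
    def test_zero_differences(self):
        r = paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert r.statistic == 0.0
        assert r.p == 1.0

    def test_published_d_p_consistency(self):
        # paired d = t/sqrt(n): the printed (d, p) pairs of the intervention
        # rows (one-sided, n=14) and control rows (two-sided, n=11)
        for d, n, sided, p_expected in [
            (0.692, 14, "one", 0.011),
            (0.593, 14, "one", 0.022),
            (0.539, 14, "one", 0.032),
            (0.632, 11, "two", 0.062),
        ]:
            t = d * np.sqrt(n)
            p = (sps.t.sf(t, n - 1) if sided == "one"
                 else 2 * sps.t.sf(abs(t), n - 1))
            assert round(p, 3) == p_expected

    def test_matches_scipy_oracle(self, rng):
        pre = rng.normal(10, 2, 15)
        post = pre + rng.normal(0.5, 1, 15)
        mine = paired_t(pre, post, sided="two")
        t, p = sps.ttest_rel(post, pre)
        assert mine.statistic == pytest.approx(t, rel=1e-12)
        assert mine.p == pytest.approx(p, rel=1e-12)
        one = paired_t(pre, post, sided="one", direction="increase")
        assert one.p == pytest.approx(
            sps.ttest_rel(post, pre, alternative="greater").pvalue, rel=1e-12
        )

    def test_d_times_sqrt_n_equals_t(self, rng):
        pre = rng.normal(0, 1, 20)
        post = pre + rng.normal(0.3, 0.8, 20)
        d = cohens_d_paired(pre, post)
        t = paired_t(pre, post).statistic
        assert d * np.sqrt(20) == pytest.approx(t, rel=1e-12)

    def test_null_one_sided_p_uniform(self):
        # under the null, one-sided p-values are Uniform(0, 1)
        rng = np.random.default_rng(99)
        diffs = rng.standard_normal((1000, 14))
        t = diffs.mean(axis=1) / (diffs.std(ddof=1, axis=1) / np.sqrt(14))
        pvals = sps.t.sf(t, 13)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestEffectSizes:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [(3.628, 1, 23, 0.136), (4.82, 1, 23, 0.173), (0.0, 1, 23, 0.0)],
    )
    def test_partial_eta_sq_published_values(self, F, df1, df2, expected):
        assert round(partial_eta_sq(F, df1, df2), 3) == expected

    def test_monotone_and_bounded(self):
        vals = [partial_eta_sq(F, 1, 23) for F in (0.0, 1.0, 5.0, 50.0)]
        assert np.all(np.diff(vals) > 0)
        assert all(0.0 <= v < 1.0 for v in vals)

    def test_cohens_d_simple(self):
        # differences (-2, 2, 6): mean 2, sample sd 4 -> d = 0.5
        pre = np.zeros(3)
        post = np.array([-2.0, 2.0, 6.0])
        assert cohens_d_paired(pre, post) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            cohens_d_paired([1.0, 2.0], [2.0, 3.0])  # zero-variance diffs
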