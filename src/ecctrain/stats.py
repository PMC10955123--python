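"""Cohort-level scalar statistics.

Covers the analysis battery of a two-group pre/post training study:
z-score outlier exclusion, 2x2 mixed repeated-measures ANOVA with partial
eta squared, mixed MANOVA (Wilks' lambda on within-subject contrast
variables with Rao's F approximation), hypothesis-dependent paired t-tests
and paired Cohen's d. The group-by-time interaction p is the
"between-group difference" value of a pre/post comparison table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._mixedanova import mixed_anova_2x2_arrays

__all__ = [
    "EffectResult",
    "zscore_exclude",
    "mixed_anova_2x2",
    "manova_mixed",
    "paired_t",
    "cohens_d_paired",
    "partial_eta_sq",
]


@dataclass
class EffectResult:
    """One test statistic with its inference and effect size."""

    name: str
    statistic: float                  # F or t
    df: tuple
    p: float
    sidedness: str = "two"            # "one" | "two"
    effect_size: float | None = None
    effect_size_name: str | None = None
    wilks_lambda: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def zscore_exclude(values, cutoff: float = 2.5) -> np.ndarray:
    """Single-pass outlier mask: True = keep, False = excluded.

    z = (x - mean)/sd with the sample sd; values with |z| >= cutoff are
    excluded. No iterative re-exclusion. Zero spread keeps everything
    (with a warning).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for z-score exclusion")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero standard deviation: no exclusions possible")
        return np.ones(x.size, dtype=bool)
    z = (x - x.mean()) / sd
    return np.abs(z) < cutoff


def _pivot_parameter(table: pd.DataFrame, parameter: str):
    sub = table[table["parameter"] == parameter]
    if sub.empty:
        raise ValueError(f"parameter {parameter!r} not in table")
    if sub[["pre", "post"]].isna().any().any():
        bad = sub.loc[sub[["pre", "post"]].isna().any(axis=1), "subject"]
        raise ValueError(f"missing pre/post cell for subjects {list(bad)}")
    return (
        sub["pre"].to_numpy(float),
        sub["post"].to_numpy(float),
        sub["group"].to_numpy(),
    )


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return F * df1 / (F * df1 + df2)


def mixed_anova_2x2(table: pd.DataFrame, parameter: str) -> dict[str, EffectResult]:
    """Mixed 2x2 ANOVA (group x time) for one cohort-table parameter.

    Expects the long cohort layout (columns subject, group, parameter, pre,
    post). Returns EffectResults for "group", "time" and "interaction".
    """
    pre, post, group = _pivot_parameter(table, parameter)
    res = mixed_anova_2x2_arrays(pre, post, group)
    out = {}
    for name, r in res.items():
        F = float(r["F"][0])
        df1, df2 = r["df"]
        out[name] = EffectResult(
            name=name, statistic=F, df=(df1, df2),
            p=float(sps.f.sf(F, df1, df2)),
            effect_size=partial_eta_sq(F, df1, df2),
            effect_size_name="partial_eta_sq",
        )
    return out


def wilks_to_f(lam: float, p: int, df_h: int, df_e: int):
    """Rao's F approximation for Wilks' lambda (exact when s = 1)."""
    if not (0.0 < lam <= 1.0):
        raise ValueError("lambda must lie in (0, 1]")
    if p**2 + df_h**2 - 5 > 0:
        s = np.sqrt((p**2 * df_h**2 - 4) / (p**2 + df_h**2 - 5))
    else:
        s = 1.0
    m = df_e - (p - df_h + 1) / 2.0
    df1 = p * df_h
    df2 = m * s - p * df_h / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    F = (1.0 - lam_s) / lam_s * df2 / df1
    return float(F), (float(df1), float(df2)), float(s)


def manova_mixed(
    table: pd.DataFrame,
    parameters: list[str],
    effects: tuple = ("time", "interaction"),
) -> dict[str, EffectResult]:
    """Mixed MANOVA over several parameters (group between, time within).

    Works on the within-subject contrast variables d_v = post - pre of each
    dependent variable: the time effect tests the (unweighted) grand mean
    of d, the group-by-time effect the group difference in d. Wilks' lambda
    comes from the hypothesis and error cross-product matrices of the
    cell-means GLM; the multivariate partial eta squared is 1 - lambda^(1/s)
    (= 1 - lambda for single-df effects).
    """
    p = len(parameters)
    if p < 1:
        raise ValueError("need at least one parameter")
    mats = [_pivot_parameter(table, par) for par in parameters]
    group = mats[0][2]
    for _, _, g in mats[1:]:
        if not np.array_equal(g, group):
            raise ValueError("parameters cover different subject sets")
    D = np.column_stack([post - pre for pre, post, _ in mats])  # (N, p)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("need exactly 2 groups")
    N = D.shape[0]
    n0, n1 = int((group == levels[0]).sum()), int((group == levels[1]).sum())
    if min(n0, n1) <= p:
        raise ValueError("each group must exceed the number of DVs")
    # cell-means design: columns = group indicators
    X = np.column_stack([(group == levels[0]).astype(float),
                         (group == levels[1]).astype(float)])
    XtX = X.T @ X
    B = np.linalg.solve(XtX, X.T @ D)            # (2, p) group means of d
    E = D.T @ D - B.T @ XtX @ B                   # residual SSCP, df N-2
    df_e = N - 2
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"singular error matrix (condition number {cond:.3g})")

    contrasts = {
        "time": np.array([[0.5, 0.5]]),           # unweighted grand mean of d
        "interaction": np.array([[1.0, -1.0]]),   # group difference in d
    }
    out = {}
    for name in effects:
        c = contrasts[name]
        cb = c @ B                                # (1, p)
        mid = np.linalg.inv(c @ np.linalg.inv(XtX) @ c.T)
        H = cb.T @ mid @ cb
        lam = float(np.linalg.det(E) / np.linalg.det(E + H))
        F, df, s = wilks_to_f(lam, p, 1, df_e)
        out[name] = EffectResult(
            name=name, statistic=F, df=df,
            p=float(sps.f.sf(F, *df)),
            effect_size=1.0 - lam ** (1.0 / s),
            effect_size_name="partial_eta_sq",
            wilks_lambda=lam,
        )
    return out


def cohens_d_paired(pre, post) -> float:
    """Paired Cohen's d: mean(post - pre) / sd(post - pre) (so d = t/sqrt(n))."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.size < 2 or pre.shape != post.shape:
        raise ValueError("need >= 2 matched pairs")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: d undefined")
    return float(diff.mean() / sd)


def paired_t(
    pre, post, sided: str = "two", direction: str = "increase"
) -> EffectResult:
    """Paired t-test on post - pre differences.

    ``sided="one"`` tests in the hypothesized ``direction`` ("increase":
    post > pre, "decrease": post < pre) -- the convention for
    hypothesis-dependent reporting of pre-registered intervention
    improvements, with two-sided tests elsewhere.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.size < 2 or pre.shape != post.shape:
        raise ValueError("need >= 2 matched pairs")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return EffectResult(
                name="paired_t", statistic=0.0, df=(pre.size - 1,),
                p=1.0 if sided == "two" else 0.5, sidedness=sided,
                effect_size=0.0, effect_size_name="cohens_d",
            )
        raise ValueError("zero-variance differences: t undefined")
    n = pre.size
    t = diff.mean() / (sd / np.sqrt(n))
    dfree = n - 1
    if sided == "two":
        pval = 2.0 * float(sps.t.sf(abs(t), dfree))
    elif sided == "one":
        tt = t if direction == "increase" else -t
        pval = float(sps.t.sf(tt, dfree))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return EffectResult(
        name="paired_t", statistic=float(t), df=(dfree,), p=pval,
        sidedness=sided, effect_size=float(diff.mean() / sd),
        effect_size_name="cohens_d",
    )
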