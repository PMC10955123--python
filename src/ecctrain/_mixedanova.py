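"""Vectorized 2x2 mixed (split-plot) ANOVA core.

One between-subject factor (group, 2 levels, possibly unequal n) and one
within-subject factor (time, 2 levels: pre/post), subject as random
blocking factor. Shared by the scalar cohort statistics and the node-wise
SPM field engine; the field case simply runs all nodes at once along the
trailing axis.

With two within levels the analysis reduces to two orthogonal univariate
strata: subject means m_i = (pre+post)/2 carry the between-group effect,
subject differences d_i = post - pre carry time and group-by-time. Effects
involving time are tested with the unweighted cell-mean (Type III)
contrasts, matching how mixed GLMs are conventionally reported for
unbalanced groups; with balanced groups this coincides with the classic
sums-of-squares decomposition.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["mixed_anova_2x2_arrays", "mixed_anova_residuals"]


def _as2d(x):
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def mixed_anova_2x2_arrays(pre, post, group):
    """F fields for group, time and interaction.

    Parameters
    ----------
    pre, post : (N,) or (N, Q) arrays, one row per subject.
    group : (N,) array-like with exactly two distinct labels.

    Returns
    -------
    dict mapping effect name -> dict(F=(Q,) array, df=(df1, df2)).
    All effects have df1 = 1 and df2 = N - 2.
    """
    pre, post = _as2d(pre), _as2d(post)
    group = np.asarray(group)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have the same shape")
    if group.shape[0] != pre.shape[0]:
        raise ValueError("group labels must match the number of subjects")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.size}")
    g0, g1 = group == levels[0], group == levels[1]
    n0, n1 = int(g0.sum()), int(g1.sum())
    if min(n0, n1) < 2:
        raise ValueError("each group needs at least 2 subjects")
    N = n0 + n1
    df2 = N - 2

    m = 0.5 * (pre + post)            # between stratum
    d = post - pre                    # within stratum

    # --- between: one-way ANOVA on subject means (x2 for two occasions)
    m0, m1 = m[g0].mean(axis=0), m[g1].mean(axis=0)
    grand = m.mean(axis=0)
    ss_group = 2.0 * (n0 * (m0 - grand) ** 2 + n1 * (m1 - grand) ** 2)
    ss_subj = 2.0 * (
        ((m[g0] - m0) ** 2).sum(axis=0) + ((m[g1] - m1) ** 2).sum(axis=0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        F_group = np.where(
            ss_subj > 0, ss_group / (ss_subj / df2), 0.0
        )

    # --- within: pooled variance of differences
    d0, d1 = d[g0].mean(axis=0), d[g1].mean(axis=0)
    sse = ((d[g0] - d0) ** 2).sum(axis=0) + ((d[g1] - d1) ** 2).sum(axis=0)
    sp2 = sse / df2                   # pooled var of d
    inv_n = 1.0 / n0 + 1.0 / n1
    with np.errstate(divide="ignore", invalid="ignore"):
        # time: unweighted mean of group difference-means vs 0
        c_time = 0.5 * (d0 + d1)
        F_time = np.where(sp2 > 0, c_time**2 / (sp2 * 0.25 * inv_n), 0.0)
        # interaction: two-sample comparison of d between groups;
        # scaled to the split-plot error term (var(d) = 2 * MS_error)
        F_int = np.where(sp2 > 0, (d0 - d1) ** 2 / (sp2 * inv_n), 0.0)

    out = {}
    for name, F in (("group", F_group), ("time", F_time),
                    ("interaction", F_int)):
        F = np.clip(np.asarray(F, dtype=float), 0.0, None)
        out[name] = {"F": F, "df": (1, df2)}
    return out


def mixed_anova_residuals(pre, post, group):
    """Model residual fields, one row per subject per stratum.

    Stacks the centered between-stratum fields (m_i - mean within group)
    and within-stratum fields (d_i - mean within group); their smoothness
    drives the null distribution of the maximum F statistic.
    """
    pre, post = _as2d(pre), _as2d(post)
    group = np.asarray(group)
    levels = np.unique(group)
    m = 0.5 * (pre + post)
    d = post - pre
    parts = []
    for lev in levels:
        gi = group == lev
        parts.append(m[gi] - m[gi].mean(axis=0))
        parts.append(d[gi] - d[gi].mean(axis=0))
    return np.vstack(parts)


def f_pvalue(F, df1, df2):
    return float(sps.f.sf(F, df1, df2))
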