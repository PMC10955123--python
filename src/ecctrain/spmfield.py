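"""One-dimensional statistical parametric mapping over torque-angle curves.

At each of the Q (=101) nodes of the common %ROM grid a 2x2 mixed
repeated-measures ANOVA yields F fields for the effects group, time and
group-by-time. Familywise inference over the whole curve uses random field
theory: the field's smoothness (FWHM) is estimated from the normalized
model residuals and the critical threshold is the value whose expected
suprathreshold Euler characteristic equals alpha. A permutation scheme
(max-F distribution under group-label permutation / within-subject time
flips) is provided as a non-parametric alternative and as the oracle the
RFT threshold is validated against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from ._mixedanova import mixed_anova_2x2_arrays, mixed_anova_residuals

__all__ = [
    "CurveSet",
    "SpmFieldResult",
    "anova_field",
    "estimate_fwhm",
    "rft_critical_threshold",
    "permutation_threshold",
    "suprathreshold_clusters",
    "spm_anova",
]

_4LOG2 = 4.0 * math.log(2.0)


@dataclass
class CurveSet:
    """Balanced pre/post curve collection on a common node grid.

    ``pre``/``post``: (N, Q) arrays, one row per subject; ``group``: length-N
    labels (two levels). Every subject must contribute both occasions,
    which the two-array layout enforces by construction.
    """

    pre: np.ndarray
    post: np.ndarray
    group: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pre = np.atleast_2d(np.asarray(self.pre, dtype=float))
        self.post = np.atleast_2d(np.asarray(self.post, dtype=float))
        self.group = np.asarray(self.group)
        if self.pre.shape != self.post.shape:
            raise ValueError("pre and post curve arrays must match in shape")
        if self.group.shape[0] != self.pre.shape[0]:
            raise ValueError("one group label per subject is required")
        if self.subjects is None:
            self.subjects = np.array(
                [f"S{i + 1:03d}" for i in range(self.pre.shape[0])]
            )

    @property
    def n_nodes(self) -> int:
        return int(self.pre.shape[1])

    @property
    def n_subjects(self) -> int:
        return int(self.pre.shape[0])

    @classmethod
    def from_frame(cls, df, value_columns, group_col="group",
                   subject_col="subject", time_col="time"):
        """Build from a long table with one row per subject x time."""
        wide = df.pivot_table(
            index=[subject_col, group_col], columns=time_col,
            values=list(value_columns), sort=True,
        )
        pre = wide.xs("pre", axis=1, level=1).to_numpy()
        post = wide.xs("post", axis=1, level=1).to_numpy()
        if np.isnan(pre).any() or np.isnan(post).any():
            bad = wide.index[np.isnan(pre).any(axis=1) | np.isnan(post).any(axis=1)]
            raise ValueError(f"unbalanced subjects (missing occasion): "
                             f"{[i[0] for i in bad]}")
        groups = np.array([g for _, g in wide.index])
        subs = np.array([s for s, _ in wide.index])
        return cls(pre=pre, post=post, group=groups, subjects=subs)


@dataclass
class SpmFieldResult:
    """Node-wise F field with its familywise inference."""

    effect: str
    F: np.ndarray
    df: tuple
    fwhm: float = float("nan")
    resels: float = float("nan")
    F_critical: float = float("nan")
    alpha: float = 0.05
    clusters: list = field(default_factory=list)   # [(start, stop, max F)]

    @property
    def significant(self) -> bool:
        return bool(len(self.clusters))


def anova_field(curves: CurveSet) -> dict[str, SpmFieldResult]:
    """Per-effect F fields of the 2x2 mixed repeated-measures ANOVA."""
    res = mixed_anova_2x2_arrays(curves.pre, curves.post, curves.group)
    return {
        name: SpmFieldResult(effect=name, F=r["F"], df=r["df"])
        for name, r in res.items()
    }


def estimate_fwhm(residual_fields: np.ndarray) -> float:
    """Field smoothness (FWHM, node units) from normalized residuals.

    The per-node mean squared gradient of the variance-normalized residual
    fields, averaged over nodes, gives v; FWHM = sqrt(4 ln 2 / v). Perfectly
    smooth residuals (v -> 0) are reported as infinite smoothness with a
    warning.
    """
    R = np.atleast_2d(np.asarray(residual_fields, dtype=float))
    if R.shape[0] < 2:
        raise ValueError("need at least 2 residual fields")
    ssq = (R**2).sum(axis=0)
    if np.all(ssq == 0):
        raise ValueError("zero-variance residuals: smoothness undefined")
    grad = np.gradient(R, axis=1)
    v = (grad**2).sum(axis=0) / np.where(ssq > 0, ssq, np.nan)
    vbar = float(np.nanmean(v))
    if vbar <= 0 or not np.isfinite(vbar):
        warnings.warn("effectively infinite smoothness (constant-gradient "
                      "residuals)")
        return float("inf")
    return math.sqrt(_4LOG2 / vbar)


def _ec_density_f_1d(u: float, df: tuple) -> float:
    """1D Euler-characteristic density of an F field (resel units)."""
    k, v = float(df[0]), float(df[1])
    if u <= 0:
        return float("inf")
    loggam = gammaln((v + k - 1.0) / 2.0) - gammaln(v / 2.0) - gammaln(k / 2.0)
    t = k * u / v
    # coefficient sqrt(4 ln 2 / (2 pi)): for k=1 this reduces to twice the
    # one-sided T-field density at sqrt(u), as the F = T^2 identity requires
    return (
        math.sqrt(_4LOG2 / (2.0 * math.pi)) * math.exp(loggam) * math.sqrt(2.0)
        * t ** (0.5 * (k - 1.0)) * (1.0 + t) ** (-0.5 * (v + k - 2.0))
    )


def expected_euler_characteristic(u: float, df: tuple, resels: float) -> float:
    """Expected EC of the suprathreshold set of a smooth 1D F field."""
    return float(sps.f.sf(u, *df)) + resels * _ec_density_f_1d(u, df)


def rft_critical_threshold(
    df: tuple, fwhm: float, Q: int, alpha: float = 0.05
) -> float:
    """Critical F controlling familywise error over the field at alpha.

    Smallest u with expected suprathreshold Euler characteristic <= alpha,
    with resels R = (Q - 1)/FWHM; solved by bisection to 1e-6. In the R -> 0
    (infinitely smooth) limit this is the scalar F quantile.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if df[1] <= 0:
        raise ValueError("df2 must be positive")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    resels = (Q - 1) / fwhm if math.isfinite(fwhm) else 0.0
    lo = float(sps.f.isf(alpha, *df))          # EC >= alpha here
    if resels == 0.0:
        return lo
    hi = lo
    while expected_euler_characteristic(hi, df, resels) > alpha:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("RFT threshold search failed to bracket")
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if expected_euler_characteristic(mid, df, resels) > alpha:
            lo = mid
        else:
            hi = mid
    return hi


def suprathreshold_clusters(F: np.ndarray, F_critical: float) -> list:
    """Maximal runs of consecutive nodes with F > F_critical.

    Returns [(start, stop, max_F)] with half-open 0-based node ranges.
    """
    above = np.asarray(F) > F_critical
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    return [
        (int(a), int(b), float(np.max(F[a:b])))
        for a, b in zip(starts, stops)
    ]


def _max_f(pre, post, group, effect):
    res = mixed_anova_2x2_arrays(pre, post, group)
    return float(res[effect]["F"].max())


def permutation_threshold(
    curves: CurveSet,
    effect: str = "interaction",
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """(1 - alpha) quantile of the max-over-nodes F permutation distribution.

    Exchangeability per effect: group and interaction permute group labels
    between subjects; time flips pre/post within subjects. When the number
    of distinct rearrangements does not exceed ``n_perm``, all are
    enumerated exactly.
    """
    if effect not in ("group", "time", "interaction"):
        raise ValueError(f"unknown effect {effect!r}")
    rng = np.random.default_rng(seed)
    pre, post, group = curves.pre, curves.post, curves.group
    N = curves.n_subjects
    maxf = []
    if effect in ("group", "interaction"):
        levels, counts = np.unique(group, return_counts=True)
        n0 = int(counts[0])
        total = math.comb(N, n0)
        if total <= n_perm:
            for chosen in combinations(range(N), n0):
                lab = np.full(N, levels[1], dtype=group.dtype)
                lab[list(chosen)] = levels[0]
                maxf.append(_max_f(pre, post, lab, effect))
        else:
            for _ in range(n_perm):
                lab = rng.permutation(group)
                maxf.append(_max_f(pre, post, lab, effect))
    else:  # time: sign flips of within-subject differences
        total = 2**N
        if total <= n_perm:
            for signs in product((1.0, -1.0), repeat=N):
                s = np.array(signs)[:, None]
                flip = s < 0
                p2 = np.where(flip, post, pre)
                q2 = np.where(flip, pre, post)
                maxf.append(_max_f(p2, q2, group, effect))
        else:
            for _ in range(n_perm):
                flip = rng.random(N)[:, None] < 0.5
                p2 = np.where(flip, post, pre)
                q2 = np.where(flip, pre, post)
                maxf.append(_max_f(p2, q2, group, effect))
    return float(np.quantile(maxf, 1.0 - alpha))


def spm_anova(
    curves: CurveSet,
    alpha: float = 0.05,
    inference: str = "rft",
    n_perm: int = 10000,
    seed: int | None = None,
) -> dict[str, SpmFieldResult]:
    """Full SPM analysis: F fields, smoothness, threshold, clusters."""
    results = anova_field(curves)
    resid = mixed_anova_residuals(curves.pre, curves.post, curves.group)
    fwhm = estimate_fwhm(resid)
    Q = curves.n_nodes
    for name, r in results.items():
        r.alpha = alpha
        r.fwhm = fwhm
        r.resels = (Q - 1) / fwhm if math.isfinite(fwhm) else 0.0
        if inference == "rft":
            r.F_critical = rft_critical_threshold(r.df, fwhm, Q, alpha)
        elif inference == "perm":
            r.F_critical = permutation_threshold(
                curves, name, n_perm=n_perm, alpha=alpha, seed=seed
            )
        else:
            raise ValueError(f"unknown inference {inference!r}")
        r.clusters = suprathreshold_clusters(r.F, r.F_critical)
    return results
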