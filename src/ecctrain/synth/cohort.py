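"""Synthetic pre/post cohort tables with a known group-by-time effect.

Each subject has a random intercept shared by pre and post (between-subject
variability) plus independent occasion noise (within-subject variability).
Intervention post-test means are shifted by a configurable percent effect;
control post-test means are unshifted. Defaults follow the study
conditions: 14 intervention vs 11 control subjects and the cohort's body
mass distribution (84.8 +- 11.3 kg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "simulate_cohort"]


def _per_param(value, name: str, params: dict) -> dict:
    if isinstance(value, dict):
        missing = set(params) - set(value)
        if missing:
            raise ValueError(f"{name} missing entries for {sorted(missing)}")
        return dict(value)
    return {p: float(value) for p in params}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated two-group pre/post cohort.

    ``baseline_means`` maps parameter name -> pre-test population mean;
    ``effect_pct`` maps parameter name -> percent change applied to the
    intervention group's post mean (parameters absent from the map get 0 %).
    SDs may be scalars (shared by all parameters) or per-parameter maps.
    """

    n_intervention: int = 14
    n_control: int = 11
    baseline_means: dict = field(
        default_factory=lambda: {"ecc_peak_30": 39.56}
    )
    effect_pct: dict = field(default_factory=dict)
    between_subject_sd: float | dict = 8.0
    within_subject_sd: float | dict = 2.0
    body_mass_mean: float = 84.8
    body_mass_sd: float = 11.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intervention < 2 or self.n_control < 2:
            raise ValueError("group sizes must be >= 2")
        for sd in (self.between_subject_sd, self.within_subject_sd):
            vals = sd.values() if isinstance(sd, dict) else [sd]
            if any(v < 0 for v in vals):
                raise ValueError("standard deviations must be >= 0")
        if self.body_mass_sd < 0:
            raise ValueError("body_mass_sd must be >= 0")
        unknown = set(self.effect_pct) - set(self.baseline_means)
        if unknown:
            raise ValueError(f"effect_pct for unknown parameters {sorted(unknown)}")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Long-format cohort table: one row per subject x parameter.

    Columns: subject, group, body_mass, parameter, pre, post.
    Draw order (fixed contract): body masses, then per parameter the
    subject intercepts, then the pre noise, then the post noise.
    """
    params = list(spec.baseline_means)
    sd_b = _per_param(spec.between_subject_sd, "between_subject_sd", spec.baseline_means)
    sd_w = _per_param(spec.within_subject_sd, "within_subject_sd", spec.baseline_means)

    n = spec.n_intervention + spec.n_control
    groups = np.array(
        ["intervention"] * spec.n_intervention + ["control"] * spec.n_control
    )
    streams = np.random.SeedSequence(spec.seed).spawn(1 + len(params))
    rng_mass = np.random.default_rng(streams[0])
    body_mass = rng_mass.normal(spec.body_mass_mean, spec.body_mass_sd, n)
    body_mass = np.clip(body_mass, 40.0, None)

    rows = []
    for k, p in enumerate(params):
        rng = np.random.default_rng(streams[1 + k])
        mu = spec.baseline_means[p]
        effect = spec.effect_pct.get(p, 0.0)
        intercept = rng.normal(0.0, sd_b[p], n)
        e_pre = rng.normal(0.0, sd_w[p], n)
        e_post = rng.normal(0.0, sd_w[p], n)
        pre = mu + intercept + e_pre
        post_mu = np.where(
            groups == "intervention", mu * (1.0 + effect / 100.0), mu
        )
        post = post_mu + intercept + e_post
        for i in range(n):
            rows.append(
                (f"S{i + 1:03d}", groups[i], body_mass[i], p, pre[i], post[i])
            )
    return pd.DataFrame(
        rows, columns=["subject", "group", "body_mass", "parameter", "pre", "post"]
    )
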