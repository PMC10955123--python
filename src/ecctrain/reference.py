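"""Bundled published summary tables and their recomputation.

The study's subject-level data is not shipped; its published group-level
summaries (pre/post means, SDs, percent changes, p and d per parameter,
plus the omnibus test statistics) are bundled as plain-text data. From
those printed means the pipeline recomputes the derived quantities --
percent change, partial eta squared from F and df, the Wilks-lambda
effect-size identity, and the paired t <-> d consistency -- as worked
examples of the same routines used on synthetic cohorts.
"""

from __future__ import annotations

import importlib.resources as resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import partial_eta_sq
from .strength import percent_change

__all__ = [
    "load_reference_outcomes",
    "load_reference_statistics",
    "recompute_percent_changes",
    "recompute_effect_sizes",
    "d_to_paired_p",
]


def _data_path(name: str):
    return resources.files("ecctrain.data").joinpath(name)


def load_reference_outcomes() -> pd.DataFrame:
    """Published per-parameter group summaries (three outcome tables)."""
    with resources.as_file(_data_path("reference_outcomes.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_reference_statistics() -> dict:
    import json

    with resources.as_file(_data_path("reference_statistics.json")) as p:
        return json.loads(p.read_text())


def recompute_percent_changes(atol: float = 0.005) -> pd.DataFrame:
    """Percent change from the printed group means, against the printed value.

    Adds ``delta_pct_computed`` and ``consistent`` -- whether the printed
    value equals the recomputed one to two decimals (|difference| < 0.005
    plus two-decimal rounding slack of the means themselves, taken as a
    0.01-level agreement on the result). Rows failing this are printing
    artifacts (sign dropped or a transcription slip), not computation
    differences.
    """
    df = load_reference_outcomes().copy()
    df["delta_pct_computed"] = [
        percent_change(row.pre_mean, row.post_mean) for row in df.itertuples()
    ]
    # the printed means are rounded to 2 decimals; propagate that rounding
    # into a per-row tolerance for the recomputed percent change
    slack = 100.0 * (
        0.005 / df["pre_mean"].abs()
        + 0.005 * (df["post_mean"] / df["pre_mean"] ** 2).abs()
    )
    df["consistent"] = (
        (df["delta_pct_computed"].round(2) - df["delta_pct"]).abs()
        <= (atol + slack)
    )
    return df


def recompute_effect_sizes() -> pd.DataFrame:
    """Partial eta squared from printed F/df and 1 - lambda from printed
    Wilks' lambda, against the printed effect sizes."""
    ref = load_reference_statistics()
    rows = []
    for item in ref["anova"]:
        val = partial_eta_sq(item["F"], *item["df"])
        rows.append(
            ("anova", item["name"], val, item["partial_eta_sq"])
        )
    for item in ref["manova"]:
        # single-df effects: s = 1, so the multivariate eta_p^2 is 1 - lambda
        val = 1.0 - item["wilks_lambda"]
        rows.append(
            ("manova", item["name"], val, item["partial_eta_sq"])
        )
    out = pd.DataFrame(
        rows, columns=["kind", "name", "computed", "printed"]
    )
    out["consistent"] = (out["computed"].round(3) - out["printed"]).abs() < 5e-4
    return out


def d_to_paired_p(d: float, n: int, sided: str = "one") -> float:
    """p-value implied by a paired Cohen's d at sample size n (t = d*sqrt(n))."""
    t = d * np.sqrt(n)
    if sided == "one":
        return float(sps.t.sf(t, n - 1))
    return float(2.0 * sps.t.sf(abs(t), n - 1))
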