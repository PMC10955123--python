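"""Per-subject strength summaries and pre/post change metrics.

The maximum and mean torque over the isokinetic phase summarize each
repetition; per-subject values aggregate repetitions (best repetition's
peak, mean of repetition means -- both rules configurable). Percent change
is computed from absolute (non-normalized) group means, matching how
pre/post tables in this field report it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isokin import IsokineticPhase

__all__ = [
    "StrengthRecord",
    "torque_summary",
    "aggregate_repetitions",
    "percent_change",
]


@dataclass
class StrengthRecord:
    subject: str
    group: str
    time: str                 # "pre" | "post"
    mode: str                 # "eccentric" | "concentric"
    speed: float              # deg/s
    peak_torque: float        # Nm
    mean_torque: float        # Nm
    body_mass: float | None = None

    @property
    def peak_torque_norm(self) -> float | None:
        return None if not self.body_mass else self.peak_torque / self.body_mass

    @property
    def mean_torque_norm(self) -> float | None:
        return None if not self.body_mass else self.mean_torque / self.body_mass


def torque_summary(phase: IsokineticPhase | np.ndarray) -> tuple[float, float]:
    """(peak, mean) torque over an isokinetic interval (sample mean)."""
    torque = phase.torque if isinstance(phase, IsokineticPhase) else np.asarray(phase, float)
    if torque.size == 0:
        raise ValueError("empty isokinetic phase")
    return float(torque.max()), float(torque.mean())


def aggregate_repetitions(
    summaries: list[tuple[float, float]],
    peak_rule: str = "max",
    mean_rule: str = "mean",
) -> tuple[float, float]:
    """Per-subject (peak, mean) from repetition-level summaries.

    Default: the best repetition's peak and the mean across repetition
    means.
    """
    if not summaries:
        raise ValueError("no repetition summaries")
    peaks = np.array([s[0] for s in summaries])
    means = np.array([s[1] for s in summaries])
    peak = float(peaks.max() if peak_rule == "max" else peaks.mean())
    mean = float(means.mean() if mean_rule == "mean" else means.max())
    return peak, mean


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre."""
    if pre == 0:
        raise ValueError("pre value must be nonzero for percent change")
    return 100.0 * (post - pre) / pre
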