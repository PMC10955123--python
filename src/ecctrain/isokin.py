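"""Isokinetic dynamometer preprocessing.

Raw dynamometer trials (angle/torque/velocity sampled at 200 Hz) are
low-pass filtered with a zero-lag Butterworth filter, cut into repetitions
by movement direction, reduced to the constant-velocity (isokinetic) phase
of each repetition, normalized to body mass and interpolated onto a fixed
101-node 0-100 %ROM grid for curve-level statistics.

Angle convention: 0 deg = lever arm perpendicular to the body; positive
angles = external rotation. Positive velocity therefore moves toward
external rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "DynamometerTrial",
    "RepetitionSegment",
    "IsokineticPhase",
    "NormalizedTorqueCurve",
    "filter_zero_lag",
    "filter_trial",
    "segment_repetitions",
    "extract_isokinetic_phase",
    "normalize_to_body_mass",
    "to_normalized_curve",
]


@dataclass
class DynamometerTrial:
    """One recorded dynamometer trial on a uniform time grid.

    ``meta`` carries at least ``mode`` (concentric/eccentric/passive),
    ``direction``, ``target_speed`` (deg/s), ``body_mass`` (kg) and
    ``sampling_rate`` (Hz).
    """

    time: np.ndarray        # s
    angle: np.ndarray       # deg
    torque: np.ndarray      # Nm
    velocity: np.ndarray    # deg/s, signed
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        n = self.time.size
        if not (self.angle.size == self.torque.size == self.velocity.size == n):
            raise ValueError("time/angle/torque/velocity must have equal length")
        if n >= 2:
            dt = np.median(np.diff(self.time))
            fs = self.meta.get("sampling_rate")
            if fs is not None and abs(dt - 1.0 / fs) > 1e-6:
                raise ValueError(
                    f"sampling_rate {fs} Hz inconsistent with median time step {dt} s"
                )
        mass = self.meta.get("body_mass")
        if mass is not None and mass <= 0:
            raise ValueError("body_mass must be positive")

    @property
    def sampling_rate(self) -> float:
        fs = self.meta.get("sampling_rate")
        if fs is None:
            fs = 1.0 / np.median(np.diff(self.time))
        return float(fs)

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class RepetitionSegment:
    """Half-open sample range [start, stop) of one directional movement."""

    start: int
    stop: int
    direction: str                     # "internal" | "external"
    trial: DynamometerTrial

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("segment must be non-empty")

    @property
    def angle(self) -> np.ndarray:
        return self.trial.angle[self.start:self.stop]

    @property
    def torque(self) -> np.ndarray:
        return self.trial.torque[self.start:self.stop]

    @property
    def velocity(self) -> np.ndarray:
        return self.trial.velocity[self.start:self.stop]


@dataclass
class IsokineticPhase:
    """Constant-velocity portion of a repetition.

    ``start``/``stop`` are absolute (trial-level) half-open sample indices.
    """

    start: int
    stop: int
    segment: RepetitionSegment
    achieved_speed: float              # mean |velocity| over the phase, deg/s

    @property
    def angle(self) -> np.ndarray:
        return self.segment.trial.angle[self.start:self.stop]

    @property
    def torque(self) -> np.ndarray:
        return self.segment.trial.torque[self.start:self.stop]

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class NormalizedTorqueCurve:
    """Torque (Nm/kg) on an equally spaced 0-100 %ROM grid (101 nodes)."""

    torque: np.ndarray                 # Nm/kg, length n_nodes
    angle_start: float                 # deg, grid endpoint at 0 %ROM
    angle_end: float                   # deg, grid endpoint at 100 %ROM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.torque = np.asarray(self.torque, dtype=float)

    @property
    def n_nodes(self) -> int:
        return int(self.torque.size)

    @property
    def rom_percent(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_nodes)

    @property
    def angle_grid(self) -> np.ndarray:
        return np.linspace(self.angle_start, self.angle_end, self.n_nodes)


def filter_zero_lag(
    series: Sequence[float],
    sampling_rate: float,
    cutoff: float = 6.0,
    order: int = 5,
) -> np.ndarray:
    """Forward-backward (zero phase lag) Butterworth low-pass filter.

    The filter is designed at ``order`` and applied in both time directions,
    so the net phase shift is zero and the effective attenuation is the
    squared magnitude response.
    """
    x = np.asarray(series, dtype=float)
    if cutoff >= sampling_rate / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = butter(order, cutoff, btype="low", fs=sampling_rate)
    padlen = 3 * max(len(a), len(b))
    if x.size <= padlen:
        raise ValueError(
            f"series too short for zero-lag filtering: need more than "
            f"{padlen} samples, got {x.size}"
        )
    return filtfilt(b, a, x)


def filter_trial(
    trial: DynamometerTrial, cutoff: float = 6.0, order: int = 5
) -> DynamometerTrial:
    """Return a copy of the trial with torque, angle and velocity filtered."""
    fs = trial.sampling_rate
    return DynamometerTrial(
        time=trial.time.copy(),
        angle=filter_zero_lag(trial.angle, fs, cutoff, order),
        torque=filter_zero_lag(trial.torque, fs, cutoff, order),
        velocity=filter_zero_lag(trial.velocity, fs, cutoff, order),
        meta=dict(trial.meta),
    )


def segment_repetitions(
    trial: DynamometerTrial,
    min_duration_s: float = 0.1,
    velocity_eps: float = 1e-9,
) -> list[RepetitionSegment]:
    """Cut a trial into directional repetitions at velocity zero-crossings.

    Runs of constant velocity sign delimit movements; runs shorter than
    ``min_duration_s`` are treated as chatter and merged into neighbours by
    being dropped. Positive velocity maps to "external", negative to
    "internal".
    """
    v = trial.velocity
    sign = np.sign(v)
    sign[np.abs(v) <= velocity_eps] = 0.0
    # carry last nonzero sign through exact zeros so a touch of v=0 does not
    # split a movement
    nonzero = sign != 0
    if not nonzero.any():
        warnings.warn("velocity has no nonzero samples; returning one segment")
        return [RepetitionSegment(0, len(trial), "external", trial)]
    idx = np.where(nonzero, np.arange(v.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, sign[np.clip(idx, 0, None)], 0.0)
    # leading zeros inherit the first nonzero sign
    first = np.argmax(nonzero)
    filled[:first] = sign[first]

    changes = np.flatnonzero(np.diff(filled) != 0) + 1
    bounds = np.concatenate(([0], changes, [v.size]))
    min_len = int(round(min_duration_s * trial.sampling_rate))
    segments: list[RepetitionSegment] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < max(min_len, 1):
            continue
        direction = "external" if filled[a] > 0 else "internal"
        segments.append(RepetitionSegment(int(a), int(b), direction, trial))
    if not segments:
        warnings.warn("no movement run exceeded the minimum duration; "
                      "returning one segment")
        direction = "external" if filled[first] > 0 else "internal"
        segments = [RepetitionSegment(0, len(trial), direction, trial)]
    return segments


def extract_isokinetic_phase(
    seg: RepetitionSegment,
    target_speed: float,
    tol_fraction: float = 0.10,
) -> IsokineticPhase:
    """Longest contiguous run with |velocity| within +-tol of the target.

    Acceleration and deceleration samples fall outside the band and are
    thereby excluded.
    """
    if target_speed <= 0:
        raise ValueError("target_speed must be positive")
    speed = np.abs(seg.velocity)
    lo = (1.0 - tol_fraction) * target_speed
    hi = (1.0 + tol_fraction) * target_speed
    ok = (speed >= lo) & (speed <= hi)
    if not ok.any():
        raise ValueError(
            f"no isokinetic phase: no sample within +-{tol_fraction:.0%} of "
            f"{target_speed} deg/s"
        )
    # longest run of True
    padded = np.concatenate(([False], ok, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    k = int(np.argmax(stops - starts))
    a, b = int(starts[k]), int(stops[k])
    achieved = float(speed[a:b].mean())
    return IsokineticPhase(seg.start + a, seg.start + b, seg, achieved)


def normalize_to_body_mass(torque, body_mass: float) -> np.ndarray:
    """Torque in Nm/kg: element-wise division by body mass."""
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    return np.asarray(torque, dtype=float) / body_mass


def to_normalized_curve(
    phase: IsokineticPhase,
    n_nodes: int = 101,
    body_mass: float | None = None,
    meta: dict | None = None,
) -> NormalizedTorqueCurve:
    """Linear interpolation of phase torque onto ``n_nodes`` equal angles.

    The grid spans the phase's angle extremes in movement order, so node 0
    is 0 %ROM at the phase start angle and the last node is 100 %ROM.
    Duplicate angles are averaged before interpolation; endpoints are
    preserved exactly.
    """
    angle = phase.angle
    torque = phase.torque
    if body_mass is None:
        body_mass = phase.segment.trial.meta.get("body_mass", 1.0)
    torque = normalize_to_body_mass(torque, body_mass)
    a0, a1 = float(angle[0]), float(angle[-1])
    if np.ptp(angle) < 1e-12 or a0 == a1:
        raise ValueError("degenerate angle span: phase covers no angular range")
    # sort into increasing angle and average duplicates
    order = np.argsort(angle, kind="stable")
    asort, tsort = angle[order], torque[order]
    uniq, inv, counts = np.unique(asort, return_inverse=True, return_counts=True)
    tmean = np.bincount(inv, weights=tsort) / counts
    if uniq.size < 2:
        raise ValueError("degenerate angle span: fewer than 2 distinct angles")
    grid = np.linspace(min(a0, a1), max(a0, a1), n_nodes)
    vals = np.interp(grid, uniq, tmean)
    if a0 > a1:  # movement toward decreasing angle: keep movement order
        grid_start, grid_end = a0, a1
        vals = vals[::-1]
    else:
        grid_start, grid_end = a0, a1
    return NormalizedTorqueCurve(
        torque=vals, angle_start=grid_start, angle_end=grid_end,
        meta=dict(meta or {}),
    )
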