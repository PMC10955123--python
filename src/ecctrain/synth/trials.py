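"""Synthetic isokinetic dynamometer trials.

Active (concentric/eccentric) trials follow a trapezoidal velocity profile
per repetition -- ramp up over ``accel_time``, hold the commanded speed,
ramp down -- with a smooth unimodal (Gaussian-in-angle) torque bell peaking
at a configurable optimum angle. Passive trials advance at the slow test
speed while torque grows as the three-parameter exponential
``T(theta) = a*exp(b*theta) + c`` and motion reverses at a torque threshold
(9 Nm) or an angle cap, whichever comes first. Ground-truth structure
(plateau sample ranges, reversal angles) is returned alongside every trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..isokin import DynamometerTrial

__all__ = ["TrialSpec", "simulate_active_trial", "simulate_passive_trial"]

PASSIVE_TORQUE_LIMIT_NM = 9.0     # reversal criterion of the passive ROM test


@dataclass(frozen=True)
class TrialSpec:
    """Protocol parameters of one simulated dynamometer trial."""

    mode: str                        # "concentric" | "eccentric" | "passive"
    direction: str = "external"      # "internal" | "external"
    target_speed: float = 30.0       # deg/s (10 for passive tests)
    rom_start: float = -60.0         # deg
    rom_end: float = 90.0            # deg
    sampling_rate: float = 200.0     # Hz
    accel_time: float = 0.2          # s, ramp duration of the trapezoid
    noise_sd_torque: float = 0.25    # Nm, additive Gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("concentric", "eccentric", "passive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.direction not in ("internal", "external"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.rom_end - self.rom_start <= 0:
            raise ValueError("rom_end must exceed rom_start")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.target_speed <= 0:
            raise ValueError("target_speed must be positive")
        if self.noise_sd_torque < 0:
            raise ValueError("noise_sd_torque must be >= 0")


def _trapezoid_profile(spec: TrialSpec):
    """Closed-form kinematics of one repetition.

    Returns (rep_duration, plateau_t0, plateau_t1, displacement) where the
    plateau interval holds |velocity| = target exactly.
    """
    D = spec.rom_end - spec.rom_start
    v = spec.target_speed
    ta = spec.accel_time
    plateau = (D - v * ta) / v        # ramps each travel v*ta/2
    if plateau <= 0:
        raise ValueError(
            "no isokinetic plateau: accel_time too long for the commanded ROM"
        )
    return ta + plateau + ta, ta, ta + plateau, D


def _rep_kinematics(tau: np.ndarray, spec: TrialSpec):
    """Velocity magnitude and displacement at local rep times ``tau``."""
    v = spec.target_speed
    ta = spec.accel_time
    T, t0, t1, D = _trapezoid_profile(spec)
    vel = np.where(
        tau < t0, v * tau / ta,
        np.where(tau < t1, v, np.clip(v * (T - tau) / ta, 0.0, v)),
    )
    disp = np.where(
        tau < t0, 0.5 * v * tau**2 / ta,
        np.where(
            tau < t1, 0.5 * v * ta + v * (tau - t0),
            D - 0.5 * v * np.clip(T - tau, 0.0, ta) ** 2 / ta,
        ),
    )
    return vel, disp


def simulate_active_trial(
    spec: TrialSpec,
    peak_torque: float = 40.0,
    optimum_angle: float = 20.0,
    n_reps: int = 3,
    bell_width: float = 35.0,
) -> tuple[DynamometerTrial, dict]:
    """Simulate an active strength trial with ``n_reps`` alternating reps.

    Each repetition is one out-and-back cycle: a movement from
    ``rom_start`` to ``rom_end`` (positive velocity, external direction)
    followed by the return movement, so a 3-repetition trial contains 3
    movements per direction. Torque is
    ``peak_torque * exp(-(angle-optimum)^2 / (2*bell_width^2))`` plus
    Gaussian noise. Ground truth contains the half-open plateau sample
    range of every movement and the bell parameters.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_mov = 2 * n_reps
    T_rep, t0, t1, D = _trapezoid_profile(spec)
    fs = spec.sampling_rate
    n_total = int(round(n_mov * T_rep * fs))
    t = np.arange(n_total) / fs
    rep = np.minimum((t / T_rep).astype(int), n_mov - 1)
    tau = t - rep * T_rep
    vel_mag, disp = _rep_kinematics(tau, spec)
    forward = rep % 2 == 0
    velocity = np.where(forward, vel_mag, -vel_mag)
    angle = np.where(forward, spec.rom_start + disp, spec.rom_end - disp)

    torque_clean = peak_torque * np.exp(
        -((angle - optimum_angle) ** 2) / (2.0 * bell_width**2)
    )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    torque = torque_clean + rng.normal(0.0, spec.noise_sd_torque, n_total)

    plateaus = []
    for r in range(n_mov):
        in_plateau = (rep == r) & (tau >= t0) & (tau < t1)
        idx = np.flatnonzero(in_plateau)
        plateaus.append((int(idx[0]), int(idx[-1] + 1)))

    trial = DynamometerTrial(
        time=t, angle=angle, torque=torque, velocity=velocity,
        meta={
            "mode": spec.mode, "direction": spec.direction,
            "target_speed": spec.target_speed,
            "sampling_rate": spec.sampling_rate,
        },
    )
    truth = {
        "plateau_ranges": plateaus,
        "plateau_duration_s": t1 - t0,
        "peak_torque": peak_torque,
        "optimum_angle": optimum_angle,
        "bell_width": bell_width,
        "rep_duration_s": T_rep,
    }
    return trial, truth


def passive_reversal_angle(
    a: float, b: float, c: float,
    threshold: float = PASSIVE_TORQUE_LIMIT_NM,
    angle_cap: float | None = None,
) -> float:
    """Angle at which passive torque reaches ``threshold``, or the cap.

    Inverts ``a*exp(b*theta) + c = threshold``. When the torque never
    reaches the threshold the cap is returned; with no cap either, raises.
    """
    theta_inf = math.inf
    if a > 0 and b > 0 and threshold > c:
        theta_inf = math.log((threshold - c) / a) / b
    if angle_cap is not None:
        return min(theta_inf, angle_cap)
    if math.isinf(theta_inf):
        raise ValueError(
            "passive torque never reaches the reversal threshold and no "
            "angle cap is set"
        )
    return theta_inf


def simulate_passive_trial(
    spec: TrialSpec,
    stiffness_params: tuple[float, float, float] = (0.5, 0.05, 0.0),
    n_cycles: int = 10,
) -> tuple[DynamometerTrial, dict]:
    """Simulate a passive ROM test of ``n_cycles`` stretch-return cycles.

    The lever advances from ``rom_start`` at the passive test speed; motion
    reverses when the noiseless torque model reaches 9 Nm or the angle cap
    (``rom_end``), then returns to ``rom_start``. Each cycle contributes one
    stretch and one return movement (so velocity-sign segmentation yields
    ``2*n_cycles`` segments).
    """
    if spec.mode != "passive":
        raise ValueError("simulate_passive_trial requires mode='passive'")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    a, b, c = stiffness_params
    cap = spec.rom_end if math.isfinite(spec.rom_end) else None
    theta_rev = passive_reversal_angle(a, b, c, angle_cap=cap)
    if theta_rev <= spec.rom_start:
        raise ValueError("reversal angle not beyond rom_start")

    v = spec.target_speed
    fs = spec.sampling_rate
    half = (theta_rev - spec.rom_start) / v        # s, one-way duration
    T_cyc = 2.0 * half
    n_total = int(round(n_cycles * T_cyc * fs))
    t = np.arange(n_total) / fs
    cyc = np.minimum((t / T_cyc).astype(int), n_cycles - 1)
    tau = t - cyc * T_cyc
    stretching = tau < half
    angle = np.where(
        stretching,
        spec.rom_start + v * tau,
        theta_rev - v * np.clip(tau - half, 0.0, half),
    )
    velocity = np.where(stretching, v, -v)

    torque_clean = a * np.exp(b * angle) + c
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    torque = torque_clean + rng.normal(0.0, spec.noise_sd_torque, n_total)

    trial = DynamometerTrial(
        time=t, angle=angle, torque=torque, velocity=velocity,
        meta={
            "mode": "passive", "direction": spec.direction,
            "target_speed": v, "sampling_rate": fs,
        },
    )
    truth = {
        "reversal_angle": theta_rev,
        "stiffness_params": (a, b, c),
        "n_cycles": n_cycles,
        "cycle_duration_s": T_cyc,
    }
    return trial, truth
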