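"""Passive and active flexibility analysis.

Passive torque-angle curves (averaged over repeated stretch trials) are
fitted with the three-parameter exponential ``T(theta) = a*exp(b*theta) + c``.
Inverting the fit at a torque threshold gives range of motion: maximal ROM
at the 9 Nm test criterion (capped at the device's angle limit, 100 deg
internal / 140 deg external rotation) and submaximal ROM at a configurable
lower threshold (default 4.5 Nm, half the maximal criterion -- a stand-in,
exposed in config). Active ROM is the mean extreme angle over cycles of an
active stretch trial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .isokin import DynamometerTrial

__all__ = [
    "PassiveFitResult",
    "average_passive_trials",
    "fit_efunction",
    "rom_at_torque",
    "rom_submax",
    "with_rom",
    "active_rom",
    "TORQUE_THRESHOLD_NM",
    "SUBMAX_THRESHOLD_NM",
    "ANGLE_CAP_INTERNAL",
    "ANGLE_CAP_EXTERNAL",
]

TORQUE_THRESHOLD_NM = 9.0
SUBMAX_THRESHOLD_NM = 4.5
ANGLE_CAP_INTERNAL = 100.0
ANGLE_CAP_EXTERNAL = 140.0


@dataclass
class PassiveFitResult:
    """Three-parameter exponential fit with derived ROM values."""

    a: float                  # Nm
    b: float                  # 1/deg
    c: float                  # Nm
    rmse: float               # Nm
    converged: bool = True
    degenerate: bool = False  # near-linear data: b ~ 0, large uncertainty
    rom_max: float | None = None
    rom_sub: float | None = None
    torque_threshold_used: float = TORQUE_THRESHOLD_NM

    def torque(self, angle) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(angle, float)) + self.c


def average_passive_trials(
    curves: list[tuple[np.ndarray, np.ndarray]],
    n_expected: int = 5,
    n_grid: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise average of repeated (angle, torque) stretch curves.

    Trials are resampled onto a common angle grid spanning the intersection
    of their angle supports, then averaged. Raises when the supports do not
    overlap.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 trials to average")
    if len(curves) != n_expected:
        warnings.warn(
            f"averaging {len(curves)} trials (protocol expects {n_expected})"
        )
    lo = max(float(np.min(a)) for a, _ in curves)
    hi = min(float(np.max(a)) for a, _ in curves)
    if hi <= lo:
        raise ValueError("trial angle supports are disjoint")
    grid = np.linspace(lo, hi, n_grid)
    vals = []
    for ang, trq in curves:
        ang = np.asarray(ang, float)
        trq = np.asarray(trq, float)
        order = np.argsort(ang, kind="stable")
        vals.append(np.interp(grid, ang[order], trq[order]))
    return grid, np.mean(vals, axis=0)


def _init_efunction(angle: np.ndarray, torque: np.ndarray):
    """Deterministic starting values: log-linear regression on first
    differences for b, then linear solve for a and c."""
    d_t = np.diff(torque)
    d_a = np.diff(angle)
    slope = d_t / np.where(d_a == 0, np.nan, d_a)
    mid = 0.5 * (angle[:-1] + angle[1:])
    ok = np.isfinite(slope) & (slope > 0)
    if ok.sum() >= 2:
        # dT/dtheta = a*b*exp(b*theta): slope of log is b
        coef = np.polyfit(mid[ok], np.log(slope[ok]), 1)
        b0 = float(coef[0])
    else:
        b0 = 0.0
    if abs(b0) < 1e-6:
        b0 = 1e-3
    basis = np.exp(b0 * angle)
    A = np.column_stack([basis, np.ones_like(angle)])
    (a0, c0), *_ = np.linalg.lstsq(A, torque, rcond=None)
    return float(a0), b0, float(c0)


def fit_efunction(angle, torque) -> PassiveFitResult:
    """Least-squares fit of ``T(theta) = a*exp(b*theta) + c``.

    Initialization is deterministic (no random restarts); convergence is
    required to 1e-10 on the parameters, otherwise the result is flagged
    ``converged=False``. Near-linear data is flagged ``degenerate`` (b has
    essentially no curvature information).
    """
    angle = np.asarray(angle, dtype=float)
    torque = np.asarray(torque, dtype=float)
    if angle.size < 10:
        raise ValueError("need at least 10 points for a stable fit")
    if np.ptp(angle) < 20.0:
        raise ValueError("angle range must span at least 20 deg")
    x0 = _init_efunction(angle, torque)

    def resid(p):
        a, b, c = p
        return a * np.exp(np.clip(b * angle, -700, 700)) + c - torque

    sol = least_squares(
        resid, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        max_nfev=5000,
    )
    a, b, c = sol.x
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    # curvature information: does exp(b*theta) differ measurably from a line?
    span = np.ptp(angle)
    degenerate = abs(b) * span < 1e-3
    if degenerate:
        warnings.warn(
            "near-linear torque-angle data: b is ~0 with large uncertainty"
        )
    return PassiveFitResult(
        a=float(a), b=float(b), c=float(c), rmse=rmse,
        converged=bool(sol.status > 0), degenerate=degenerate,
    )


def rom_at_torque(
    fit: PassiveFitResult,
    threshold: float = TORQUE_THRESHOLD_NM,
    angle_cap: float = ANGLE_CAP_INTERNAL,
) -> float:
    """Angle at which the fitted torque reaches ``threshold``, capped.

    Inversion: ``theta = ln((threshold - c)/a) / b``, evaluated in the
    tested direction's own increasing coordinate. When the asymptote lies
    at or above the threshold (threshold <= c) the cap is returned with a
    warning.
    """
    if threshold <= fit.c:
        warnings.warn(
            "torque asymptote lies below the threshold; returning angle cap"
        )
        return float(angle_cap)
    if fit.a <= 0 or fit.b == 0:
        return float(angle_cap)
    theta = math.log((threshold - fit.c) / fit.a) / fit.b
    return float(min(theta, angle_cap))


def rom_submax(
    fit: PassiveFitResult,
    sub_threshold: float = SUBMAX_THRESHOLD_NM,
    angle_cap: float = ANGLE_CAP_INTERNAL,
) -> float:
    """Submaximal ROM: the same inversion at a lower torque threshold."""
    return rom_at_torque(fit, threshold=sub_threshold, angle_cap=angle_cap)


def with_rom(
    fit: PassiveFitResult,
    threshold: float = TORQUE_THRESHOLD_NM,
    sub_threshold: float = SUBMAX_THRESHOLD_NM,
    angle_cap: float = ANGLE_CAP_INTERNAL,
) -> PassiveFitResult:
    """Return a copy of the fit with rom_max/rom_sub filled in."""
    return replace(
        fit,
        rom_max=rom_at_torque(fit, threshold, angle_cap),
        rom_sub=rom_submax(fit, sub_threshold, angle_cap),
        torque_threshold_used=threshold,
    )


def active_rom(trial: DynamometerTrial, direction: str = "external") -> float:
    """Mean extreme angle over cycles of an active ROM trial.

    Cycles are delimited by velocity-sign reversals; for the external
    direction the local angle maxima at reversals are averaged, for the
    internal direction the local minima.
    """
    v = trial.velocity
    sign = np.sign(v)
    nz = sign != 0
    if not nz.any():
        raise ValueError("no movement in trial")
    s = sign[nz]
    reversals = np.flatnonzero(np.diff(s) != 0)
    if reversals.size == 0:
        raise ValueError("no direction reversals in active ROM trial")
    # map back to full-array indices
    full_idx = np.flatnonzero(nz)
    extremes = []
    bounds = np.concatenate(([0], reversals + 1, [s.size]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = trial.angle[full_idx[a]:full_idx[b - 1] + 1]
        if s[a] > 0 and direction == "external":
            extremes.append(float(seg.max()))
        elif s[a] < 0 and direction == "internal":
            extremes.append(float(seg.min()))
    if not extremes:
        raise ValueError(f"no movements toward {direction} rotation found")
    return float(np.mean(extremes))
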