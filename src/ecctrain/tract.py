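"""Muscle DTI computations: tensor fitting, FA, deterministic tractography.

Tensor estimation is the standard log-linear least-squares fit of the
monoexponential signal model ``S_i = S0 * exp(-b * g_i' D g_i)``. Fiber
tracking integrates the principal-eigenvector direction field with a
fixed-step fourth-order Runge-Kutta scheme, bidirectionally from each seed,
with the usual stopping rules (mask exit, FA bounds, per-step turning
angle, length cap). Fascicle metrics follow whole-muscle tractography
practice: mean streamline arc length, unique traversed voxels times voxel
volume, and length-weighted mean FA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TensorVolume",
    "Streamline",
    "TractStats",
    "TrackingCriteria",
    "fit_tensor_lls",
    "fractional_anisotropy",
    "integrate_direction_field",
    "track_streamline",
    "track_volume",
    "tract_statistics",
]


def fractional_anisotropy(eigenvalues) -> float:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||, in [0, 1]."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-15):
        raise ValueError("eigenvalues must be non-negative")
    norm = np.linalg.norm(lam)
    if norm == 0:
        raise ValueError("all-zero eigenvalues have undefined FA")
    dev = lam - lam.mean()
    return float(np.sqrt(1.5) * np.linalg.norm(dev) / norm)


def _design_matrix(gradients: np.ndarray) -> np.ndarray:
    g = np.asarray(gradients, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    # tensor component order: xx, yy, zz, xy, xz, yz
    return np.column_stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )


def fit_tensor_lls(
    dwi_signals: Sequence[float],
    gradients: np.ndarray,
    b: float,
    s0: float,
) -> np.ndarray:
    """Log-linear least-squares diffusion tensor fit.

    Solves ``ln(S_i/S0) = -b * g_i' D g_i`` for the six unique components
    and returns the symmetric 3x3 tensor. Negative eigenvalues are clamped
    to zero with a warning.
    """
    s = np.asarray(dwi_signals, dtype=float)
    g = np.asarray(gradients, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise ValueError("gradients must be (n, 3)")
    if s.shape[0] != g.shape[0]:
        raise ValueError("signal count must match gradient count")
    if g.shape[0] < 6:
        raise ValueError("at least 6 gradient directions are required")
    if np.any(s <= 0) or s0 <= 0:
        raise ValueError("signals must be positive")
    X = _design_matrix(g)
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("rank-deficient gradient scheme: directions are "
                         "not sufficiently non-collinear")
    y = -np.log(s / s0) / b
    d, *_ = np.linalg.lstsq(X, y, rcond=None)
    D = np.array(
        [[d[0], d[3], d[4]],
         [d[3], d[1], d[5]],
         [d[4], d[5], d[2]]]
    )
    lam, V = np.linalg.eigh(D)
    if np.any(lam < 0):
        warnings.warn("negative tensor eigenvalues clamped to zero")
        lam = np.clip(lam, 0.0, None)
        D = (V * lam) @ V.T
    return D


@dataclass
class TensorVolume:
    """3-D grid of symmetric diffusion tensors with a binary muscle mask.

    ``affine`` maps voxel indices (i, j, k, 1) to world mm coordinates;
    the default is a scaling by ``voxel_size`` (voxel centers at integer
    indices, half-open world-to-voxel convention).
    """

    tensors: np.ndarray                 # (nx, ny, nz, 3, 3), mm^2/s
    mask: np.ndarray                    # (nx, ny, nz) bool
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tensors.shape[:3] != self.mask.shape:
            raise ValueError("tensor grid and mask shapes differ")
        if self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must be (nx, ny, nz, 3, 3)")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        else:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            A = np.eye(4)
            A[0, 0], A[1, 1], A[2, 2] = self.voxel_size
            self.affine = A
        self.affine = np.asarray(self.affine, dtype=float)
        self._inv_affine = np.linalg.inv(self.affine)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, p: np.ndarray) -> np.ndarray:
        return self._inv_affine[:3, :3] @ p + self._inv_affine[:3, 3]

    def voxel_to_world(self, v: np.ndarray) -> np.ndarray:
        return self.affine[:3, :3] @ v + self.affine[:3, 3]

    def in_mask(self, p: np.ndarray) -> bool:
        v = np.rint(self.world_to_voxel(p)).astype(int)
        if np.any(v < 0) or np.any(v >= self.mask.shape):
            return False
        return bool(self.mask[v[0], v[1], v[2]])

    def tensor_at(self, p: np.ndarray) -> np.ndarray:
        """Component-wise trilinear interpolation of the tensor at a world
        point, then usable for eigen-decomposition (smoother than
        nearest-neighbour eigenvectors)."""
        v = self.world_to_voxel(p)
        f = np.floor(v).astype(int)
        shape = np.array(self.mask.shape)
        f = np.clip(f, 0, shape - 2)
        w = np.clip(v - f, 0.0, 1.0)
        block = self.tensors[f[0]:f[0] + 2, f[1]:f[1] + 2, f[2]:f[2] + 2]
        wx = np.array([1 - w[0], w[0]])
        wy = np.array([1 - w[1], w[1]])
        wz = np.array([1 - w[2], w[2]])
        weights = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
        return np.tensordot(weights, block, axes=3)

    def fa_at(self, p: np.ndarray) -> float:
        lam = np.linalg.eigvalsh(self.tensor_at(p))
        lam = np.clip(lam, 0.0, None)
        if not lam.any():
            return 0.0
        return fractional_anisotropy(lam)

    def direction_at(self, p: np.ndarray, ref: np.ndarray | None = None):
        """Principal eigenvector at a world point, sign-aligned to ``ref``."""
        lam, V = np.linalg.eigh(self.tensor_at(p))
        e1 = V[:, -1]
        if ref is not None and float(e1 @ ref) < 0:
            e1 = -e1
        return e1


@dataclass
class Streamline:
    """Tracked fascicle polyline in world (mm) coordinates."""

    points: np.ndarray                  # (n, 3)
    mean_fa: float = float("nan")
    voxels: set = field(default_factory=set)   # 0-based voxel index tuples

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def arc_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class TractStats:
    fascicle_length: float              # mm, mean streamline arc length
    fascicle_volume: float              # mm^3, unique voxels x voxel volume
    mean_fa: float                      # length-weighted mean along paths
    n_streamlines: int


@dataclass(frozen=True)
class TrackingCriteria:
    """Stopping criteria for deterministic streamline tracking.

    Defaults are provisional, configurable values in the range used for
    whole-muscle tractography.
    """

    step_mm: float = 1.0
    fa_min: float = 0.05
    fa_max: float = 0.6
    angle_max_deg: float = 30.0
    min_length_mm: float = 10.0
    max_length_mm: float = 200.0


def integrate_direction_field(
    field_fn: Callable[[np.ndarray, np.ndarray], np.ndarray | None],
    seed: np.ndarray,
    init_dir: np.ndarray,
    step: float,
    max_steps: int,
    angle_max_deg: float = 90.0,
    method: str = "rk4",
) -> np.ndarray:
    """Fixed-step integration of a unit direction field from ``seed``.

    ``field_fn(x, ref)`` returns the unit direction at ``x`` sign-aligned
    with ``ref``, or None where the field is undefined (stop). Returns the
    polyline of visited points including the seed.
    """
    x = np.asarray(seed, dtype=float).copy()
    d_prev = np.asarray(init_dir, dtype=float)
    d_prev = d_prev / np.linalg.norm(d_prev)
    pts = [x.copy()]
    cos_max = np.cos(np.deg2rad(angle_max_deg))
    for _ in range(max_steps):
        if method == "rk4":
            k1 = field_fn(x, d_prev)
            if k1 is None:
                break
            k2 = field_fn(x + 0.5 * step * k1, k1)
            if k2 is None:
                break
            k3 = field_fn(x + 0.5 * step * k2, k2)
            if k3 is None:
                break
            k4 = field_fn(x + step * k3, k3)
            if k4 is None:
                break
            # raw RK4 increment: the stage slopes are unit vectors but the
            # combined increment must NOT be renormalized or the scheme
            # degrades to second order on curved paths
            incr = (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        elif method == "euler":
            incr = field_fn(x, d_prev)
            if incr is None:
                break
        else:
            raise ValueError(f"unknown method {method!r}")
        nrm = np.linalg.norm(incr)
        if nrm == 0:
            break
        d = incr / nrm
        if float(d @ d_prev) < cos_max:
            break
        x = x + step * incr
        nxt = field_fn(x, d)
        if nxt is None:                 # stepped outside the defined field
            break
        pts.append(x.copy())
        d_prev = d
    return np.array(pts)


def _volume_field(volume: TensorVolume, crit: TrackingCriteria):
    def field_fn(p, ref):
        if not volume.in_mask(p):
            return None
        fa = volume.fa_at(p)
        if not (crit.fa_min <= fa <= crit.fa_max):
            return None
        return volume.direction_at(p, ref)
    return field_fn


def track_streamline(
    volume: TensorVolume,
    seed_point,
    criteria: TrackingCriteria = TrackingCriteria(),
) -> Streamline:
    """Bidirectional RK4 streamline from a world-coordinate seed."""
    seed = np.asarray(seed_point, dtype=float)
    if not volume.in_mask(seed):
        raise ValueError("seed point lies outside the mask")
    field_fn = _volume_field(volume, criteria)
    if field_fn(seed, None) is None:
        return Streamline(points=seed[None, :])
    e1 = volume.direction_at(seed)
    half_steps = int(np.ceil(0.5 * criteria.max_length_mm / criteria.step_mm))
    fwd = integrate_direction_field(
        field_fn, seed, e1, criteria.step_mm, half_steps,
        criteria.angle_max_deg,
    )
    bwd = integrate_direction_field(
        field_fn, seed, -e1, criteria.step_mm, half_steps,
        criteria.angle_max_deg,
    )
    pts = np.vstack([bwd[::-1], fwd[1:]])
    sl = Streamline(points=pts)
    if len(pts) >= 2:
        fas = [volume.fa_at(p) for p in pts]
        sl.mean_fa = float(np.mean(fas))
        vox = np.rint([volume.world_to_voxel(p) for p in pts]).astype(int)
        sl.voxels = {tuple(v) for v in vox}
    return sl


def track_volume(
    volume: TensorVolume,
    criteria: TrackingCriteria = TrackingCriteria(),
    max_seeds: int | None = None,
) -> list[Streamline]:
    """Whole-muscle tractography: one seed per masked voxel center.

    Seeds are taken in deterministic C order; with ``max_seeds`` the set is
    subsampled at a uniform deterministic stride.
    """
    idx = np.argwhere(volume.mask)
    if max_seeds is not None and len(idx) > max_seeds:
        stride = int(np.ceil(len(idx) / max_seeds))
        idx = idx[::stride]
    out = []
    for v in idx:
        seed = volume.voxel_to_world(v.astype(float))
        try:
            sl = track_streamline(volume, seed, criteria)
        except ValueError:
            continue
        if sl.arc_length >= criteria.min_length_mm:
            out.append(sl)
    return out


def tract_statistics(
    streamlines: Sequence[Streamline], volume: TensorVolume
) -> TractStats:
    """Fascicle metrics over a tracked bundle."""
    sls = [s for s in streamlines if len(s.points) >= 2]
    if not sls:
        raise ValueError("no streamlines to summarize")
    lengths = np.array([s.arc_length for s in sls])
    vox: set = set()
    for s in sls:
        vox |= s.voxels
    fas = np.array([s.mean_fa for s in sls])
    ok = np.isfinite(fas)
    mean_fa = float(np.average(fas[ok], weights=lengths[ok])) if ok.any() else float("nan")
    return TractStats(
        fascicle_length=float(lengths.mean()),
        fascicle_volume=len(vox) * volume.voxel_volume,
        mean_fa=mean_fa,
        n_streamlines=len(sls),
    )
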