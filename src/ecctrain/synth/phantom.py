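"""Pennate-muscle DTI phantom with known fascicle geometry and FA.

A cylindrical "muscle" mask is filled with parallel fascicle paths --
straight lines at a configurable pennation angle, or circular arcs (the
arc option exists to exercise integrator order-of-convergence tests). Each
masked voxel carries an axially symmetric positive-definite tensor whose
principal eigenvector is tangent to the local path and whose eigenvalues
realize the requested fractional anisotropy exactly. Optionally, DWI
signals ``S_i = S0 * exp(-b g_i' D g_i)`` are produced over a set of unit
gradient directions with Gaussian or Rician noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..tract import TensorVolume

__all__ = [
    "PhantomSpec",
    "simulate_phantom",
    "axial_eigenvalues",
    "make_gradient_directions",
    "dwi_signals",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal parameters of the muscle phantom."""

    grid_shape: tuple = (16, 16, 48)
    voxel_size: float = 1.0                # mm, isotropic
    fascicle_length_true: float = 40.0     # mm, path length inside the mask
    pennation_angle: float = 0.0           # deg, tilt of straight fascicles
    fa_target: float = 0.30
    eigenvalue_scale: float = 1.7e-3       # mm^2/s, principal eigenvalue
    n_directions: int = 48
    b_value: float = 400.0                 # s/mm^2
    noise_sd_signal: float = 0.0           # fraction of S0
    geometry: str = "straight"             # "straight" | "arc"
    arc_radius: float = 60.0               # mm, for geometry="arc"
    radius_frac: float = 0.38              # cylinder radius / min(nx, ny)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fa_target < 1.0):
            raise ValueError("fa_target must lie in [0, 1)")
        if self.geometry not in ("straight", "arc"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes of at least 4 voxels")
        if self.voxel_size <= 0 or self.eigenvalue_scale <= 0:
            raise ValueError("voxel_size and eigenvalue_scale must be positive")


def axial_eigenvalues(fa: float, lam1: float) -> tuple[float, float, float]:
    """Eigenvalues (lam1, lam2, lam2) of an axially symmetric tensor with
    the requested FA.

    With t = lam2/lam1, FA = (1 - t)/sqrt(1 + 2 t^2); solving the quadratic
    gives t exactly, so the generated FA matches to machine precision.
    """
    if not (0.0 <= fa < 1.0):
        raise ValueError("fa must lie in [0, 1)")
    f2 = fa * fa
    denom = 1.0 - 2.0 * f2
    if abs(denom) < 1e-12:
        t = (1.0 - f2) / 2.0
    else:
        disc = 1.0 - denom * (1.0 - f2)
        t = (1.0 - math.sqrt(disc)) / denom
    return lam1, t * lam1, t * lam1


def _tangent_field(spec: PhantomSpec, xyz: np.ndarray) -> np.ndarray:
    """Unit fascicle tangent at world points ``xyz`` (n, 3)."""
    if spec.geometry == "straight":
        alpha = math.radians(spec.pennation_angle)
        d = np.array([math.sin(alpha), 0.0, math.cos(alpha)])
        return np.broadcast_to(d, xyz.shape).copy()
    # circular arcs in the x-z plane around a center offset in x
    cx = -spec.arc_radius
    r = xyz[:, [0, 2]] - np.array([cx, 0.0])
    t = np.column_stack([-r[:, 1], np.zeros(len(xyz)), r[:, 0]])
    nrm = np.linalg.norm(t, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return t / nrm


def simulate_phantom(spec: PhantomSpec) -> tuple[TensorVolume, dict]:
    """Build the phantom tensor volume and its ground truth.

    The mask is a cylinder around the grid's central (x, y) axis whose
    extent along the fascicle direction equals ``fascicle_length_true`` (for
    straight fascicles the slab thickness is scaled by cos(pennation) so the
    oblique path length through it equals the requested value).
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    xyz = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float) * vs

    cx, cy = (nx - 1) / 2.0 * vs, (ny - 1) / 2.0 * vs
    radius = spec.radius_frac * min(nx, ny) * vs
    in_disk = (xyz[:, 0] - cx) ** 2 + (xyz[:, 1] - cy) ** 2 <= radius**2

    alpha = math.radians(spec.pennation_angle)
    slab = spec.fascicle_length_true * math.cos(alpha)
    z0 = ((nz - 1) * vs - slab) / 2.0
    if z0 < 0:
        raise ValueError("grid too short along z for the requested fascicle length")
    in_slab = (xyz[:, 2] >= z0) & (xyz[:, 2] <= z0 + slab)
    mask = (in_disk & in_slab).reshape(nx, ny, nz)

    lam1, lam2, _ = axial_eigenvalues(spec.fa_target, spec.eigenvalue_scale)
    tang = _tangent_field(spec, xyz)
    eye = np.eye(3)
    outer = np.einsum("ni,nj->nij", tang, tang)
    tensors = lam2 * eye[None, :, :] + (lam1 - lam2) * outer
    tensors = tensors.reshape(nx, ny, nz, 3, 3)
    tensors[~mask] = spec.eigenvalue_scale * eye  # isotropic background

    volume = TensorVolume(tensors=tensors, mask=mask, voxel_size=vs)
    truth = {
        "fascicle_length_true": spec.fascicle_length_true,
        "fa_target": spec.fa_target,
        "eigenvalues": (lam1, lam2, lam2),
        "pennation_angle": spec.pennation_angle,
        "geometry": spec.geometry,
        "slab_z_range": (z0, z0 + slab),
        "mask_voxels": int(mask.sum()),
    }
    return volume, truth


def make_gradient_directions(n: int = 48, seed: int = 7) -> np.ndarray:
    """Approximately uniform unit gradient directions (Fibonacci sphere)."""
    if n < 6:
        raise ValueError("need at least 6 directions")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    g = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    return g


def dwi_signals(
    volume: TensorVolume,
    gradients: np.ndarray,
    b: float = 400.0,
    s0: float = 1.0,
    noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    seed: int = 0,
) -> np.ndarray:
    """DWI signals for every voxel: shape (nx, ny, nz, n_directions)."""
    g = np.asarray(gradients, dtype=float)
    D = volume.tensors
    # g' D g for every voxel and direction
    adc = np.einsum("md,xyzde,me->xyzm", g, D, g)
    s = s0 * np.exp(-b * adc)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        sigma = noise_sd * s0
        if noise_model == "gaussian":
            s = s + rng.normal(0.0, sigma, s.shape)
        elif noise_model == "rician":
            s = np.sqrt(
                (s + rng.normal(0.0, sigma, s.shape)) ** 2
                + rng.normal(0.0, sigma, s.shape) ** 2
            )
        else:
            raise ValueError(f"unknown noise_model {noise_model!r}")
        s = np.clip(s, 1e-12, None)
    return s
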