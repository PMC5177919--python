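"""ICOSA6 encoding geometry and least-squares field reconstruction.

The six encoding directions point through one vertex of each antipodal pair of
a regular icosahedron, built from the golden ratio phi as the normalised
(0, +/-1, +/-phi) permutation family.  Any distinct pair satisfies
|e_a . e_b| = 1 / sqrt(5), and the set is a tight frame:
sum_i e_i e_i^T = 2 I.

Two linear models are solved per voxel:

* the directional mean velocities ``m_i = e_i . u`` give the Cartesian
  velocity by ordinary least squares against the 6x3 projection matrix
  (for the tight frame the pseudoinverse is simply ``E^T / 2``);
* the directional variances ``sigma_i^2 = e_i^T <u' u'^T> e_i`` are linear in
  the six unique Reynolds-tensor entries, giving a 6x6 system whose exact
  inverse is precomputed once per scheme, so per-voxel solves are
  matrix-vector products.

Reconstructed tensors are symmetric by construction.  Negative diagonal
entries can arise from measurement noise; they are flagged but retained so
that the signed square-sum analyses downstream see unbiased values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EncodingScheme",
    "icosa6_directions",
    "solve_velocity",
    "solve_reynolds_tensor",
    "reconstruct",
    "ReconVolume",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class EncodingScheme:
    """Six unit encoding directions and the precomputed solve operators."""

    directions: np.ndarray            # (6, 3) unit vectors
    venc: float | None = None
    design_matrix_velocity: np.ndarray = field(default=None, repr=False)
    design_matrix_tensor: np.ndarray = field(default=None, repr=False)
    pinv_velocity: np.ndarray = field(default=None, repr=False)
    inv_tensor: np.ndarray = field(default=None, repr=False)


def _tensor_design_row(e: np.ndarray) -> np.ndarray:
    """Coefficients of sigma_e^2 = e^T T e in packed (xx,yy,zz,xy,xz,yz) order."""
    ex, ey, ez = e
    return np.array([ex * ex, ey * ey, ez * ez,
                     2.0 * ex * ey, 2.0 * ex * ez, 2.0 * ey * ez])


def icosa6_directions(venc: float | None = None,
                      directions: np.ndarray | None = None) -> EncodingScheme:
    """Build the ICOSA6 encoding scheme (optionally from rotated directions).

    With no argument, returns the canonical golden-ratio vertex set.  Passing
    ``directions`` (six unit vectors, e.g. a rotation of the canonical set)
    builds the scheme for that geometry; tensor estimates are equivariant
    under such rotations.
    """
    if directions is None:
        phi = GOLDEN_RATIO
        raw = np.array([
            [0.0, 1.0, phi],
            [0.0, 1.0, -phi],
            [1.0, phi, 0.0],
            [1.0, -phi, 0.0],
            [phi, 0.0, 1.0],
            [-phi, 0.0, 1.0],
        ])
        directions = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    else:
        directions = np.asarray(directions, dtype=np.float64)
        if directions.shape != (6, 3):
            raise ValueError("directions must have shape (6, 3)")
        norms = np.linalg.norm(directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("encoding directions must be unit vectors")

    a_vel = directions
    a_tens = np.stack([_tensor_design_row(e) for e in directions])
    if (np.linalg.matrix_rank(a_vel) < 3
            or np.linalg.matrix_rank(a_tens) < 6):
        raise ValueError("encoding scheme design matrices are rank deficient")
    return EncodingScheme(
        directions=directions,
        venc=venc,
        design_matrix_velocity=a_vel,
        design_matrix_tensor=a_tens,
        pinv_velocity=np.linalg.pinv(a_vel),
        inv_tensor=np.linalg.inv(a_tens),
    )


def solve_velocity(directional_velocities: np.ndarray,
                   scheme: EncodingScheme | None = None,
                   valid: np.ndarray | None = None) -> np.ndarray:
    """Least-squares Cartesian velocity from directional measurements.

    ``directional_velocities`` carries the six encodings on the *first* axis
    (``(6,)`` or ``(6, nx, ny, nz)``); the Cartesian components come out on
    the *last* axis.  ``valid`` optionally masks out individual directions of
    a single measurement (at least three must remain).
    """
    scheme = scheme or icosa6_directions()
    m = np.asarray(directional_velocities, dtype=np.float64)
    if m.shape[0] != 6:
        raise ValueError("expected six directional measurements on axis 0")
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if m.ndim != 1:
            raise ValueError("per-direction masking is supported for single voxels only")
        a = scheme.design_matrix_velocity[valid]
        if np.linalg.matrix_rank(a) < 3:
            raise ValueError("fewer than three independent directions remain")
        sol, *_ = np.linalg.lstsq(a, m[valid], rcond=None)
        return sol
    return np.tensordot(scheme.pinv_velocity, m, axes=([1], [0])).transpose(
        tuple(range(1, m.ndim)) + (0,))


def solve_reynolds_tensor(directional_variances: np.ndarray,
                          scheme: EncodingScheme | None = None) -> np.ndarray:
    """Solve the 6x6 linear system for the packed Reynolds tensor.

    Input: directional variances sigma_e^2 (m^2/s^2) with the six encodings on
    the first axis.  Output: packed (xx, yy, zz, xy, xz, yz) tensor entries on
    the last axis.  The solve is exact for consistent inputs; negative
    diagonals from noisy data are the caller's to flag.
    """
    scheme = scheme or icosa6_directions()
    s2 = np.asarray(directional_variances, dtype=np.float64)
    if s2.shape[0] != 6:
        raise ValueError("expected six directional variances on axis 0")
    return np.tensordot(scheme.inv_tensor, s2, axes=([1], [0])).transpose(
        tuple(range(1, s2.ndim)) + (0,))


@dataclass
class ReconVolume:
    """Reconstructed per-voxel fields ready for stress mapping.

    ``reynolds_tensor`` stores <u'_i u'_j> in m^2/s^2 (multiply by ``density``
    at the reporting layer for stress units).  ``ivsd`` holds the six
    directional IVSDs; ``clipped_mask`` marks voxels where at least one
    direction hit the noise-clipping rule of the IVSD estimator and
    ``negative_diag_mask`` marks noise-induced negative tensor diagonals.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    voxel_size: float
    velocity: np.ndarray          # (nx, ny, nz, 3) m/s
    ivsd: np.ndarray              # (6, nx, ny, nz) m/s
    reynolds_tensor: np.ndarray   # (nx, ny, nz, 6) m^2/s^2
    valid_mask: np.ndarray
    clipped_mask: np.ndarray
    negative_diag_mask: np.ndarray
    density: float
    viscosity: float
    bulk_velocity: float
    lumen_radius: float

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    @property
    def origin(self) -> np.ndarray:
        return np.array([self.x[0], self.y[0], self.z[0]])


def reconstruct(acquisition, scheme: EncodingScheme | None = None) -> ReconVolume:
    """Full-volume reconstruction of velocity and Reynolds tensor.

    Phases have already been turned into directional velocities by the
    simulator (velocities from the phase channel, IVSDs from the magnitude
    channel — the two least-squares problems are solved separately).
    """
    from .mri import estimate_ivsd, signed_squared_ivsd  # avoid a cycle

    scheme = scheme or icosa6_directions(directions=acquisition.directions)
    k_v = acquisition.k_v
    valid = acquisition.valid_mask

    mag_s0 = np.where(valid, acquisition.mag_s0, 1.0)
    sigma = np.zeros_like(acquisition.v_dir)
    sigma_sq = np.zeros_like(acquisition.v_dir)
    clipped_any = np.zeros(valid.shape, dtype=bool)
    for i in range(6):
        mag = np.abs(acquisition.signals[i])
        s, c = estimate_ivsd(mag_s0, mag, k_v)
        sigma[i] = np.where(valid, s, 0.0)
        # signed variances keep the noise zero-mean through the tensor solve
        sigma_sq[i] = np.where(valid, signed_squared_ivsd(mag_s0, mag, k_v), 0.0)
        clipped_any |= valid & c

    velocity = solve_velocity(acquisition.v_dir, scheme)
    velocity[~valid] = 0.0
    tensor = solve_reynolds_tensor(sigma_sq, scheme)
    tensor[~valid] = 0.0
    neg_diag = valid & (tensor[..., :3].min(axis=-1) < 0.0)

    return ReconVolume(
        x=acquisition.x, y=acquisition.y, z=acquisition.z,
        voxel_size=acquisition.voxel_size,
        velocity=velocity, ivsd=sigma, reynolds_tensor=tensor,
        valid_mask=valid, clipped_mask=clipped_any,
        negative_diag_mask=neg_diag,
        density=acquisition.density, viscosity=acquisition.viscosity,
        bulk_velocity=acquisition.bulk_velocity,
        lumen_radius=acquisition.lumen_radius,
    )
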