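"""Packed symmetric 3x3 tensor storage and closed-form eigenvalue helpers.

Symmetric tensor fields (Reynolds stress, strain rate, viscous stress) are
stored with six components on the last axis in the fixed order

    (xx, yy, zz, xy, xz, yz)

which is also the dataset layout used by the HDF5 I/O layer.
"""

from __future__ import annotations

import numpy as np

PACKED_ORDER: tuple[str, ...] = ("xx", "yy", "zz", "xy", "xz", "yz")

#: (row, col) index of each packed component in the full 3x3 matrix.
_PACKED_IJ = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


def pack(matrix: np.ndarray, *, check_symmetry: bool = False, rtol: float = 1e-8) -> np.ndarray:
    """Pack symmetric ``(..., 3, 3)`` matrices into ``(..., 6)`` component order."""
    matrix = np.asarray(matrix)
    if matrix.shape[-2:] != (3, 3):
        raise ValueError(f"expected trailing (3, 3) shape, got {matrix.shape}")
    if check_symmetry:
        asym = np.abs(matrix - np.swapaxes(matrix, -1, -2))
        scale = np.maximum(np.abs(matrix).max(initial=0.0), 1e-300)
        if asym.max(initial=0.0) > rtol * scale:
            raise ValueError("matrix is not symmetric within tolerance")
    return np.stack([matrix[..., i, j] for i, j in _PACKED_IJ], axis=-1)


def unpack(packed: np.ndarray) -> np.ndarray:
    """Expand packed ``(..., 6)`` components into full symmetric ``(..., 3, 3)``."""
    packed = np.asarray(packed)
    if packed.shape[-1] != 6:
        raise ValueError(f"expected trailing axis of length 6, got {packed.shape}")
    xx, yy, zz, xy, xz, yz = (packed[..., k] for k in range(6))
    row0 = np.stack([xx, xy, xz], axis=-1)
    row1 = np.stack([xy, yy, yz], axis=-1)
    row2 = np.stack([xz, yz, zz], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def trace(packed: np.ndarray) -> np.ndarray:
    packed = np.asarray(packed)
    return packed[..., 0] + packed[..., 1] + packed[..., 2]


def contract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full double contraction ``a_ij b_ij`` of two packed symmetric tensors.

    Off-diagonal components appear twice in the 9-term sum, hence the factor 2.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    diag = a[..., 0] * b[..., 0] + a[..., 1] * b[..., 1] + a[..., 2] * b[..., 2]
    offd = a[..., 3] * b[..., 3] + a[..., 4] * b[..., 4] + a[..., 5] * b[..., 5]
    return diag + 2.0 * offd


def eigvals_sym3(packed: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvalues of packed symmetric 3x3 tensors, closed form, descending.

    Uses the trigonometric (Cardano) solution for the characteristic cubic of a
    symmetric matrix: with ``q = tr/3`` and ``p`` the RMS deviatoric scale, the
    eigenvalues are ``q + 2 p cos(phi + 2 pi k / 3)``.  Degenerate (isotropic)
    tensors fall out naturally with ``p = 0``.  The argument of ``arccos`` is
    clipped to [-1, 1] to guard round-off for near-degenerate spectra.

    Returns
    -------
    (lam1, lam2, lam3) with ``lam1 >= lam2 >= lam3`` elementwise.
    """
    packed = np.asarray(packed, dtype=np.float64)
    xx, yy, zz, xy, xz, yz = (packed[..., k] for k in range(6))
    q = (xx + yy + zz) / 3.0
    p1 = xy * xy + xz * xz + yz * yz
    dxx, dyy, dzz = xx - q, yy - q, zz - q
    p2 = dxx * dxx + dyy * dyy + dzz * dzz + 2.0 * p1
    p = np.sqrt(p2 / 6.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        inv_p = np.where(p > 0.0, 1.0 / np.where(p > 0.0, p, 1.0), 0.0)
        bxx, byy, bzz = dxx * inv_p, dyy * inv_p, dzz * inv_p
        bxy, bxz, byz = xy * inv_p, xz * inv_p, yz * inv_p
        detb = (
            bxx * (byy * bzz - byz * byz)
            - bxy * (bxy * bzz - byz * bxz)
            + bxz * (bxy * byz - byy * bxz)
        )
    r = np.clip(detb / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0

    lam1 = q + 2.0 * p * np.cos(phi)
    lam3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    lam2 = 3.0 * q - lam1 - lam3
    return lam1, lam2, lam3


def is_positive_semidefinite(packed: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Elementwise PSD test via the smallest closed-form eigenvalue."""
    _, _, lam3 = eigvals_sym3(packed)
    scale = np.maximum(np.abs(np.asarray(packed)).max(axis=-1), 1.0)
    return lam3 >= -tol * scale - 1e-300
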