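"""Hemodynamic stress maps: TKE, PLVS, PRSS, TVSS and volumetric indices.

Given a reconstructed (or ground-truth) velocity and Reynolds-tensor volume,
this module computes:

* the mean strain-rate tensor S_ij = (du_i/dx_j + du_j/dx_i) / 2 from
  mask-aware second-order finite differences;
* the laminar viscous stress tau_ij = mu (du_i/dx_j + du_j/dx_i) and its
  maximum principal shear (PLVS, half the spread of the extreme eigenvalues);
* the Reynolds stress rho <u'_i u'_j> and its maximum principal shear (PRSS);
* turbulent kinetic energy TKE = rho/2 sum_i sigma_i^2;
* the turbulence production P = -rho <u'_i u'_j> S_ij, which under the
  production-dissipation balance gives the dissipation rate eps = P / rho and
  the turbulent viscous shear stress TVSS = sqrt(mu rho eps) = sqrt(mu P);
* the signed square-sum of TVSS, sum sign(P) |mu P| dV, which keeps
  noise-induced negative production contributions with their sign and is
  therefore robust to zero-mean noise where the flagged TVSS sum is biased.

TVSS itself is undefined (NaN, flagged) where P < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensors import contract, eigvals_sym3, pack, trace

__all__ = [
    "velocity_gradient",
    "strain_rate",
    "laminar_viscous_stress",
    "max_principal_shear",
    "tke",
    "turbulence_production",
    "tvss",
    "tvss_square_sum",
    "volumetric_sum",
    "StressMaps",
    "compute_stress_maps",
    "ground_truth_stress_maps",
]

#: Isolated prefactor of the TVSS estimate sqrt(prefactor * mu * rho * eps);
#: kept as one constant so the convention can be adjusted without touching
#: callers.
TVSS_PREFACTOR = 1.0


def _shift(a: np.ndarray, step: int, axis: int, fill=0.0) -> np.ndarray:
    """Shift with constant fill (neighbour lookup without wrap-around)."""
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step > 0:
        src[axis] = slice(step, None)
        dst[axis] = slice(None, -step)
    else:
        src[axis] = slice(None, step)
        dst[axis] = slice(-step, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _masked_derivative(f: np.ndarray, axis: int, h: float,
                       mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """d f / d x_axis with out-of-mask neighbours excluded.

    Second-order central differences where both neighbours are in the mask,
    one-sided second order (three-point) at mask boundaries, first-order
    two-point where only a single neighbour exists.  Returns the derivative
    and a flag of in-mask points with no valid neighbour along this axis.
    """
    fm = _shift(f, -1, axis)
    fp = _shift(f, +1, axis)
    fpp = _shift(f, +2, axis)
    fmm = _shift(f, -2, axis)
    mm = _shift(mask, -1, axis, fill=False)
    mp = _shift(mask, +1, axis, fill=False)
    mpp = _shift(mask, +2, axis, fill=False)
    mmm = _shift(mask, -2, axis, fill=False)

    central = mp & mm
    fwd2 = mp & mpp & ~mm
    fwd1 = mp & ~mpp & ~mm
    bwd2 = mm & mmm & ~mp
    bwd1 = mm & ~mmm & ~mp

    d = np.zeros_like(f)
    d = np.where(central, (fp - fm) / (2.0 * h), d)
    d = np.where(fwd2, (-3.0 * f + 4.0 * fp - fpp) / (2.0 * h), d)
    d = np.where(fwd1, (fp - f) / h, d)
    d = np.where(bwd2, (3.0 * f - 4.0 * fm + fmm) / (2.0 * h), d)
    d = np.where(bwd1, (f - fm) / h, d)
    d = np.where(mask, d, 0.0)
    isolated = mask & ~(mp | mm)
    return d, isolated


def velocity_gradient(velocity: np.ndarray, spacing: float,
                      mask: np.ndarray | None = None):
    """Gradient tensor du_i/dx_j of a velocity volume.

    ``velocity`` has shape ``(nx, ny, nz, 3)``; the result has shape
    ``(nx, ny, nz, 3, 3)`` with ``grad[..., i, j] = du_i/dx_j``.  Returns
    ``(grad, flagged)`` where ``flagged`` marks in-mask voxels isolated along
    some axis (their derivative there is zero).
    """
    velocity = np.asarray(velocity, dtype=np.float64)
    if velocity.ndim != 4 or velocity.shape[-1] != 3:
        raise ValueError("velocity must have shape (nx, ny, nz, 3)")
    if min(velocity.shape[:3]) < 3:
        raise ValueError("need at least 3 voxels per axis")
    if mask is None:
        mask = np.ones(velocity.shape[:3], dtype=bool)
    grad = np.zeros(velocity.shape[:3] + (3, 3), dtype=np.float64)
    flagged = np.zeros(velocity.shape[:3], dtype=bool)
    for i in range(3):
        for j in range(3):
            d, iso = _masked_derivative(velocity[..., i], j, spacing, mask)
            grad[..., i, j] = d
            flagged |= iso
    return grad, flagged


def strain_rate(grad: np.ndarray) -> np.ndarray:
    """Packed mean strain-rate tensor S_ij from a gradient tensor (1/s)."""
    return pack(0.5 * (grad + np.swapaxes(grad, -1, -2)))


def laminar_viscous_stress(grad: np.ndarray, viscosity: float) -> np.ndarray:
    """Packed laminar viscous stress tau_ij = mu (du_i/dx_j + du_j/dx_i)."""
    return pack(viscosity * (grad + np.swapaxes(grad, -1, -2)))


def max_principal_shear(tensor: np.ndarray) -> np.ndarray:
    """Maximum principal shear (lam_max - lam_min) / 2 of symmetric tensors.

    Accepts packed ``(..., 6)`` tensors or full ``(..., 3, 3)`` matrices (the
    latter are validated for symmetry).  Rotation invariant by construction.
    """
    tensor = np.asarray(tensor)
    if tensor.ndim >= 2 and tensor.shape[-2:] == (3, 3):
        tensor = pack(tensor, check_symmetry=True)
    elif tensor.shape[-1] != 6:
        raise ValueError("expected packed (..., 6) or full (..., 3, 3) tensor")
    lam1, _, lam3 = eigvals_sym3(tensor)
    return 0.5 * (lam1 - lam3)


def tke(sigma_x, sigma_y, sigma_z, density: float):
    """Turbulent kinetic energy per unit volume, rho/2 sum sigma_i^2 (J/m^3)."""
    sx = np.asarray(sigma_x, dtype=np.float64)
    sy = np.asarray(sigma_y, dtype=np.float64)
    sz = np.asarray(sigma_z, dtype=np.float64)
    if np.any(sx < 0) or np.any(sy < 0) or np.any(sz < 0):
        raise ValueError("IVSD values must be non-negative")
    return 0.5 * density * (sx**2 + sy**2 + sz**2)


def turbulence_production(reynolds_tensor: np.ndarray, strain: np.ndarray,
                          density: float) -> np.ndarray:
    """Turbulence production P = -rho <u'_i u'_j> S_ij (W/m^3).

    Full nine-term contraction via packed symmetric storage.  Negative values
    (noise, or local counter-gradient transport) are propagated with sign.
    """
    return -density * contract(reynolds_tensor, strain)


def tvss(production: np.ndarray, viscosity: float, density: float | None = None):
    """Turbulent viscous shear stress sqrt(mu rho eps) with eps = P / rho.

    Since eps = P / rho, the density cancels: TVSS = sqrt(mu P).  Returns
    ``(tvss, defined)``: NaN and ``defined=False`` where P < 0 (the
    noise-undefined voxels that the flagged sums exclude).
    """
    if viscosity <= 0.0:
        raise ValueError("viscosity must be positive")
    if density is not None and density <= 0.0:
        raise ValueError("density must be positive")
    p = np.asarray(production, dtype=np.float64)
    defined = p >= 0.0
    out = np.full(p.shape, np.nan)
    np.sqrt(TVSS_PREFACTOR * viscosity * p, out=out, where=defined)
    if np.ndim(production) == 0:
        return float(out), bool(defined)
    return out, defined


def tvss_square_sum(production: np.ndarray, viscosity: float,
                    mask: np.ndarray, voxel_volume: float) -> float:
    """Signed volumetric square-sum of TVSS (N^2/m^4 * m^3).

    ``sum over voxels of sign(P) |mu P| dV``: negative-production voxels enter
    with negative sign, so zero-mean production noise cancels in expectation.
    Reduces to ``sum TVSS^2 dV`` when all P >= 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    p = np.asarray(production, dtype=np.float64)[mask]
    return float(np.sum(np.sign(p) * np.abs(TVSS_PREFACTOR * viscosity * p)) * voxel_volume)


def volumetric_sum(field: np.ndarray, mask: np.ndarray, voxel_volume: float) -> float:
    """Sum of a per-voxel stress field times the voxel volume over a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(np.asarray(field, dtype=np.float64)[mask].sum() * voxel_volume)


@dataclass
class StressMaps:
    """Per-voxel scalar stress fields and their validity flags.

    ``tvss`` is NaN where production is negative; ``signed_tvss_sq`` (the
    per-voxel signed square, sign(P) |mu P|) is defined everywhere.
    ``partial_volume_mask`` marks voxels whose kernel support intersected the
    wall; volumetric sums are available with and without them.
    """

    spacing: float
    valid_mask: np.ndarray
    tke: np.ndarray                 # J/m^3
    plvs: np.ndarray                # N/m^2
    prss: np.ndarray                # N/m^2
    production: np.ndarray          # W/m^3
    tvss: np.ndarray                # N/m^2, NaN where undefined
    tvss_defined: np.ndarray
    signed_tvss_sq: np.ndarray      # N^2/m^4
    gradient_flagged: np.ndarray
    partial_volume_mask: np.ndarray | None = None

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def volumetric_sums(self, exclude_partial_volume: bool = False) -> dict[str, float]:
        """Volumetric stress indices (value * voxel volume, SI units).

        Keys: ``tke_sum`` (J), ``plvs_sum``/``prss_sum``/``tvss_sum``
        (N/m^2 * m^3 = J energy-equivalent), ``tvss_sq_sum_signed``
        (N^2/m^4 * m^3).  ``tvss_sum`` runs over defined (P >= 0) voxels
        only; the signed square-sum runs over all valid voxels.
        """
        mask = self.valid_mask
        if exclude_partial_volume and self.partial_volume_mask is not None:
            mask = mask & ~self.partial_volume_mask
        vv = self.voxel_volume
        tvss_mask = mask & self.tvss_defined
        return {
            "tke_sum": volumetric_sum(self.tke, mask, vv),
            "plvs_sum": volumetric_sum(self.plvs, mask, vv),
            "prss_sum": volumetric_sum(self.prss, mask, vv),
            "tvss_sum": volumetric_sum(np.nan_to_num(self.tvss), tvss_mask, vv),
            "tvss_sq_sum_signed": float(
                np.sum(self.signed_tvss_sq[mask]) * vv),
        }


def _build_maps(velocity, tensor, mask, spacing, density, viscosity,
                partial_volume=None) -> StressMaps:
    grad, flagged = velocity_gradient(velocity, spacing, mask)
    s_ij = strain_rate(grad)
    tau_lam = laminar_viscous_stress(grad, viscosity)
    plvs = np.where(mask, max_principal_shear(tau_lam), 0.0)
    prss = np.where(mask, max_principal_shear(density * np.asarray(tensor, dtype=np.float64)), 0.0)
    energy = np.where(mask, 0.5 * density * trace(np.asarray(tensor, dtype=np.float64)), 0.0)
    prod = np.where(mask, turbulence_production(tensor, s_ij, density), 0.0)
    tvss_map, defined = tvss(prod, viscosity, density)
    tvss_map = np.where(mask, tvss_map, np.nan)
    signed_sq = np.where(mask, np.sign(prod) * np.abs(TVSS_PREFACTOR * viscosity * prod), 0.0)
    return StressMaps(
        spacing=spacing, valid_mask=mask, tke=energy, plvs=plvs, prss=prss,
        production=prod, tvss=tvss_map, tvss_defined=defined & mask,
        signed_tvss_sq=signed_sq, gradient_flagged=flagged,
        partial_volume_mask=partial_volume,
    )


def compute_stress_maps(recon) -> StressMaps:
    """Stress maps from a reconstructed volume (:class:`~icosaflow.recon.ReconVolume`)."""
    pv = recon.clipped_mask | recon.negative_diag_mask
    # partial-volume flag: lumen-fraction information lives on the acquisition;
    # the reconstruction carries clipping/negative-diagonal flags instead.
    return _build_maps(
        recon.velocity, recon.reynolds_tensor, recon.valid_mask,
        recon.voxel_size, recon.density, recon.viscosity,
        partial_volume=pv,
    )


def ground_truth_stress_maps(phantom) -> StressMaps:
    """Reference stress maps directly from the fine-grid phantom fields.

    Bypasses the MRI chain entirely: gradients of the true mean velocity and
    the prescribed Reynolds tensor on the phantom grid.
    """
    spec = phantom.spec
    return _build_maps(
        phantom.mean_velocity.astype(np.float64),
        phantom.reynolds_tensor.astype(np.float64),
        phantom.mask, phantom.grid_spacing,
        spec.density, spec.dynamic_viscosity,
    )
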