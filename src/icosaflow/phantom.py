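"""Synthetic stenotic-jet flow phantom with fully known turbulence statistics.

This module generates the ground-truth flow fields that the MRI acquisition
simulator consumes: a fine-grid steady mean velocity field for a cosine-shaped
pipe stenosis, a prescribed symmetric positive-semidefinite Reynolds-stress
tensor field concentrated in the post-stenotic jet shear layer, and an ensemble
of instantaneous velocity snapshots whose pointwise fluctuation covariance
equals the prescribed tensor (Gaussian fluctuation model).

The phantom is a *statistical* stand-in for a scale-resolving CFD solution: the
mean field conserves volumetric flow rate section by section and the tensor
field has the qualitative structure of a turbulent jet (production-positive
shear-layer anisotropy), but no Navier-Stokes equations are solved and the
fluctuations are temporally uncorrelated between snapshots.

Geometry and coordinate conventions
-----------------------------------
The principal flow direction is +X.  The grid is rectilinear and cell-centred,
indexed ``[x, y, z]``, with physical coordinates in metres.  The lumen wall
follows a cosine constriction of length one upstream diameter ``D`` centred at
``x = 0``; an optional post-stenotic dilatation (PSD) widens the downstream
pipe to ``psd_factor * D`` over a further diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tensors import trace

__all__ = [
    "PhantomSpec",
    "FlowPhantom",
    "cosine_stenosis_radius",
    "generate_phantom",
]

#: Full axial domain (in upstream diameters) over which the stenosis profile
#: is defined: inlet at -4 D, outlet at +21 D.
AXIAL_DOMAIN_DIAMETERS = (-4.0, 21.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic stenosis phantom.

    Defaults reproduce the reference configuration: water-like fluid
    (rho = 997 kg/m^3, mu = 8.899e-4 kg/m/s) in a D = 14.6 mm pipe with a 75%
    area-reduction stenosis at Re = 2000 on a 0.25 mm fine grid.

    ``axial_extent`` is expressed in upstream diameters and defaults to
    (-2, +6): the post-stenotic jet and its shear layer — where all turbulence
    in this phantom lives — are fully contained, while the long recovered
    outflow of the full (-4, +21) domain is omitted.  Any sub-interval of the
    full domain may be requested.

    ``turbulence_intensity`` is the mixing-length ratio of the fluctuation
    model (ell = intensity * r_jet): the axial fluctuation std at the jet edge
    is ``2 * intensity * U_centerline``, so the default 0.15 gives edge
    fluctuations of 30% of the local centreline velocity — representative of
    a transitional post-stenotic jet.
    """

    upstream_diameter: float = 0.0146
    area_reduction: float = 0.75
    psd_factor: float = 1.0
    reynolds_number: float = 2000.0
    density: float = 997.0
    dynamic_viscosity: float = 8.899e-4
    grid_spacing: float = 0.25e-3
    axial_extent: tuple[float, float] = (-2.0, 6.0)
    turbulence_intensity: float = 0.15
    shear_correlation: float = 0.45
    jet_spread_rate: float = 0.15
    jet_core_length: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.area_reduction < 1.0:
            raise ValueError("area_reduction must lie in (0, 1)")
        for name in ("upstream_diameter", "reynolds_number", "density",
                     "dynamic_viscosity", "grid_spacing"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if self.psd_factor < 1.0:
            raise ValueError("psd_factor must be >= 1")
        if self.turbulence_intensity < 0.0:
            raise ValueError("turbulence_intensity must be >= 0")
        if not -1.0 < self.shear_correlation < 1.0:
            raise ValueError("shear_correlation must lie in (-1, 1)")
        lo, hi = self.axial_extent
        if not lo < hi:
            raise ValueError("axial_extent must be increasing")
        if lo < AXIAL_DOMAIN_DIAMETERS[0] or hi > AXIAL_DOMAIN_DIAMETERS[1]:
            raise ValueError(
                f"axial_extent must lie within {AXIAL_DOMAIN_DIAMETERS} diameters")

    # -- derived quantities -------------------------------------------------

    @property
    def radius(self) -> float:
        """Upstream pipe radius R0 = D/2 (m)."""
        return 0.5 * self.upstream_diameter

    @property
    def throat_radius(self) -> float:
        """Throat radius r_t = R0 sqrt(1 - s) for area reduction s (m)."""
        return self.radius * math.sqrt(1.0 - self.area_reduction)

    @property
    def psd_radius(self) -> float:
        return self.psd_factor * self.radius

    @property
    def bulk_velocity(self) -> float:
        """Mean (bulk) upstream velocity from Re = rho U D / mu (m/s)."""
        return (self.reynolds_number * self.dynamic_viscosity
                / (self.density * self.upstream_diameter))

    @property
    def flow_rate(self) -> float:
        """Volumetric flow rate Q = U_bulk * pi R0^2 (m^3/s)."""
        return self.bulk_velocity * math.pi * self.radius**2

    @property
    def throat_centerline_velocity(self) -> float:
        """Centerline velocity of the parabolic profile at the throat (m/s)."""
        return 2.0 * self.flow_rate / (math.pi * self.throat_radius**2)


def cosine_stenosis_radius(axial_position, spec: PhantomSpec):
    """Lumen wall radius r(x) of the cosine stenosis (m).

    The constriction is a raised-cosine dip of length ``L = D`` centred at
    x = 0, blended smoothly into a post-stenotic dilatation plateau of radius
    ``psd_factor * D / 2`` over a further diameter:

        r(x) = R0 - (R0 - r_t) (1 + cos(2 pi x / L)) / 2,  |x| <= L/2.

    Positions outside the full [-4 D, +21 D] domain raise ``ValueError``.
    """
    x = np.asarray(axial_position, dtype=np.float64)
    D = spec.upstream_diameter
    lo, hi = (d * D for d in AXIAL_DOMAIN_DIAMETERS)
    if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
        raise ValueError(
            f"axial position outside the phantom domain [{lo:.4g}, {hi:.4g}] m")

    r0 = spec.radius
    rt = spec.throat_radius
    rp = spec.psd_radius
    half = 0.5 * D          # half throat length
    blend = D               # PSD blending length

    r = np.full(x.shape, r0, dtype=np.float64)
    in_throat = np.abs(x) <= half
    r[in_throat] = r0 - (r0 - rt) * (1.0 + np.cos(2.0 * np.pi * x[in_throat] / D)) / 2.0
    in_blend = (x > half) & (x < half + blend)
    r[in_blend] = r0 + (rp - r0) * (1.0 - np.cos(np.pi * (x[in_blend] - half) / blend)) / 2.0
    r[x >= half + blend] = rp
    if np.isscalar(axial_position) or np.ndim(axial_position) == 0:
        return float(r)
    return r


def _jet_profile_radius(x: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Radius of the parabolic velocity profile along the axis.

    Upstream of the throat minimum (x = 0) the profile fills the converging
    lumen.  Downstream the jet separates at the throat radius, holds it over
    a potential core of ``jet_core_length`` diameters, then spreads linearly
    until it re-attaches to the (possibly dilated) wall.
    """
    wall = np.asarray(cosine_stenosis_radius(x, spec))
    x_core = spec.jet_core_length * spec.upstream_diameter
    rj = spec.throat_radius + spec.jet_spread_rate * np.maximum(x - x_core, 0.0)
    return np.where(x <= 0.0, wall, np.minimum(rj, wall))


@dataclass
class FlowPhantom:
    """Fine-grid ground-truth flow realisation.

    Attributes
    ----------
    x, y, z:
        1-D cell-centre coordinates (m); ``x`` is the flow axis.
    mask:
        Boolean lumen mask, shape ``(nx, ny, nz)``; velocity is exactly zero
        outside (no-slip wall).
    mean_velocity:
        Mean velocity field U_i, shape ``(nx, ny, nz, 3)`` (m/s), float32.
    reynolds_tensor:
        Packed symmetric <u'_i u'_j>, shape ``(nx, ny, nz, 6)`` (m^2/s^2),
        component order (xx, yy, zz, xy, xz, yz).
    snapshots:
        Instantaneous velocity ensemble, shape ``(n, nx, ny, nz, 3)``, float32.
    """

    spec: PhantomSpec
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    mean_velocity: np.ndarray
    reynolds_tensor: np.ndarray
    snapshots: np.ndarray
    snapshot_times: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def grid_spacing(self) -> float:
        return self.spec.grid_spacing

    @property
    def n_snapshots(self) -> int:
        return self.snapshots.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def peak_tke_index(self) -> tuple[int, int, int]:
        """Grid index of the maximum prescribed turbulent kinetic energy."""
        k = trace(self.reynolds_tensor)
        return tuple(int(i) for i in np.unravel_index(np.argmax(k), k.shape))

    def axial_flow_rate(self) -> np.ndarray:
        """Discrete volumetric flow rate through each cross-section (m^3/s)."""
        h = self.grid_spacing
        return self.mean_velocity[..., 0].sum(axis=(1, 2)) * h * h


def generate_phantom(spec: PhantomSpec, n_snapshots: int = 25,
                     snapshot_interval: float = 0.015) -> FlowPhantom:
    """Generate the synthetic turbulent stenotic-jet phantom.

    The mean field is a parabolic (Poiseuille-family) profile carried through
    the constriction into a spreading free jet, with the radial velocity
    obtained from axisymmetric continuity so that streamlines follow the
    contracting/spreading jet and the volumetric flow rate is conserved at
    every section.  Fluctuations are zero-mean Gaussian with pointwise
    covariance equal to the prescribed Reynolds tensor, realised through an
    analytic Cholesky factor in the local (axial, radial, azimuthal) frame,
    independent between snapshots, and reproducible from ``spec.seed``.
    """
    if n_snapshots < 2:
        raise ValueError("n_snapshots must be >= 2")
    if snapshot_interval <= 0.0:
        raise ValueError("snapshot_interval must be positive")

    D = spec.upstream_diameter
    h = spec.grid_spacing
    lo, hi = (d * D for d in spec.axial_extent)

    nx = int(round((hi - lo) / h))
    x = lo + (np.arange(nx) + 0.5) * h
    half_width = spec.psd_radius + 2.0 * h
    nhalf = int(math.ceil(half_width / h))
    ny = nz = 2 * nhalf
    y = (np.arange(ny) - (ny - 1) / 2.0) * h
    z = y.copy()

    rad = np.sqrt(y[:, None] ** 2 + z[None, :] ** 2)            # (ny, nz)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(rad > 0, y[:, None] / np.where(rad > 0, rad, 1.0), 1.0)
        sin_t = np.where(rad > 0, z[None, :] / np.where(rad > 0, rad, 1.0), 0.0)

    wall = np.asarray(cosine_stenosis_radius(x, spec))          # (nx,)
    mask = rad[None, :, :] < wall[:, None, None]

    # ---- mean velocity ----------------------------------------------------
    rp = _jet_profile_radius(x, spec)                           # (nx,)
    drp = np.gradient(rp, h)
    q2 = 2.0 * spec.flow_rate / math.pi                         # 2 Q / pi
    uc = q2 / rp**2                                             # centreline velocity

    eta = rad[None, :, :] / rp[:, None, None]
    core = (eta < 1.0) & mask
    shape_fn = np.clip(1.0 - eta**2, 0.0, None)
    u_ax = np.where(core, uc[:, None, None] * shape_fn, 0.0)
    # radial velocity from continuity of the parabolic jet profile:
    #   u_r = U_c r_p'(x) eta (1 - eta^2)
    u_r = np.where(core, uc[:, None, None] * drp[:, None, None] * eta * shape_fn, 0.0)

    mean_velocity = np.empty((nx, ny, nz, 3), dtype=np.float32)
    mean_velocity[..., 0] = u_ax
    mean_velocity[..., 1] = u_r * cos_t[None, :, :]
    mean_velocity[..., 2] = u_r * sin_t[None, :, :]

    # ---- prescribed Reynolds tensor --------------------------------------
    # Mixing-length-style closure: the axial fluctuation std follows the local
    # mean shear of the parabolic jet, sigma_a = I * ell * |du/dr| with
    # ell = I_ratio * r_p, i.e. sigma_a = 2 I U_c(x) eta inside the jet, with a
    # Gaussian tail into the recirculation region outside the jet edge.  An
    # asymmetric axial envelope suppresses fluctuations in the accelerating
    # nozzle (turbulence develops downstream of the throat, peaks ~1.5 D
    # after it and decays slowly with the spreading jet).
    x_peak = 1.5 * D
    w_up, w_down = 0.8 * D, 2.5 * D
    g_ax = np.where(x < x_peak,
                    np.exp(-((x - x_peak) / w_up) ** 2),
                    np.exp(-((x - x_peak) / w_down) ** 2))      # (nx,)
    edge_tail = np.exp(-(((eta - 1.0) / 0.25) ** 2))
    shear_env = np.where(eta < 1.0, eta, edge_tail)

    sigma_a = (2.0 * spec.turbulence_intensity * uc[:, None, None]
               * g_ax[:, None, None] * shear_env)
    sigma_a = np.where(mask, sigma_a, 0.0).astype(np.float32)
    sigma_r = np.float32(0.6) * sigma_a                         # radial std
    sigma_t = sigma_r                                           # azimuthal std
    c = spec.shear_correlation
    # <u'_ax u'_rad> > 0 drives positive production against du/dr < 0
    t_ar = np.float32(c) * sigma_a * sigma_r

    cs = cos_t[None, :, :].astype(np.float32)
    sn = sin_t[None, :, :].astype(np.float32)
    tensor = np.empty((nx, ny, nz, 6), dtype=np.float32)
    tensor[..., 0] = sigma_a**2
    tensor[..., 1] = sigma_r**2 * cs**2 + sigma_t**2 * sn**2
    tensor[..., 2] = sigma_r**2 * sn**2 + sigma_t**2 * cs**2
    tensor[..., 3] = t_ar * cs
    tensor[..., 4] = t_ar * sn
    tensor[..., 5] = (sigma_r**2 - sigma_t**2) * cs * sn

    # ---- snapshot ensemble ------------------------------------------------
    # Local-frame Cholesky factor of the (axial, radial, azimuthal) covariance.
    l21 = np.float32(c) * sigma_r
    l22 = np.float32(math.sqrt(1.0 - c * c)) * sigma_r
    rng = np.random.default_rng(spec.seed)
    snapshots = np.empty((n_snapshots, nx, ny, nz, 3), dtype=np.float32)
    for k in range(n_snapshots):
        if spec.turbulence_intensity == 0.0:
            snapshots[k] = mean_velocity
            continue
        xi = rng.standard_normal((nx, ny, nz, 3), dtype=np.float32)
        d_a = sigma_a * xi[..., 0]
        d_r = l21 * xi[..., 0] + l22 * xi[..., 1]
        d_t = sigma_t * xi[..., 2]
        snapshots[k, ..., 0] = mean_velocity[..., 0] + d_a
        snapshots[k, ..., 1] = mean_velocity[..., 1] + d_r * cs - d_t * sn
        snapshots[k, ..., 2] = mean_velocity[..., 2] + d_r * sn + d_t * cs

    times = np.arange(n_snapshots) * snapshot_interval
    return FlowPhantom(
        spec=spec, x=x, y=y, z=z, mask=mask,
        mean_velocity=mean_velocity, reynolds_tensor=tensor,
        snapshots=snapshots, snapshot_times=times,
    )
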