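"""HDF5 / VTK / CSV persistence and YAML run configuration.

HDF5 is the primary interchange format: multi-component volumes are stored as
datasets with mandatory attributes (``spacing``, ``origin``, ``units``,
``component_order`` where applicable) plus file-level provenance
(``schema_version``, ``tool_version``, ``config_hash``).  Reads validate the
schema version and the presence of units, so a mismatched or under-described
file fails loudly rather than silently misinterpreting data.

A minimal legacy-ASCII VTK writer (structured points for volumes, polydata
for pathlines) is included for visualisation since no VTK library backs this
environment; it writes only, and stays byte-for-byte deterministic.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .bdi import DamageModel
from .mri import Acquisition, AcquisitionSettings
from .phantom import FlowPhantom, PhantomSpec
from .recon import ReconVolume
from .stress import StressMaps
from .tensors import PACKED_ORDER

__all__ = [
    "SCHEMA_VERSION",
    "IcosaflowIOError",
    "RunConfig",
    "load_config",
    "config_hash",
    "save_phantom",
    "load_phantom",
    "save_acquisition",
    "load_acquisition",
    "save_recon_volume",
    "load_recon_volume",
    "save_stress_maps",
    "write_vtk_structured_points",
    "write_vtk_polylines",
]

SCHEMA_VERSION = "1"


class IcosaflowIOError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# run configuration (YAML, schema-validated)
# ---------------------------------------------------------------------------

class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    upstream_diameter: float = 0.0146
    area_reduction: float = 0.75
    psd_factor: float = 1.0
    reynolds_number: float = 2000.0
    density: float = 997.0
    dynamic_viscosity: float = 8.899e-4
    grid_spacing: float = 0.25e-3
    axial_extent: tuple[float, float] = (-2.0, 6.0)
    turbulence_intensity: float = 0.20
    shear_correlation: float = 0.45
    jet_spread_rate: float = 0.15
    n_snapshots: int = 25
    snapshot_interval: float = 0.015

    def to_spec(self, seed: int = 0) -> PhantomSpec:
        data = self.model_dump()
        data.pop("n_snapshots")
        data.pop("snapshot_interval")
        return PhantomSpec(**data, seed=seed)


class AcquisitionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    voxel_size: float = 1.0e-3
    venc: float | None = None           # None: auto from the phantom
    venc_margin: float = 1.2
    snr: float = math.inf
    signal_scale: float = 1.0
    lumen_fraction_threshold: float = 0.5

    def to_settings(self, venc: float, seed: int = 0) -> AcquisitionSettings:
        return AcquisitionSettings(
            voxel_size=self.voxel_size, venc=self.venc or venc, snr=self.snr,
            seed=seed, signal_scale=self.signal_scale,
            lumen_fraction_threshold=self.lumen_fraction_threshold)


class DamageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    exponent_a: float = 0.785
    exponent_b: float = 2.416
    coefficient_c: float = 3.62e-5
    stress_source: str = "tvss"
    squared_stress_mode: bool = True
    n_pathlines: int = 2000
    step_dt: float = 5e-4
    max_steps: int = 6000

    def to_model(self) -> DamageModel:
        return DamageModel(
            exponent_a=self.exponent_a, exponent_b=self.exponent_b,
            coefficient_c=self.coefficient_c, stress_source=self.stress_source,
            squared_stress_mode=self.squared_stress_mode)


class SweepSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    voxel_sizes: list[float] = Field(
        default_factory=lambda: [round(1.0e-3 + 0.2e-3 * i, 10) for i in range(11)])
    snr_levels: list[float] = Field(
        default_factory=lambda: [2, 5, 10, 20, 40, 80, math.inf])
    n_repetitions: int = 10
    include_bdi: bool = True
    bdi_snr_levels: list[float] | None = [40.0, 80.0, math.inf]


class RunConfig(BaseModel):
    """Validated top-level run configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    damage: DamageConfig = Field(default_factory=DamageConfig)
    sweep: SweepSection = Field(default_factory=SweepSection)
    output_dir: str = "icosaflow_out"
    log_level: str = "INFO"
    seed: int = 0


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of a configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# HDF5 volumes
# ---------------------------------------------------------------------------

def _write_provenance(fh: h5py.File, kind: str, config_digest: str | None) -> None:
    fh.attrs["schema_version"] = SCHEMA_VERSION
    fh.attrs["tool_version"] = __version__
    fh.attrs["kind"] = kind
    if config_digest is not None:
        fh.attrs["config_hash"] = config_digest


def _check_provenance(fh: h5py.File, kind: str) -> None:
    found = fh.attrs.get("schema_version")
    if found != SCHEMA_VERSION:
        raise IcosaflowIOError(
            f"schema version mismatch: expected {SCHEMA_VERSION!r}, found {found!r}")
    if fh.attrs.get("kind") != kind:
        raise IcosaflowIOError(
            f"expected a {kind!r} file, found {fh.attrs.get('kind')!r}")


def _dset(group, name, data, units: str, **attrs) -> None:
    d = group.create_dataset(name, data=data)
    d.attrs["units"] = units
    for k, v in attrs.items():
        d.attrs[k] = v


def _require_units(dset, name: str) -> None:
    if "units" not in dset.attrs:
        raise IcosaflowIOError(f"dataset {name!r} is missing the 'units' attribute")


def save_phantom(path, phantom: FlowPhantom, config_digest: str | None = None) -> None:
    spec = phantom.spec
    with h5py.File(path, "w") as fh:
        _write_provenance(fh, "phantom", config_digest)
        for k, v in vars(spec).items():
            fh.attrs[f"spec_{k}"] = v
        _dset(fh, "x", phantom.x, "m")
        _dset(fh, "y", phantom.y, "m")
        _dset(fh, "z", phantom.z, "m")
        _dset(fh, "mask", phantom.mask.astype(np.uint8), "bool")
        _dset(fh, "mean_velocity", phantom.mean_velocity, "m/s",
              component_order="x,y,z")
        _dset(fh, "reynolds_tensor", phantom.reynolds_tensor, "m^2/s^2",
              component_order=",".join(PACKED_ORDER))
        _dset(fh, "snapshots", phantom.snapshots, "m/s", component_order="x,y,z")
        _dset(fh, "snapshot_times", phantom.snapshot_times, "s")


def load_phantom(path) -> FlowPhantom:
    with h5py.File(path, "r") as fh:
        _check_provenance(fh, "phantom")
        spec_kwargs = {}
        for k, v in fh.attrs.items():
            if k.startswith("spec_"):
                name = k[len("spec_"):]
                if name == "axial_extent":
                    v = tuple(float(t) for t in v)
                elif name == "seed":
                    v = int(v)
                else:
                    v = float(v)
                spec_kwargs[name] = v
        spec = PhantomSpec(**spec_kwargs)
        for name in ("x", "y", "z", "mask", "mean_velocity",
                     "reynolds_tensor", "snapshots", "snapshot_times"):
            _require_units(fh[name], name)
        return FlowPhantom(
            spec=spec,
            x=fh["x"][...], y=fh["y"][...], z=fh["z"][...],
            mask=fh["mask"][...].astype(bool),
            mean_velocity=fh["mean_velocity"][...],
            reynolds_tensor=fh["reynolds_tensor"][...],
            snapshots=fh["snapshots"][...],
            snapshot_times=fh["snapshot_times"][...],
        )


def save_acquisition(path, acq: Acquisition, config_digest: str | None = None) -> None:
    s = acq.settings
    with h5py.File(path, "w") as fh:
        _write_provenance(fh, "acquisition", config_digest)
        fh.attrs.update({
            "voxel_size": s.voxel_size, "venc": s.venc, "snr": s.snr,
            "seed": s.seed, "signal_scale": s.signal_scale,
            "lumen_fraction_threshold": s.lumen_fraction_threshold,
            "density": acq.density, "viscosity": acq.viscosity,
            "bulk_velocity": acq.bulk_velocity, "lumen_radius": acq.lumen_radius,
            "noise_snr": acq.noise_snr,
            "noise_seed": -1 if acq.noise_seed is None else acq.noise_seed,
        })
        _dset(fh, "x", acq.x, "m")
        _dset(fh, "y", acq.y, "m")
        _dset(fh, "z", acq.z, "m")
        _dset(fh, "directions", acq.directions, "unit")
        _dset(fh, "lumen_fraction", acq.lumen_fraction, "fraction")
        _dset(fh, "valid_mask", acq.valid_mask.astype(np.uint8), "bool")
        _dset(fh, "mag_s0", acq.mag_s0, "a.u.")
        _dset(fh, "signals", acq.signals, "a.u.")
        _dset(fh, "v_dir", acq.v_dir, "m/s")
        _dset(fh, "velocity", acq.velocity, "m/s", component_order="x,y,z")


def load_acquisition(path) -> Acquisition:
    with h5py.File(path, "r") as fh:
        _check_provenance(fh, "acquisition")
        a = fh.attrs
        settings = AcquisitionSettings(
            voxel_size=float(a["voxel_size"]), venc=float(a["venc"]),
            snr=float(a["snr"]), seed=int(a["seed"]),
            signal_scale=float(a["signal_scale"]),
            lumen_fraction_threshold=float(a["lumen_fraction_threshold"]))
        for name in ("x", "y", "z", "lumen_fraction", "mag_s0", "signals",
                     "v_dir", "velocity"):
            _require_units(fh[name], name)
        noise_seed = int(a["noise_seed"])
        return Acquisition(
            settings=settings, directions=fh["directions"][...],
            x=fh["x"][...], y=fh["y"][...], z=fh["z"][...],
            lumen_fraction=fh["lumen_fraction"][...],
            valid_mask=fh["valid_mask"][...].astype(bool),
            mag_s0=fh["mag_s0"][...], signals=fh["signals"][...],
            v_dir=fh["v_dir"][...], velocity=fh["velocity"][...],
            density=float(a["density"]), viscosity=float(a["viscosity"]),
            bulk_velocity=float(a["bulk_velocity"]),
            lumen_radius=float(a["lumen_radius"]),
            noise_snr=float(a["noise_snr"]),
            noise_seed=None if noise_seed < 0 else noise_seed,
        )


def save_recon_volume(path, recon: ReconVolume, config_digest: str | None = None) -> None:
    with h5py.File(path, "w") as fh:
        _write_provenance(fh, "recon", config_digest)
        fh.attrs.update({
            "voxel_size": recon.voxel_size, "density": recon.density,
            "viscosity": recon.viscosity, "bulk_velocity": recon.bulk_velocity,
            "lumen_radius": recon.lumen_radius,
        })
        _dset(fh, "x", recon.x, "m")
        _dset(fh, "y", recon.y, "m")
        _dset(fh, "z", recon.z, "m")
        _dset(fh, "velocity", recon.velocity, "m/s", component_order="x,y,z")
        _dset(fh, "ivsd", recon.ivsd, "m/s")
        _dset(fh, "reynolds_tensor", recon.reynolds_tensor, "m^2/s^2",
              component_order=",".join(PACKED_ORDER))
        _dset(fh, "valid_mask", recon.valid_mask.astype(np.uint8), "bool")
        _dset(fh, "clipped_mask", recon.clipped_mask.astype(np.uint8), "bool")
        _dset(fh, "negative_diag_mask",
              recon.negative_diag_mask.astype(np.uint8), "bool")


def load_recon_volume(path) -> ReconVolume:
    with h5py.File(path, "r") as fh:
        _check_provenance(fh, "recon")
        a = fh.attrs
        for name in ("x", "y", "z", "velocity", "ivsd", "reynolds_tensor"):
            _require_units(fh[name], name)
        return ReconVolume(
            x=fh["x"][...], y=fh["y"][...], z=fh["z"][...],
            voxel_size=float(a["voxel_size"]),
            velocity=fh["velocity"][...], ivsd=fh["ivsd"][...],
            reynolds_tensor=fh["reynolds_tensor"][...],
            valid_mask=fh["valid_mask"][...].astype(bool),
            clipped_mask=fh["clipped_mask"][...].astype(bool),
            negative_diag_mask=fh["negative_diag_mask"][...].astype(bool),
            density=float(a["density"]), viscosity=float(a["viscosity"]),
            bulk_velocity=float(a["bulk_velocity"]),
            lumen_radius=float(a["lumen_radius"]),
        )


def save_stress_maps(path, maps: StressMaps, config_digest: str | None = None) -> None:
    with h5py.File(path, "w") as fh:
        _write_provenance(fh, "stress_maps", config_digest)
        fh.attrs["spacing"] = maps.spacing
        _dset(fh, "valid_mask", maps.valid_mask.astype(np.uint8), "bool")
        _dset(fh, "tke", maps.tke, "J/m^3")
        _dset(fh, "plvs", maps.plvs, "N/m^2")
        _dset(fh, "prss", maps.prss, "N/m^2")
        _dset(fh, "production", maps.production, "W/m^3")
        _dset(fh, "tvss", maps.tvss, "N/m^2")
        _dset(fh, "tvss_defined", maps.tvss_defined.astype(np.uint8), "bool")
        _dset(fh, "signed_tvss_sq", maps.signed_tvss_sq, "N^2/m^4")


# ---------------------------------------------------------------------------
# legacy-ASCII VTK export (write-only)
# ---------------------------------------------------------------------------

def write_vtk_structured_points(path, fields: dict[str, np.ndarray],
                                origin, spacing) -> None:
    """Write scalar/vector voxel fields as a legacy-ASCII VTK structured grid.

    VTK orders points with x varying fastest, hence the transposes below.
    NaNs are preserved (ParaView renders them as blank).
    """
    if not fields:
        raise ValueError("no fields to write")
    shapes = {np.asarray(f).shape[:3] for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share the voxel grid shape")
    nx, ny, nz = shapes.pop()
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    org = np.asarray(origin, dtype=float)
    lines = [
        "# vtk DataFile Version 3.0",
        "icosaflow volume export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {org[0]:.9g} {org[1]:.9g} {org[2]:.9g}",
        f"SPACING {sp[0]:.9g} {sp[1]:.9g} {sp[2]:.9g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, data in fields.items():
        arr = np.asarray(data, dtype=np.float64)
        if arr.ndim == 3:
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.transpose(2, 1, 0).ravel()
            lines.extend(f"{v:.7g}" for v in flat)
        elif arr.ndim == 4 and arr.shape[-1] == 3:
            lines.append(f"VECTORS {name} float")
            flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
            lines.extend(f"{v[0]:.7g} {v[1]:.7g} {v[2]:.7g}" for v in flat)
        else:
            raise ValueError(f"field {name!r} must be scalar or 3-vector valued")
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_polylines(path, polylines: list[np.ndarray]) -> None:
    """Write pathlines as legacy-ASCII VTK polydata (one polyline each)."""
    pts = [np.asarray(p, dtype=np.float64).reshape(-1, 3) for p in polylines]
    n_pts = sum(p.shape[0] for p in pts)
    lines = [
        "# vtk DataFile Version 3.0",
        "icosaflow pathlines",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n_pts} float",
    ]
    for p in pts:
        lines.extend(f"{q[0]:.7g} {q[1]:.7g} {q[2]:.7g}" for q in p)
    size = sum(p.shape[0] + 1 for p in pts)
    lines.append(f"LINES {len(pts)} {size}")
    offset = 0
    for p in pts:
        ids = " ".join(str(offset + i) for i in range(p.shape[0]))
        lines.append(f"{p.shape[0]} {ids}")
        offset += p.shape[0]
    Path(path).write_text("\n".join(lines) + "\n")
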