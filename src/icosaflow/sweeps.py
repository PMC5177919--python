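"""Voxel-size and SNR evaluation sweeps with agreement statistics.

Orchestrates the two study designs:

* a noise-free **resolution sweep** over a grid of phantom cases and isotropic
  voxel sizes, pairing the simulated volumetric stress sums with ground-truth
  sums computed directly from the fine-grid phantom fields, followed by linear
  regression per voxel size (slope trends: decreasing for PLVS, increasing for
  PRSS as voxels grow);
* an **SNR sweep** at fixed voxel size with repeated noise realisations, where
  every metric is normalised to its own noise-free value (the SNR = inf entry
  is exactly 1 by construction).  Repetition seeds are ``base_seed + index``
  and are shared across SNR levels, so each repetition sees paired noise draws
  scaled to the level's amplitude.

Agreement between paired (ground truth, simulated) values is summarised by
ordinary least squares (slope, intercept, R^2, p) and Bland-Altman statistics
(bias of the differences simulated - truth and mean +/- 1.96 SD limits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bdi import DamageModel, compute_bdi
from .mri import AcquisitionSettings, add_noise, simulate_acquisition, suggest_venc
from .phantom import PhantomSpec, generate_phantom
from .recon import reconstruct
from .stress import compute_stress_maps, ground_truth_stress_maps

__all__ = [
    "SweepConfig",
    "AgreementReport",
    "run_resolution_sweep",
    "run_snr_sweep",
    "regression_and_bland_altman",
    "resolution_slopes",
    "mean_underestimation_percent",
]

STRESS_METRICS = ("tke_sum", "plvs_sum", "prss_sum", "tvss_sum", "tvss_sq_sum_signed")


def _default_voxel_sizes() -> tuple[float, ...]:
    """1.0 to 3.0 mm at 0.2 mm intervals."""
    return tuple(np.round(np.arange(1.0, 3.01, 0.2), 10) * 1e-3)


def _default_specs() -> tuple[PhantomSpec, ...]:
    """Reduced case grid: 2 severities x 1 PSD x 3 Reynolds numbers."""
    return tuple(
        PhantomSpec(area_reduction=sev, reynolds_number=re, seed=i)
        for i, (sev, re) in enumerate(
            (s, r) for s in (0.60, 0.75) for r in (1000.0, 2000.0, 4000.0))
    )


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of the evaluation experiments.

    ``snr_voxel_size`` fixes the acquisition resolution of the SNR sweep
    (1 mm).  ``bdi_snr_levels`` restricts the (costly) pathline/BDI metric to
    a subset of the SNR levels; ``None`` runs it at every level.
    """

    specs: tuple[PhantomSpec, ...] = field(default_factory=_default_specs)
    voxel_sizes: tuple[float, ...] = field(default_factory=_default_voxel_sizes)
    snr_levels: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 40.0, 80.0, math.inf)
    n_repetitions: int = 10
    base_seed: int = 0
    n_snapshots: int = 25
    snapshot_interval: float = 0.015
    venc_margin: float = 1.2
    snr_voxel_size: float = 1.0e-3
    include_bdi: bool = True
    bdi_snr_levels: tuple[float, ...] | None = (40.0, 80.0, math.inf)
    damage_model: DamageModel = field(default_factory=DamageModel)
    n_pathlines: int = 2000
    pathline_dt: float = 5e-4
    pathline_max_steps: int = 6000

    def __post_init__(self) -> None:
        if not self.specs or not self.voxel_sizes or not self.snr_levels:
            raise ValueError("specs, voxel_sizes and snr_levels must be non-empty")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass(frozen=True)
class AgreementReport:
    """OLS regression and Bland-Altman agreement of paired measurements."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    bias: float
    loa_lower: float
    loa_upper: float
    n: int


def regression_and_bland_altman(truth, simulated) -> AgreementReport:
    """Agreement statistics for paired (ground-truth, simulated) values.

    Regression is ordinary least squares of simulated on truth; differences
    are analysed as simulated - truth with 95% limits of agreement
    ``bias +/- 1.96 SD``.  A constant ground-truth vector leaves R^2 and the
    slope p-value undefined (NaN).
    """
    x = np.asarray(truth, dtype=np.float64)
    y = np.asarray(simulated, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 pairs of equal length")
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(x) == 0.0:
        return AgreementReport(slope=math.nan, intercept=float(y.mean()),
                               r_squared=math.nan, p_value=math.nan,
                               bias=bias, loa_lower=bias - 1.96 * sd,
                               loa_upper=bias + 1.96 * sd, n=x.size)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return AgreementReport(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_squared=float(model.rsquared), p_value=float(model.pvalues[1]),
        bias=bias, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
        n=x.size,
    )


def _case_row(spec: PhantomSpec) -> dict:
    return {
        "area_reduction": spec.area_reduction,
        "reynolds_number": spec.reynolds_number,
        "psd_factor": spec.psd_factor,
    }


def run_resolution_sweep(config: SweepConfig) -> pd.DataFrame:
    """Noise-free simulate/reconstruct/stress chain per (case, voxel size).

    Returns a tidy table with one row per case, voxel size and metric, the
    simulated volumetric sum and the paired fine-grid ground-truth sum.
    """
    rows = []
    for case_id, spec in enumerate(config.specs):
        phantom = generate_phantom(spec, config.n_snapshots, config.snapshot_interval)
        truth = ground_truth_stress_maps(phantom).volumetric_sums()
        venc = suggest_venc(phantom, config.venc_margin)
        for dz in config.voxel_sizes:
            settings = AcquisitionSettings(voxel_size=dz, venc=venc)
            maps = compute_stress_maps(reconstruct(simulate_acquisition(phantom, settings)))
            sums = maps.volumetric_sums()
            for metric in STRESS_METRICS:
                rows.append({
                    "case": case_id, **_case_row(spec), "voxel_size": dz,
                    "metric": metric, "value": sums[metric],
                    "truth": truth[metric],
                })
        del phantom
    return pd.DataFrame(rows)


def resolution_slopes(table: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth regression slope per (voxel size, metric) across cases."""
    rows = []
    for (dz, metric), grp in table.groupby(["voxel_size", "metric"]):
        rep = regression_and_bland_altman(grp["truth"], grp["value"])
        rows.append({"voxel_size": dz, "metric": metric, "slope": rep.slope,
                     "r_squared": rep.r_squared, "n": rep.n})
    return pd.DataFrame(rows)


def run_snr_sweep(config: SweepConfig, spec: PhantomSpec | None = None) -> pd.DataFrame:
    """Noise sweep with repetitions at fixed (1 mm default) voxel size.

    One noise-free encode is reused for every noisy realisation.  Each row
    carries the raw metric value and its normalisation to the noise-free
    value; the SNR = inf rows are exactly 1 by construction.
    """
    spec = spec or config.specs[0]
    phantom = generate_phantom(spec, config.n_snapshots, config.snapshot_interval)
    venc = suggest_venc(phantom, config.venc_margin)
    settings = AcquisitionSettings(voxel_size=config.snr_voxel_size, venc=venc)
    acq0 = simulate_acquisition(phantom, settings)
    del phantom

    def metrics_of(acq):
        recon = reconstruct(acq)
        maps = compute_stress_maps(recon)
        return dict(maps.volumetric_sums()), recon, maps

    base, recon0, maps0 = metrics_of(acq0)
    bdi_levels = (set(config.bdi_snr_levels) if config.bdi_snr_levels is not None
                  else set(config.snr_levels) | {math.inf})
    if config.include_bdi:
        base["bdi_median"] = compute_bdi(
            recon0, maps0, config.damage_model,
            n_seeds=config.n_pathlines, step_dt=config.pathline_dt,
            max_steps=config.pathline_max_steps, seed=config.base_seed,
        ).summary.median

    rows = []

    def emit(snr, rep, values):
        for metric, value in values.items():
            ref = base[metric]
            rows.append({
                "snr": snr, "repetition": rep, "metric": metric,
                "value": value,
                "normalized": value / ref if ref != 0.0 else math.nan,
            })

    for snr in config.snr_levels:
        reps = 1 if math.isinf(snr) else config.n_repetitions
        for rep in range(reps):
            seed = config.base_seed + rep
            acq = add_noise(acq0, snr, seed) if not math.isinf(snr) else acq0
            values, recon, maps = metrics_of(acq)
            if config.include_bdi and snr in bdi_levels:
                values["bdi_median"] = compute_bdi(
                    recon, maps, config.damage_model,
                    n_seeds=config.n_pathlines, step_dt=config.pathline_dt,
                    max_steps=config.pathline_max_steps, seed=config.base_seed,
                ).summary.median
            emit(snr, rep, values)
    return pd.DataFrame(rows)


def mean_underestimation_percent(table: pd.DataFrame, metric: str,
                                 snr_levels) -> float:
    """Mean relative underestimation (noise-free - noisy)/noise-free in %.

    Averaged over repetitions and the requested SNR levels; positive values
    mean the noisy measurement underestimates the noise-free one.
    """
    sel = table[(table["metric"] == metric) & (table["snr"].isin(list(snr_levels)))]
    if sel.empty:
        raise ValueError(f"no rows for metric {metric!r} at the requested SNR levels")
    return float((1.0 - sel["normalized"]).mean() * 100.0)
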