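"""Correlation / group-comparison statistics and end-to-end cohort runs.

The cohort runner regenerates, per synthetic patient axis, the whole chain
network -> zone morphometry -> rosette detection -> radial geometry ->
pressure solve -> zone pressure medians, pools one observation per
(sample, axis, zone), and reports the Pearson correlations of the
rosette/network volume ratio against predicted pressure and against network
connectivity, paired/unpaired t-tests between regimes, and percent changes.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import (
    CONTROL_AXIS_MEDIAN_REFERENCE_PA,
    N_ZONES,
    BileParamsConfig,
    CohortOptions,
    SyntheticConfig,
    config_hash,
)
from .netquant import assign_zones, zone_statistics
from .pressure import calibrate_secretion, solve_pressure, zone_pressure_summary
from .rosettes import detect_rosettes, rosette_network_ratio, rosette_volume
from .synthetic import gen_network, network_to_geometry
from .types import BileParams

logger = logging.getLogger("biliflow.report")

__all__ = [
    "pearson_correlation",
    "group_tests",
    "percent_change",
    "bootstrap_correlation_ci",
    "run_cohort",
    "assemble_report",
    "CohortReport",
]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation r of two equally long samples."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equally long 1-d samples")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.any(~np.isfinite(xa)) or np.any(~np.isfinite(ya)):
        raise ValueError("inputs must be finite")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance in one of the samples")
    return float(sps.pearsonr(xa, ya).statistic)


def group_tests(
    control: Sequence[float],
    disease: Sequence[float],
    mode: str = "paired",
) -> tuple[float, float]:
    """Two-tailed t-test between groups; returns (t, p).

    ``paired`` requires equal lengths. Identical paired groups return
    (0.0, 1.0) by convention; constant nonzero paired differences are a
    zero-variance degenerate case and raise.
    """
    c = np.asarray(control, dtype=float)
    d = np.asarray(disease, dtype=float)
    if c.size < 2 or d.size < 2:
        raise ValueError("need at least 2 observations per group")
    if mode == "paired":
        if c.size != d.size:
            raise ValueError("paired mode requires equal lengths")
        diff = d - c
        if np.all(diff == 0):
            return 0.0, 1.0
        if np.std(diff, ddof=1) == 0:
            raise ValueError("paired differences have zero variance")
        res = sps.ttest_rel(d, c)
    elif mode == "unpaired":
        if np.std(c, ddof=1) == 0 and np.std(d, ddof=1) == 0:
            if np.mean(c) == np.mean(d):
                return 0.0, 1.0
            raise ValueError("both groups have zero variance")
        res = sps.ttest_ind(d, c, equal_var=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def percent_change(control: float, disease: float) -> float:
    """Relative change 100 (disease - control) / control, in percent."""
    if control == 0:
        raise ValueError("control value must be nonzero")
    return 100.0 * (disease - control) / control


def bootstrap_correlation_ci(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    clusters: Optional[Sequence] = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for Pearson r over paired observations.

    With ``clusters`` given (e.g. one label per patient axis), whole clusters
    are resampled with replacement: per-zone observations within an axis
    share that axis's geometry and boundary pressure, so row-level
    resampling would understate the sampling variance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    rng = np.random.default_rng([abs(int(seed)), 99])
    rs = []
    if clusters is not None:
        labels = np.asarray(clusters)
        if labels.size != xa.size:
            raise ValueError("clusters must label every observation")
        unique = np.unique(labels)
        groups = [np.flatnonzero(labels == u) for u in unique]
        for _ in range(n_boot):
            pick = rng.integers(0, len(groups), size=len(groups))
            idx = np.concatenate([groups[k] for k in pick])
            xs, ys = xa[idx], ya[idx]
            if np.std(xs) == 0 or np.std(ys) == 0:
                continue
            rs.append(sps.pearsonr(xs, ys).statistic)
    else:
        n = xa.size
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            xs, ys = xa[idx], ya[idx]
            if np.std(xs) == 0 or np.std(ys) == 0:
                continue
            rs.append(sps.pearsonr(xs, ys).statistic)
    lo, hi = np.quantile(rs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    observations: pd.DataFrame  # one row per (sample, axis, zone)
    r_rosette_pressure: float
    r_rosette_connectivity: float
    group_tests: dict
    percent_changes: dict
    axis_summaries: pd.DataFrame  # one row per (sample, axis)
    g_const: float
    seed: int
    provenance: dict = field(default_factory=dict)


def _axis_config(
    base: SyntheticConfig, seed: int, severity: float
) -> SyntheticConfig:
    """Per-axis config with rosette insertion co-varying with dilation.

    A single severity factor scales the rosette fraction and the excess
    radius dilation together, coupling the rosette load to canalicular
    dilation (and hence to predicted pressure) across samples; network
    fragmentation follows the rosette load through the generator's
    rosette_disconnection mechanism.
    """
    return base.model_copy(
        update=dict(
            seed=seed,
            rosette_fraction=min(1.0, base.rosette_fraction * severity),
            radius_dilation_factor=1.0
            + (base.radius_dilation_factor - 1.0) * severity,
        )
    )


def run_cohort(
    seed: int = 0,
    cohort: Optional[CohortOptions] = None,
    control_template: Optional[SyntheticConfig] = None,
    psc_template: Optional[SyntheticConfig] = None,
    bile: Optional[BileParamsConfig] = None,
    n_zones: int = N_ZONES,
    g_const: Optional[float] = None,
    target_control_median_pa: float = CONTROL_AXIS_MEDIAN_REFERENCE_PA,
    solver_tol_pa: float = 0.5,
    ivp_rtol: float = 1e-6,
    ivp_method: str = "LSODA",
) -> CohortReport:
    """Generate a control + disease cohort and run the full analysis chain.

    Secretion is calibrated once, on the geometry of the first control axis,
    against the control reference axis-median pressure, and held identical
    across all patients (bile load is not a fitted per-patient quantity).
    With ``cohort.null`` set, the disease group is generated from the control
    template at the control boundary pressure, removing every regime effect.
    """
    cohort = cohort or CohortOptions()
    control_template = control_template or SyntheticConfig.for_regime("control")
    psc_template = psc_template or SyntheticConfig.for_regime("psc")
    bile = bile or BileParamsConfig()

    rng = np.random.default_rng([abs(int(seed)), 10])

    plan = []  # (sample_id, regime, template, p_duct, n_axes)
    for i in range(cohort.n_control):
        plan.append((f"control_{i}", "control", control_template,
                     bile.p_duct_control_pa, cohort.axes_per_control))
    if cohort.null:
        # no regime effect: both groups share the control geometry, the
        # control boundary pressure and one common rosette fraction (the
        # disease-level load, so the ratio is informative rather than
        # zero-inflated); the engineered rosette-disconnection coupling is
        # switched off, because the null is the generator without the
        # designed co-variation mechanisms
        null_template = control_template.model_copy(
            update={
                "rosette_fraction": psc_template.rosette_fraction,
                "rosette_disconnection": 0.0,
            }
        )
        plan = [
            (sid, regime, null_template, bile.p_duct_control_pa, n_axes)
            for sid, regime, _, _, n_axes in plan
        ]
        plan += [
            (f"psc_{i}", "psc", null_template,
             bile.p_duct_control_pa, cohort.axes_per_psc)
            for i in range(cohort.n_psc)
        ]
    else:
        for i in range(cohort.n_psc):
            plan.append((f"psc_{i}", "psc", psc_template,
                         bile.p_duct_psc_pa, cohort.axes_per_psc))

    obs_rows = []
    axis_rows = []
    g_value = g_const
    p0_hints: dict[str, float] = {}
    for sample_id, regime, template, p_duct, n_axes in plan:
        if cohort.null:
            severity = 1.0  # no regime effect and equal rosette load
        else:
            severity = float(
                np.clip(rng.normal(1.0, cohort.severity_jitter), 0.5, 1.5)
            )
        # per-patient duct boundary pressure (human common-duct baselines
        # span roughly 500-1500 Pa, so patients genuinely differ here)
        p_duct_i = max(
            100.0, p_duct + float(rng.normal(0.0, cohort.duct_pressure_jitter_pa))
        )
        for axis in range(n_axes):
            axis_seed = int(rng.integers(0, 2**31 - 1))
            cfg = _axis_config(template, axis_seed, severity)
            net = gen_network(cfg, n_zones=n_zones)
            zones = assign_zones(net, n_zones)
            zs = zone_statistics(net, n_zones=n_zones, zones=zones)
            _, counts = detect_rosettes(net, n_zones=n_zones, zones=zones)
            v_zone, _ = rosette_volume(counts)
            ratio = rosette_network_ratio(
                v_zone, zs["network_volume_um3"].to_numpy()
            )
            geom = network_to_geometry(net)
            if g_value is None:
                g_value = calibrate_secretion(
                    geom,
                    BileParams(
                        kappa=bile.kappa, R=bile.R, T=bile.T, c0=bile.c0,
                        mu=bile.mu, p_duct=bile.p_duct_control_pa, g=0.0,
                    ),
                    target_control_median_pa,
                    n_zones=n_zones,
                    solver_tol=solver_tol_pa,
                    rtol=ivp_rtol,
                    method=ivp_method,
                )
                logger.info("calibrated g = %.4g mol/(m^3 s)", g_value)
            params = BileParams(
                kappa=bile.kappa, R=bile.R, T=bile.T, c0=bile.c0,
                mu=bile.mu, p_duct=p_duct_i, g=g_value,
            )
            sol = solve_pressure(
                geom, params, tol=solver_tol_pa, rtol=ivp_rtol,
                method=ivp_method, p0_hint=p0_hints.get(regime),
            )
            p0_hints[regime] = sol.p0
            zsum = zone_pressure_summary(sol, n_zones=n_zones)
            axis_rows.append(
                dict(
                    sample=sample_id, axis=axis, regime=regime,
                    severity=severity,
                    axis_median_pa=zsum.axis_median,
                    axis_median_of_zones_pa=zsum.axis_median_of_zones,
                    elevation_pa=zsum.elevation,
                    p0_pa=sol.p0, residual_pa=sol.residual,
                    iterations=sol.iterations,
                    n_rosettes=counts.total,
                )
            )
            for z in range(n_zones):
                obs_rows.append(
                    dict(
                        sample=sample_id, axis=axis, regime=regime, zone=z,
                        rosette_ratio=ratio[z],
                        connectivity=zs.loc[z, "connectivity"],
                        predicted_pressure_pa=zsum.zone_medians[z],
                        mean_radius_um=zs.loc[z, "mean_radius_um"],
                        volume_fraction_pct=zs.loc[z, "volume_fraction_pct"],
                        surface_to_volume_um2_per_mm3=zs.loc[
                            z, "surface_to_volume_um2_per_mm3"
                        ],
                        crossings_per_mm2=zs.loc[z, "crossings_per_mm2"],
                        junctions_per_um=zs.loc[z, "junctions_per_um"],
                    )
                )

    obs = pd.DataFrame.from_records(obs_rows)
    axis_df = pd.DataFrame.from_records(axis_rows)

    ok = obs[["rosette_ratio", "connectivity", "predicted_pressure_pa"]].notna().all(axis=1)
    pooled = obs.loc[ok]
    r_p = pearson_correlation(
        pooled["rosette_ratio"], pooled["predicted_pressure_pa"]
    )
    r_c = pearson_correlation(pooled["rosette_ratio"], pooled["connectivity"])

    # paired tests across zones on per-regime zone means (axes averaged per
    # patient first, then patients averaged); unpaired test on per-axis medians
    tests = {}
    per_patient = (
        obs.groupby(["regime", "sample", "zone"]).mean(numeric_only=True).reset_index()
    )
    zone_means = per_patient.groupby(["regime", "zone"]).mean(numeric_only=True)
    for stat in ("mean_radius_um", "volume_fraction_pct", "connectivity",
                 "rosette_ratio", "predicted_pressure_pa"):
        cvals = zone_means.loc["control"][stat].to_numpy()
        dvals = zone_means.loc["psc"][stat].to_numpy()
        sel = np.isfinite(cvals) & np.isfinite(dvals)
        try:
            t, p = group_tests(cvals[sel], dvals[sel], mode="paired")
            tests[stat] = {"t": t, "p": p, "mode": "paired", "n_zones": int(sel.sum())}
        except ValueError as err:
            tests[stat] = {"error": str(err)}
    t_med, p_med = group_tests(
        axis_df.loc[axis_df.regime == "control", "axis_median_pa"],
        axis_df.loc[axis_df.regime == "psc", "axis_median_pa"],
        mode="unpaired",
    )
    tests["axis_median_pa"] = {"t": t_med, "p": p_med, "mode": "unpaired",
                               "n": int(len(axis_df))}

    changes = {}
    for stat in ("mean_radius_um", "volume_fraction_pct", "connectivity",
                 "predicted_pressure_pa"):
        cm = float(np.nanmean(zone_means.loc["control"][stat]))
        dm = float(np.nanmean(zone_means.loc["psc"][stat]))
        if cm != 0:
            changes[stat] = percent_change(cm, dm)

    return CohortReport(
        observations=obs,
        r_rosette_pressure=r_p,
        r_rosette_connectivity=r_c,
        group_tests=tests,
        percent_changes=changes,
        axis_summaries=axis_df,
        g_const=float(g_value),
        seed=int(seed),
        provenance={
            "control_config_hash": config_hash(control_template),
            "psc_config_hash": config_hash(psc_template),
            "bile_config_hash": config_hash(bile),
            "n_zones": n_zones,
            "null": cohort.null,
        },
    )


def assemble_report(report: CohortReport, out_dir: str | Path) -> Path:
    """Write the cohort report bundle (JSON summary + CSV tables).

    Deterministic: rerunning with the same seed yields byte-identical files
    (no timestamps are embedded).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.observations.to_csv(out / "axis_observations.csv", index=False)
    report.axis_summaries.to_csv(out / "axis_summaries.csv", index=False)
    summary = {
        "seed": report.seed,
        "g_const_mol_m3_s": report.g_const,
        "pearson_r_rosette_ratio_vs_pressure": report.r_rosette_pressure,
        "pearson_r_rosette_ratio_vs_connectivity": report.r_rosette_connectivity,
        "group_tests": report.group_tests,
        "percent_changes": report.percent_changes,
        "provenance": report.provenance,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out / "summary.json"
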