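"""Physical constants, study-condition defaults, and validated run configuration.

All interface lengths are micrometres; the pressure model converts to SI
internally. Concentrations are mmol/l, which equals mol/m^3, so no conversion
is needed there.
"""
from __future__ import annotations

import hashlib
import json
import logging
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger("biliflow")

# ---------------------------------------------------------------------------
# physical constants and literature-anchored parameter values
# ---------------------------------------------------------------------------

GAS_CONSTANT = 8.314462618  # J/(mol K)
BODY_TEMPERATURE_K = 310.0  # K; enters only through the product R*T
BILE_VISCOSITY_PA_S = 9.2e-4  # Pa s
WATER_PERMEABILITY_M_PER_PA_S = 4.7e-10  # m/(Pa s), apical membrane
HEPATOCYTE_OSMOLARITY_MOL_M3 = 300.0  # mol/m^3 == mmol/l
CANALICULAR_TORTUOSITY = 1.8  # path length / straight-line length
FREE_LUMEN_RATIO = 0.28  # fraction of the lumen cross-section open to flow

CONTROL_DUCT_PRESSURE_PA = 1000.0  # hydrostatic pressure at the portal boundary
PSC_DUCT_PRESSURE_PA = 2000.0  # elevated by bile-duct strictures

CONTROL_LOBULE_RADIUS_UM = 512.0  # median CV-edge-to-PV-edge distance, control
PSC_LOBULE_RADIUS_UM = 968.0  # median in PSC
PSC_RADIUS_DILATION = 1.116  # +11.6% mean canalicular radius in PSC
PSC_VOLUME_FRACTION_FACTOR = 0.901  # -9.9% network volume in PSC

# reference axis-median canalicular pressure used to set the secretion
# magnitude for the control regime (the secretion rate itself is inherited
# from prior work and not printed; see calibrate_secretion)
CONTROL_AXIS_MEDIAN_REFERENCE_PA = 1922.0

ROSETTE_DIAMETER_THRESHOLD_UM = 6.0  # strict: diameter > 6 um
ROSETTE_MIN_CELLS = 2  # strict: formed by > 2 hepatocytes
ROSETTE_BIN_MIN_UM = 3  # radius histogram bins j = 3..8 um
ROSETTE_BIN_MAX_UM = 8
ROSETTE_BIN_OFFSET_UM = 0.2  # j_off: rosettes in [j, j+1) average above j
SOX9_NUCLEAR_THRESHOLD = 200.0  # arbitrary units, bile-duct nuclear reference
PANCK_CELLULAR_THRESHOLD = 1000.0  # arbitrary units, bile-duct cell reference

N_ZONES = 11  # CV-PV axis zones 0 (pericentral) .. 10 (periportal)

UM = 1e-6  # metres per micrometre

Regime = Literal["control", "psc"]


# ---------------------------------------------------------------------------
# synthetic-data configuration
# ---------------------------------------------------------------------------

class SyntheticConfig(BaseModel):
    """Study conditions for one synthetic lobule regime.

    Defaults describe the control regime; :meth:`for_regime` applies the
    disease overrides (larger lobule, dilated canaliculi, rosettes, reduced
    connectivity).
    """

    model_config = ConfigDict(extra="forbid", frozen=False)

    regime: Regime = "control"
    seed: int = 0
    lobule_radius_um: float = CONTROL_LOBULE_RADIUS_UM
    cv_radius_um: float = 50.0
    baseline_radius_um: float = 0.6
    radius_dilation_factor: float = 1.0
    rosette_fraction: float = Field(0.002, ge=0.0, le=1.0)
    rosette_radius_range_um: Tuple[float, float] = (3.0, 8.0)
    nodes_per_zone: int = 200
    sox9_positive_fraction: float = Field(0.28, ge=0.0, le=1.0)
    panck_positive_fraction: float = Field(0.04, ge=0.0, le=1.0)
    tissue_depth_um: float = 100.0

    # radial-profile shape
    n_grid: int = 201
    volume_fraction: float = 0.035  # pericentral baseline of eps_BC
    volume_fraction_factor: float = 1.0
    focusing_gradient: float = 0.0  # 0 => constant f = FREE_LUMEN_RATIO

    # network shape
    strip_width_um: Optional[float] = 300.0  # None => fill the full annulus
    knn: int = 4
    edge_dropout: float = Field(0.05, ge=0.0, lt=1.0)  # background loss
    rosette_disconnection: float = Field(0.65, ge=0.0, le=1.0)
    radius_noise_cv: float = 0.15
    rosette_clustering: bool = False

    # 2D section table
    n_rosette_lumina: int = 60
    n_normal_lumina: int = 200
    n_duct_like_lumina: int = 20
    section_area_mm2: float = 3.2

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if not (0.0 < self.cv_radius_um < self.lobule_radius_um):
            raise ValueError(
                f"need 0 < cv_radius ({self.cv_radius_um}) < lobule radius "
                f"({self.lobule_radius_um})"
            )
        if self.baseline_radius_um <= 0:
            raise ValueError("baseline_radius_um must be positive")
        lo, hi = self.rosette_radius_range_um
        if not (3.0 <= lo < hi <= 8.0):
            raise ValueError("rosette_radius_range_um must lie within [3, 8] um")
        if self.nodes_per_zone < 2:
            raise ValueError("need at least 2 nodes per zone")
        if self.n_grid < 8:
            raise ValueError("n_grid too small")
        if not (0.0 < self.volume_fraction * self.volume_fraction_factor <= 0.2):
            raise ValueError("volume fraction must lie in (0, 0.2]")
        if self.tissue_depth_um <= 0:
            raise ValueError("tissue_depth_um must be positive")
        if self.strip_width_um is not None and self.strip_width_um <= 0:
            raise ValueError("strip_width_um must be positive (or None)")
        return self

    @classmethod
    def for_regime(cls, regime: Regime, seed: int = 0, **overrides) -> "SyntheticConfig":
        base = dict(regime=regime, seed=seed)
        if regime == "psc":
            # nodes_per_zone keeps the node density per tissue volume equal
            # to control: PSC zones are ~2x wider along the CV-PV axis
            base.update(
                lobule_radius_um=PSC_LOBULE_RADIUS_UM,
                radius_dilation_factor=PSC_RADIUS_DILATION,
                volume_fraction_factor=PSC_VOLUME_FRACTION_FACTOR,
                rosette_fraction=0.02,
                nodes_per_zone=400,
            )
        base.update(overrides)
        return cls(**base)


class BileParamsConfig(BaseModel):
    """Serializable bile-transport parameter block (SI units)."""

    model_config = ConfigDict(extra="forbid")

    kappa: float = WATER_PERMEABILITY_M_PER_PA_S
    R: float = GAS_CONSTANT
    T: float = BODY_TEMPERATURE_K
    c0: float = HEPATOCYTE_OSMOLARITY_MOL_M3
    mu: float = BILE_VISCOSITY_PA_S
    p_duct_control_pa: float = CONTROL_DUCT_PRESSURE_PA
    p_duct_psc_pa: float = PSC_DUCT_PRESSURE_PA
    g_const: Optional[float] = None  # mol/(m^3 s); None => calibrate

    @model_validator(mode="after")
    def _check(self) -> "BileParamsConfig":
        for name in ("R", "T", "c0", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.g_const is not None and self.g_const < 0:
            raise ValueError("g_const must be non-negative")
        return self


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rosette_diameter_um: float = ROSETTE_DIAMETER_THRESHOLD_UM
    min_bounding_cells: int = ROSETTE_MIN_CELLS
    sox9_nuclear: float = SOX9_NUCLEAR_THRESHOLD
    panck_cellular: float = PANCK_CELLULAR_THRESHOLD


class SolverOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    shooting_tol_pa: float = 0.1
    ivp_rtol: float = 1e-8
    max_p0_pa: float = 1e8
    start_offset_fraction: float = 1e-3  # delta = frac * (L - rho0)


class CohortOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_control: int = 3
    n_psc: int = 4
    axes_per_control: int = 1
    axes_per_psc: int = 3
    severity_jitter: float = 0.15
    duct_pressure_jitter_pa: float = 150.0  # per-patient boundary variation
    null: bool = False  # True => no regime effect (both groups control-like)


class RunConfig(BaseModel):
    """Top-level configuration for an end-to-end synthetic run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_zones: int = N_ZONES
    control: SyntheticConfig = Field(
        default_factory=lambda: SyntheticConfig.for_regime("control")
    )
    psc: SyntheticConfig = Field(
        default_factory=lambda: SyntheticConfig.for_regime("psc")
    )
    bile: BileParamsConfig = Field(default_factory=BileParamsConfig)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    solver: SolverOptions = Field(default_factory=SolverOptions)
    cohort: CohortOptions = Field(default_factory=CohortOptions)


def config_hash(cfg: BaseModel) -> str:
    """Short deterministic hash of a configuration, for provenance headers."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
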