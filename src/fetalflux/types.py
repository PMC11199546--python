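"""Core domain containers and validated configuration models.

Conventions used throughout the package:

* velocities in cm/s, areas in cm^2, flows in mL/min
* oxygen saturations as fractions in [0, 1]
* haemoglobin in g/L, weights in g, volumes in mL
* image stacks are numpy arrays ordered (frame, row, col); pixel indices are
  0-based, row-major
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

Group = Literal["control", "FGR"]
State = Literal["normoxia", "hypoxia"]

GROUPS: tuple[Group, ...] = ("control", "FGR")
STATES: tuple[State, ...] = ("normoxia", "hypoxia")

#: Vessels with a phase-contrast flow measurement.
FLOW_VESSELS: tuple[str, ...] = (
    "UV", "DV", "AAo", "MPA", "DA", "DAo", "SVC",
    "LPA", "RPA", "CCA_left", "CCA_right",
)

#: Vessels with a T2-oximetry saturation measurement.
SAT_VESSELS: tuple[str, ...] = ("UV", "DV", "AAo", "MPA", "DA", "DAo", "SVC")

#: Velocity-encoding limit (cm/s) per vessel: the velocity mapped to a phase
#: of pi in the phase-contrast acquisition.
VENC_CM_S: Dict[str, float] = {
    "AAo": 150.0, "MPA": 150.0, "DAo": 150.0, "DA": 150.0,
    "SVC": 100.0, "CCA_left": 100.0, "CCA_right": 100.0, "DV": 100.0,
    "LPA": 80.0, "RPA": 80.0,
    "UV": 50.0,
}


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# image-series containers
# ---------------------------------------------------------------------------

@dataclass
class CineSeries:
    """A cine phase-contrast acquisition for one vessel.

    ``magnitude`` and ``phase`` are (n_phases, rows, cols); phase values in
    radians in (-pi, pi].  ``venc`` maps a phase of pi to that velocity in
    cm/s; ``pixel_spacing`` is the square in-plane pixel edge in mm.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    venc: float
    pixel_spacing: float
    heart_rate: float
    slice_thickness: float = 5.0

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValidationError("magnitude and phase shapes differ")
        if self.magnitude.ndim != 3:
            raise ValidationError("expected (n_phases, rows, cols) stacks")
        if self.venc <= 0:
            raise ValidationError("venc must be positive")
        if self.pixel_spacing <= 0:
            raise ValidationError("pixel_spacing must be positive")
        if np.any(self.magnitude < 0):
            raise ValidationError("magnitude must be non-negative")

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[0]


@dataclass
class T2Series:
    """A T2-prepared image stack, one frame per preparation time (ms)."""

    images: np.ndarray
    prep_times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.prep_times_ms = np.asarray(self.prep_times_ms, dtype=float)
        if self.images.ndim != 3:
            raise ValidationError("expected (n_prep, rows, cols) stack")
        if len(self.prep_times_ms) != self.images.shape[0]:
            raise ValidationError("one image per preparation time required")
        if np.any(self.prep_times_ms <= 0):
            raise ValidationError("preparation times must be positive")
        if np.any(np.diff(self.prep_times_ms) <= 0):
            raise ValidationError("preparation times must be strictly increasing")


# ---------------------------------------------------------------------------
# measurement results
# ---------------------------------------------------------------------------

@dataclass
class FlowMeasurement:
    vessel: str
    mean_flow: float            # mL/min
    waveform: np.ndarray        # per-cardiac-phase instantaneous flow, mL/min
    n_pixels: int


@dataclass
class T2Fit:
    s0: float
    t2_ms: float
    r_squared: float
    residuals: np.ndarray
    method: str = "iterative"
    at_upper_bound: bool = False


@dataclass
class SaturationMeasurement:
    vessel: str
    y: float                    # fraction in [0, 1]
    clamped: bool = False


@dataclass
class VolumeSegmentation:
    """Integer label map: 0 background, 1 fetal body, 2 brain (brain ⊂ body)."""

    label_map: np.ndarray
    voxel_size_mm3: float

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.voxel_size_mm3 <= 0:
            raise ValidationError("voxel size must be positive")
        bad = set(np.unique(self.label_map)) - {0, 1, 2}
        if bad:
            raise ValidationError(f"unknown labels in segmentation: {sorted(bad)}")


# ---------------------------------------------------------------------------
# subject-level containers
# ---------------------------------------------------------------------------

@dataclass
class CirculationState:
    """One subject in one oxygenation state: measured flows and saturations."""

    subject_id: str
    group: Group
    state: State
    flows: Dict[str, float]          # vessel -> mL/min
    saturations: Dict[str, float]    # vessel -> fraction
    hb_g_per_l: float
    heart_rate: float
    pressures: Optional[Dict[str, float]] = None
    programmed_fo: Optional[float] = None   # generator bookkeeping

    def __post_init__(self) -> None:
        if self.hb_g_per_l <= 0:
            raise ValidationError("haemoglobin must be positive")
        for v, q in self.flows.items():
            if q < 0:
                raise ValidationError(f"negative flow for {v}")
        for v, y in self.saturations.items():
            if not 0.0 <= y <= 1.0:
                raise ValidationError(f"saturation out of [0,1] for {v}")


@dataclass
class Subject:
    subject_id: str
    group: Group
    weight_g: float
    brain_weight_g: float
    states: Dict[State, CirculationState] = field(default_factory=dict)


@dataclass
class DerivedHaemodynamics:
    pbf: float
    rvco: float
    lvco: float
    cvo: float
    fo_flow: float               # derived as LVCO - PBF; not directly measured
    lower_trunk_flow: float      # derived as DAo - UV; not directly measured
    cca_combined: float
    distribution_pct: Dict[str, float]
    delta_so2_aao_mpa: Optional[float] = None   # percentage points
    flags: List[str] = field(default_factory=list)


@dataclass
class OxygenTransport:
    fetal_do2: float
    cerebral_do2: float
    fetal_vo2: float
    cerebral_vo2: float
    fetal_oef: float
    cerebral_oef: float
    fetal_do2_per_kg: Optional[float] = None
    cerebral_do2_per_kg: Optional[float] = None
    fetal_vo2_per_kg: Optional[float] = None
    cerebral_vo2_per_kg: Optional[float] = None
    flags: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# validated configuration models
# ---------------------------------------------------------------------------

class PhantomSpec(BaseModel):
    """Geometry and signal model of a synthetic cine phase-contrast vessel."""

    vessel_radius_px: int = Field(gt=0)
    peak_velocity: float = 20.0           # cm/s at mid-lumen, scaled per phase
    waveform: Optional[List[float]] = None  # per-phase scale; default flat 1.0
    venc: float = Field(default=150.0, gt=0)
    pixel_spacing: float = Field(default=1.0, gt=0)
    slice_thickness: float = Field(default=5.0, gt=0)
    n_phases: int = Field(default=15, ge=1)
    noise_sd_phase: float = Field(default=0.0, ge=0)
    background_offset: float = 0.0
    allow_aliasing: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check_waveform(self) -> "PhantomSpec":
        if self.waveform is not None and len(self.waveform) != self.n_phases:
            raise ValueError("waveform length must equal n_phases")
        wf = np.ones(self.n_phases) if self.waveform is None \
            else np.asarray(self.waveform, dtype=float)
        if not self.allow_aliasing and \
                np.max(np.abs(self.peak_velocity * wf)) > self.venc:
            raise ValueError(
                "peak velocity exceeds VENC; set allow_aliasing=True to "
                "simulate wrap-around deliberately")
        return self

    def waveform_array(self) -> np.ndarray:
        if self.waveform is None:
            return np.ones(self.n_phases)
        return np.asarray(self.waveform, dtype=float)


class T2PhantomSpec(BaseModel):
    """Mono-exponential T2-prepared phantom: S(t) = s0 * exp(-t/T2)."""

    t2_ms: float = Field(gt=0)
    s0: float = Field(gt=0)
    prep_times_ms: List[float] = Field(
        default=[32.0, 64.0, 96.0, 128.0, 160.0, 192.0], min_length=1)
    noise_sd: float = Field(default=0.0, ge=0)
    vessel_radius_px: int = Field(default=10, gt=0)
    seed: int = 0

    @field_validator("prep_times_ms")
    @classmethod
    def _increasing(cls, v: List[float]) -> List[float]:
        arr = np.asarray(v)
        if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
            raise ValueError("prep times must be positive and strictly increasing")
        return v


class CalibrationModel(BaseModel):
    """T2 <-> SO2 calibration: 1/T2 = 1/T2_plateau + K * (1 - Y)^2.

    The defaults are provisional stand-ins of the right order of magnitude
    for fetal sheep blood; a site calibration should replace them.  An
    optional haematocrit adjustment rescales K linearly around a reference
    haematocrit.
    """

    t2_plateau_ms: float = Field(default=250.0, gt=0)
    k_rate: float = Field(default=0.02, ge=0)     # 1/ms
    hct_slope_per_unit: float = 0.0               # dK/dHct, 1/ms per Hct fraction
    hct_reference: float = 0.30
    provisional: bool = True

    def k_for_hct(self, hct: Optional[float] = None) -> float:
        if hct is None:
            return self.k_rate
        return self.k_rate + self.hct_slope_per_unit * (hct - self.hct_reference)


class ConversionFactors(BaseModel):
    """Tissue density factors converting segmented volume (mL) to weight (g).

    Defaults are provisional literature-scale tissue densities, not values
    printed in any single source this package reproduces.
    """

    fetal_g_per_ml: float = Field(default=1.03, gt=0)
    brain_g_per_ml: float = Field(default=1.04, gt=0)
    provisional: bool = True


def _nested(d: dict) -> Dict[str, Dict[str, dict]]:
    return {g: {s: dict(d[g][s]) for s in STATES} for g in GROUPS}


class CohortConfig(BaseModel):
    """Statistical design of the simulated cohort.

    Means/SDs are per group x state.  Saturations, haemoglobin and heart
    rate defaults follow the study design this package emulates; per-vessel
    flow means are NOT ground truth from any publication -- they are
    physiologically plausible fetal-sheep values chosen to be self-consistent
    with the flow-combination rules, and are expected to be edited.
    """

    n_control: int = Field(default=12, gt=0)
    n_fgr: int = Field(default=9, gt=0)
    seed: int = 0

    # effect toggles
    fgr_raises_dv_fo: bool = True
    fgr_lowers_pbf_normoxia_only: bool = True
    hypoxia_lowers_saturations: bool = True

    # group -> state -> vessel -> value; populated by default_tables() when
    # left as None so that the toggles can shape the defaults.
    flow_means: Optional[Dict[str, Dict[str, Dict[str, float]]]] = None
    flow_sds: Optional[Dict[str, Dict[str, Dict[str, float]]]] = None
    sat_means: Optional[Dict[str, Dict[str, Dict[str, float]]]] = None
    sat_sds: Optional[Dict[str, Dict[str, Dict[str, float]]]] = None
    hb_mean: Optional[Dict[str, Dict[str, float]]] = None
    hb_sd: Optional[Dict[str, Dict[str, float]]] = None
    hr_mean: Optional[Dict[str, Dict[str, float]]] = None
    hr_sd: Optional[Dict[str, Dict[str, float]]] = None
    weight_mean_g: Optional[Dict[str, float]] = None
    weight_sd_g: Optional[Dict[str, float]] = None
    brain_weight_mean_g: Optional[Dict[str, float]] = None
    brain_weight_sd_g: Optional[Dict[str, float]] = None

    @model_validator(mode="after")
    def _fill_defaults(self) -> "CohortConfig":
        tables = default_tables(
            fgr_raises_dv_fo=self.fgr_raises_dv_fo,
            fgr_lowers_pbf_normoxia_only=self.fgr_lowers_pbf_normoxia_only,
            hypoxia_lowers_saturations=self.hypoxia_lowers_saturations,
        )
        for name, value in tables.items():
            if getattr(self, name) is None:
                setattr(self, name, value)
        # sanity on the resulting tables
        for g in GROUPS:
            for s in STATES:
                for v, y in self.sat_means[g][s].items():
                    if not 0.0 <= y <= 1.0:
                        raise ValueError(f"saturation mean out of [0,1]: {g}/{s}/{v}")
                for tab in (self.flow_sds[g][s], self.sat_sds[g][s]):
                    for v, sd in tab.items():
                        if sd < 0:
                            raise ValueError("SDs must be non-negative")
        return self


#: Vessels whose flow is drawn directly; MPA is set to DA + LPA + RPA so the
#: generated circulation is conservation-consistent by construction.
DRAWN_FLOW_VESSELS: tuple[str, ...] = (
    "UV", "DV", "AAo", "DA", "DAo", "SVC", "LPA", "RPA",
    "CCA_left", "CCA_right",
)


def default_tables(*, fgr_raises_dv_fo: bool = True,
                   fgr_lowers_pbf_normoxia_only: bool = True,
                   hypoxia_lowers_saturations: bool = True) -> dict:
    """Default group x state mean/SD tables for the simulated cohort.

    Flow means (mL/min) are plausible for a ~1.4-1.8 kg fetal sheep
    (CVO ~ 450 mL/min/kg) and are NOT measured ground truth.  Saturation,
    haemoglobin and heart-rate means/SDs follow the emulated study design.
    Effects the emulated study reports as group differences are programmed at
    roughly two pooled SDs so a 12-vs-9 design detects them reliably; null
    effects are programmed at zero.
    """
    # control flows, identical in both states (no state effect on flows)
    c_flow = {"UV": 350.0, "DV": 110.0, "AAo": 340.0, "DA": 390.0,
              "DAo": 480.0, "SVC": 160.0, "LPA": 35.0, "RPA": 35.0,
              "CCA_left": 50.0, "CCA_right": 50.0}
    flow_sd = {"UV": 45.0, "DV": 25.0, "AAo": 40.0, "DA": 45.0,
               "DAo": 50.0, "SVC": 25.0, "LPA": 8.0, "RPA": 8.0,
               "CCA_left": 8.0, "CCA_right": 8.0}

    f_flow_norm = dict(c_flow)
    f_flow_hyp = dict(c_flow)
    f_flow_norm["UV"] = f_flow_hyp["UV"] = 330.0
    f_flow_norm["DAo"] = f_flow_hyp["DAo"] = 460.0
    if fgr_raises_dv_fo:
        f_flow_norm["DV"] = f_flow_hyp["DV"] = 170.0
        # FO = AAo - PBF by derivation: a larger AAo raises programmed FO
        f_flow_norm["AAo"] = f_flow_hyp["AAo"] = 420.0
    if fgr_lowers_pbf_normoxia_only:
        f_flow_norm["LPA"] = f_flow_norm["RPA"] = 17.5   # PBF 70 -> 35
        f_flow_hyp["LPA"] = f_flow_hyp["RPA"] = 32.5     # PBF ~65, no group gap

    flow_means = {
        "control": {"normoxia": dict(c_flow), "hypoxia": dict(c_flow)},
        "FGR": {"normoxia": f_flow_norm, "hypoxia": f_flow_hyp},
    }
    flow_sds = {g: {s: dict(flow_sd) for s in STATES} for g in GROUPS}

    # saturations (fractions); arterial values follow the emulated design
    c_norm = {"UV": 0.80, "DV": 0.78, "AAo": 0.585, "MPA": 0.50,
              "DA": 0.50, "DAo": 0.52, "SVC": 0.35}
    f_norm = {"UV": 0.70, "DV": 0.68, "AAo": 0.474, "MPA": 0.39,
              "DA": 0.39, "DAo": 0.41, "SVC": 0.26}
    if hypoxia_lowers_saturations:
        c_hyp = {"UV": 0.45, "DV": 0.43, "AAo": 0.29, "MPA": 0.19,
                 "DA": 0.19, "DAo": 0.24, "SVC": 0.06}
        f_hyp = {"UV": 0.42, "DV": 0.40, "AAo": 0.274, "MPA": 0.18,
                 "DA": 0.18, "DAo": 0.23, "SVC": 0.06}
    else:
        c_hyp, f_hyp = dict(c_norm), dict(f_norm)
    sat_sd = {v: 0.07 for v in SAT_VESSELS}
    sat_sd_hyp = dict(sat_sd)
    sat_sd_hyp["SVC"] = 0.03
    sat_means = {"control": {"normoxia": c_norm, "hypoxia": c_hyp},
                 "FGR": {"normoxia": f_norm, "hypoxia": f_hyp}}
    sat_sds = {g: {"normoxia": dict(sat_sd), "hypoxia": dict(sat_sd_hyp)}
               for g in GROUPS}

    return dict(
        flow_means=flow_means, flow_sds=flow_sds,
        sat_means=sat_means, sat_sds=sat_sds,
        hb_mean={"control": {"normoxia": 98.0, "hypoxia": 98.0},
                 "FGR": {"normoxia": 92.0, "hypoxia": 100.0}},
        hb_sd={"control": {"normoxia": 9.0, "hypoxia": 11.0},
               "FGR": {"normoxia": 10.0, "hypoxia": 10.0}},
        hr_mean={"control": {"normoxia": 140.0, "hypoxia": 146.0},
                 "FGR": {"normoxia": 142.0, "hypoxia": 148.0}},
        hr_sd={"control": {"normoxia": 10.0, "hypoxia": 21.0},
               "FGR": {"normoxia": 16.0, "hypoxia": 19.0}},
        weight_mean_g={"control": 1800.0, "FGR": 1400.0},
        weight_sd_g={"control": 200.0, "FGR": 180.0},
        brain_weight_mean_g={"control": 45.0, "FGR": 42.0},
        brain_weight_sd_g={"control": 5.0, "FGR": 5.0},
    )
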