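"""End-to-end orchestration: cohort -> images -> measurements -> statistics.

A run simulates the full study design (two groups, two oxygenation states
per subject), optionally routes every vessel quantity through the imaging
chain (phase-contrast phantom -> flow quantification; T2 phantom -> T2 fit
-> saturation), assembles the circulation, computes oxygen transport, and
runs the per-variable mixed repeated-measures ANOVA with pairwise
comparisons.  All outputs are tidy CSV tables plus a JSON manifest; a rerun
with the same config and seed reproduces every table byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .types import (STATES, SAT_VESSELS, VENC_CM_S, CalibrationModel,
                    CirculationState, CohortConfig, ConversionFactors,
                    PhantomSpec, T2PhantomSpec)
from .synthetic import (make_cohort, make_flow_phantom, make_label_volume,
                        make_t2_phantom, disk_mask)
from .pc_flow import (auto_lumen_mask, correct_background_offset,
                      integrate_flow, phase_to_velocity)
from .t2_oximetry import (erode_to_central_fraction, fit_t2, mean_roi_signal,
                          so2_to_t2, t2_to_so2)
from .circulation import check_conservation, derive_flows
from .oxygen_transport import compute_oxygen_transport
from .biometry import measure_volumes, volumes_to_weights
from .stats import mixed_anova

__all__ = ["RunConfig", "run_pipeline", "run_study", "evaluate_effect_patterns",
           "STUDY_VARIABLES", "PATTERN_CHECKS"]


class RunConfig(BaseModel):
    """Configuration of one reproducible pipeline run."""

    seed: int = 0
    n_control: int = Field(default=12, gt=0)
    n_fgr: int = Field(default=9, gt=0)
    imaging: bool = True                 # route values through image phantoms
    vessel_radius_px: int = Field(default=10, gt=0)
    phase_noise_sd: float = Field(default=0.01, ge=0)   # radians
    t2_noise_sd: float = Field(default=2.0, ge=0)       # signal units, s0=200
    calibration: CalibrationModel = Field(default_factory=CalibrationModel)
    conversion: ConversionFactors = Field(default_factory=ConversionFactors)
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 2.0)
    alpha: float = 0.05
    conservation_tol_pct: float = 1.0
    cohort: Optional[CohortConfig] = None

    def cohort_config(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        return CohortConfig(n_control=self.n_control, n_fgr=self.n_fgr,
                            seed=self.seed)


#: Variables carried into the statistical comparison.
STUDY_VARIABLES = (
    "UV", "DV", "DA", "DAo", "SVC", "CCA", "PBF", "FO", "lower_trunk",
    "RVCO", "LVCO", "CVO", "delta_so2",
    "fetal_do2", "fetal_vo2", "fetal_oef",
    "cerebral_do2", "cerebral_vo2", "cerebral_oef",
    "fetal_do2_per_kg", "fetal_vo2_per_kg",
    "cerebral_do2_per_kg", "cerebral_vo2_per_kg",
)


def _measure_flow(q_ml_min: float, vessel: str, radius_px: int,
                  noise_sd: float, seed: int) -> float:
    """Programme a phantom carrying ``q_ml_min`` and re-measure it."""
    r_cm = radius_px * 1.0 / 10.0
    n_phases = 15
    waveform = (1.0 + 0.3 * np.sin(2 * np.pi * np.arange(n_phases) / n_phases))
    v_peak = 2.0 * q_ml_min / (60.0 * np.pi * r_cm**2)
    spec = PhantomSpec(vessel_radius_px=radius_px, peak_velocity=v_peak,
                       waveform=list(waveform), venc=VENC_CM_S[vessel],
                       noise_sd_phase=noise_sd, background_offset=0.05,
                       n_phases=n_phases, seed=seed)
    series = make_flow_phantom(spec)
    velocity = phase_to_velocity(series)
    lumen = auto_lumen_mask(series)
    static = series.magnitude.mean(axis=0) < 50.0
    velocity = correct_background_offset(velocity, static)
    return integrate_flow(velocity, lumen, series.pixel_spacing,
                          series.heart_rate, vessel).mean_flow


def _measure_saturation(y: float, vessel: str, calib: CalibrationModel,
                        noise_sd: float, seed: int) -> float:
    """Programme a T2 phantom at saturation ``y`` and re-measure it."""
    t2_true = so2_to_t2(y, calib)
    spec = T2PhantomSpec(t2_ms=t2_true, s0=200.0, noise_sd=noise_sd,
                         vessel_radius_px=10, seed=seed)
    series = make_t2_phantom(spec)
    lumen = disk_mask(series.images.shape[1:], spec.vessel_radius_px)
    roi = erode_to_central_fraction(lumen, 0.6)
    fit = fit_t2(mean_roi_signal(series, roi), series.prep_times_ms)
    # near full saturation the calibration flattens (dT2/dY -> 0), so noise
    # can push the fitted T2 past the plateau; treat that as fully saturated
    if fit.t2_ms >= calib.t2_plateau_ms:
        return 1.0
    return t2_to_so2(fit.t2_ms, calib, vessel=vessel, clamp_tolerance=0.1).y


def _measure_weight(weight_g: float, brain_g: float, config: RunConfig,
                    ) -> tuple[float, float, float]:
    """Round-trip weight through volumetry: weight -> label map -> weight."""
    voxel_mm3 = float(np.prod(config.voxel_size_mm))
    fetal_vox = int(round(weight_g / config.conversion.fetal_g_per_ml
                          * 1000.0 / voxel_mm3))
    brain_vox = int(round(brain_g / config.conversion.brain_g_per_ml
                          * 1000.0 / voxel_mm3))
    side = int(np.ceil((fetal_vox + 1) ** (1 / 3))) + 1
    seg = make_label_volume((side, side, side), fetal_vox, brain_vox,
                            config.voxel_size_mm)
    fetal_ml, brain_ml = measure_volumes(seg)
    return volumes_to_weights(fetal_ml, brain_ml, config.conversion)


def run_study(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Execute the full analysis chain in memory; returns tidy tables.

    With ``config.imaging`` the vessel flows and saturations are routed
    through synthetic acquisitions and re-quantified; otherwise the cohort's
    drawn values enter the analysis directly (value-level mode, used for
    replicate statistical studies).
    """
    cohort_cfg = config.cohort_config()
    subjects = make_cohort(cohort_cfg)
    seed_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    flow_rows, sat_rows, derived_rows, oxy_rows = [], [], [], []
    conservation: List[dict] = []
    weight_rows = []

    for subject in subjects:
        fetal_g, brain_g, brain_pct = _measure_weight(
            subject.weight_g, subject.brain_weight_g, config)
        weight_rows.append(dict(subject=subject.subject_id, group=subject.group,
                                fetal_weight_g=fetal_g, brain_weight_g=brain_g,
                                brain_pct_of_body=brain_pct))
        for state in STATES:
            truth = subject.states[state]
            flows: Dict[str, float] = {}
            for vessel, q in truth.flows.items():
                if config.imaging:
                    seed = int(seed_rng.integers(2**31))
                    flows[vessel] = _measure_flow(
                        q, vessel, config.vessel_radius_px,
                        config.phase_noise_sd, seed)
                else:
                    flows[vessel] = q
                flow_rows.append(dict(subject=subject.subject_id,
                                      group=subject.group, state=state,
                                      vessel=vessel, true_flow_ml_min=q,
                                      flow_ml_min=flows[vessel]))
            sats: Dict[str, float] = {}
            for vessel in SAT_VESSELS:
                y = truth.saturations[vessel]
                if config.imaging:
                    seed = int(seed_rng.integers(2**31))
                    sats[vessel] = _measure_saturation(
                        y, vessel, config.calibration, config.t2_noise_sd, seed)
                else:
                    sats[vessel] = y
                sat_rows.append(dict(subject=subject.subject_id,
                                     group=subject.group, state=state,
                                     vessel=vessel, true_y=y, y=sats[vessel]))

            measured = CirculationState(
                subject_id=truth.subject_id, group=truth.group, state=state,
                flows=flows, saturations=sats, hb_g_per_l=truth.hb_g_per_l,
                heart_rate=truth.heart_rate, programmed_fo=truth.programmed_fo)
            derived = derive_flows(measured)
            conservation.append(check_conservation(
                measured, derived, config.conservation_tol_pct))
            oxy = compute_oxygen_transport(measured, derived, fetal_g)

            derived_rows.append(dict(
                subject=subject.subject_id, group=subject.group, state=state,
                PBF=derived.pbf, RVCO=derived.rvco, LVCO=derived.lvco,
                CVO=derived.cvo, FO=derived.fo_flow,
                lower_trunk=derived.lower_trunk_flow, CCA=derived.cca_combined,
                delta_so2=derived.delta_so2_aao_mpa,
                programmed_fo=truth.programmed_fo,
                **{f"pct_cvo_{k}": v for k, v in derived.distribution_pct.items()}))
            oxy_rows.append(dict(
                subject=subject.subject_id, group=subject.group, state=state,
                fetal_do2=oxy.fetal_do2, fetal_vo2=oxy.fetal_vo2,
                fetal_oef=oxy.fetal_oef, cerebral_do2=oxy.cerebral_do2,
                cerebral_vo2=oxy.cerebral_vo2, cerebral_oef=oxy.cerebral_oef,
                fetal_do2_per_kg=oxy.fetal_do2_per_kg,
                fetal_vo2_per_kg=oxy.fetal_vo2_per_kg,
                cerebral_do2_per_kg=oxy.cerebral_do2_per_kg,
                cerebral_vo2_per_kg=oxy.cerebral_vo2_per_kg))

    flows_df = pd.DataFrame(flow_rows)
    sats_df = pd.DataFrame(sat_rows)
    derived_df = pd.DataFrame(derived_rows)
    oxy_df = pd.DataFrame(oxy_rows)
    weights_df = pd.DataFrame(weight_rows)

    tidy = _tidy_study_values(flows_df, derived_df, oxy_df)
    stats_df = analyse_variables(tidy, alpha=config.alpha)

    return {"flows": flows_df, "saturations": sats_df, "derived": derived_df,
            "oxygen": oxy_df, "weights": weights_df, "values": tidy,
            "stats": stats_df,
            "conservation": pd.DataFrame(conservation)}


def _tidy_study_values(flows_df: pd.DataFrame, derived_df: pd.DataFrame,
                       oxy_df: pd.DataFrame) -> pd.DataFrame:
    """One row per subject x state x variable for the statistical layer."""
    rows = []
    direct = flows_df.pivot_table(index=["subject", "group", "state"],
                                  columns="vessel", values="flow_ml_min")
    merged = direct.reset_index().merge(
        derived_df, on=["subject", "group", "state"]).merge(
        oxy_df, on=["subject", "group", "state"])
    for var in STUDY_VARIABLES:
        for _, row in merged.iterrows():
            rows.append(dict(subject=row["subject"], group=row["group"],
                             state=row["state"], variable=var,
                             value=float(row[var])))
    return pd.DataFrame(rows)


def analyse_variables(tidy: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Mixed ANOVA + pairwise comparisons for every variable in a tidy table."""
    out = []
    for var, sub in tidy.groupby("variable", sort=False):
        res = mixed_anova(sub, dv="value", subject="subject",
                          between="group", within="state", alpha=alpha)
        row = dict(variable=var,
                   f_group=res.f_group, p_group=res.p_group,
                   f_state=res.f_state, p_state=res.p_state,
                   f_interaction=res.f_interaction,
                   p_interaction=res.p_interaction)
        for pw in res.pairwise:
            key = (pw.comparison.replace(" vs ", "_vs_")
                   .replace(" @ ", "_at_"))
            row[f"p_adj_{key}"] = pw.p_adjusted
            row[f"sig_{key}"] = pw.significant
        out.append(row)
    return pd.DataFrame(out)


#: Directional pattern checks applied to a stats table: variable, check.
PATTERN_CHECKS = (
    ("DV", "group effect in both states"),
    ("FO", "group effect in both states"),
    ("PBF", "group effect at normoxia only"),
    ("cerebral_do2", "state effect"),
    ("cerebral_oef", "state effect"),
    ("cerebral_vo2", "no state effect"),
)


def evaluate_effect_patterns(stats_df: pd.DataFrame) -> Dict[str, bool]:
    """Check the expected direction-of-effect pattern on a stats table.

    Flags whether the simulated cohort reproduces the qualitative physiology
    the pipeline is designed around: raised ductus-venosus and foramen-ovale
    flow in growth restriction in both oxygenation states, lowered pulmonary
    blood flow in growth restriction at normoxia only, and an acute-hypoxia
    drop in cerebral oxygen delivery met by raised cerebral extraction at
    unchanged cerebral consumption.
    """
    s = stats_df.set_index("variable")
    g_norm = "sig_control_vs_FGR_at_normoxia"
    g_hyp = "sig_control_vs_FGR_at_hypoxia"
    checks = {
        "dv_group_both_states": bool(s.loc["DV", g_norm] and s.loc["DV", g_hyp]),
        "fo_group_both_states": bool(s.loc["FO", g_norm] and s.loc["FO", g_hyp]),
        "pbf_group_normoxia_only": bool(s.loc["PBF", g_norm]
                                        and not s.loc["PBF", g_hyp]),
        "cerebral_do2_state_effect": bool(s.loc["cerebral_do2", "p_state"] < 0.05),
        "cerebral_oef_state_effect": bool(s.loc["cerebral_oef", "p_state"] < 0.05),
        "cerebral_vo2_no_state_effect": bool(
            s.loc["cerebral_vo2", "p_state"] >= 0.05),
    }
    checks["all"] = all(checks.values())
    return checks


def run_pipeline(config: RunConfig, out_dir: Path) -> dict:
    """Run the study and write result tables + manifest to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = run_study(config)

    row_counts = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        row_counts[name] = int(len(df))

    config_json = config.model_dump_json()
    manifest = {
        "seed": config.seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "versions": {"fetalflux": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "row_counts": row_counts,
        "provisional_constants": {
            "t2_so2_calibration": config.calibration.provisional,
            "volume_to_weight_factors": config.conversion.provisional,
            "vessel_flow_means": "not ground truth from any publication",
        },
        "patterns": evaluate_effect_patterns(tables["stats"]),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return manifest
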