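"""Synthetic phantoms and virtual cohorts.

Every downstream stage of the pipeline (phase-contrast flow quantification,
T2 relaxometry, circulation assembly, statistics) is exercised on data from
this module, so the generators implement exactly the signal models the
analysis assumes:

* flow phantoms: fully developed laminar (parabolic) through-plane velocity
  in a circular lumen, encoded as phase = pi * v / VENC wrapped to (-pi, pi],
  plus a constant background phase offset and Gaussian phase noise;
* T2 phantoms: mono-exponential decay S(t) = s0 * exp(-t / T2) plus Gaussian
  noise;
* cohorts: per group x state truncated-normal draws with a repeated-measures
  structure (each subject appears in both oxygenation states) and with the
  flow-combination identities (MPA = DA + PBF, programmed FO = AAo - PBF)
  holding exactly by construction.

All randomness flows through one integer seed per call; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .types import (
    GROUPS, STATES, DRAWN_FLOW_VESSELS, SAT_VESSELS,
    CineSeries, CirculationState, CohortConfig, PhantomSpec, Subject,
    T2PhantomSpec, T2Series, ValidationError, VolumeSegmentation,
)

__all__ = [
    "make_flow_phantom", "make_t2_phantom", "make_cohort",
    "make_label_volume", "disk_mask", "wrap_phase",
]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase values into (-pi, pi]."""
    return -np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi) + np.pi


def disk_mask(shape: tuple[int, int], radius_px: float) -> np.ndarray:
    """Boolean mask of pixels whose centre lies strictly inside a centred disk."""
    rows, cols = shape
    r = np.arange(rows) - (rows - 1) / 2.0
    c = np.arange(cols) - (cols - 1) / 2.0
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return rr**2 + cc**2 < radius_px**2


def _grid_radii(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    r = np.arange(rows) - (rows - 1) / 2.0
    c = np.arange(cols) - (cols - 1) / 2.0
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return np.sqrt(rr**2 + cc**2)


def make_flow_phantom(spec: PhantomSpec) -> CineSeries:
    """Synthesize a cine phase-contrast series for one vessel.

    The in-lumen velocity profile is parabolic, v(d) = v_peak * (1 - (d/R)^2)
    scaled per cardiac phase by ``spec.waveform``; the true volumetric flow of
    the phantom is therefore the closed form  pi R^2 v_peak / 2  (times the
    waveform mean), which serves as the oracle for flow-integration tests.
    """
    rng = np.random.default_rng(spec.seed)
    margin = 6
    side = 2 * (spec.vessel_radius_px + margin) + 1   # odd: centre pixel on axis
    shape = (side, side)
    radii = _grid_radii(shape)
    lumen = radii < spec.vessel_radius_px

    profile = np.zeros(shape)
    profile[lumen] = 1.0 - (radii[lumen] / spec.vessel_radius_px) ** 2

    wf = spec.waveform_array()
    velocity = wf[:, None, None] * spec.peak_velocity * profile[None, :, :]

    phase = np.pi * velocity / spec.venc + spec.background_offset
    if spec.noise_sd_phase > 0:
        phase = phase + rng.normal(0.0, spec.noise_sd_phase, size=phase.shape)
    phase = wrap_phase(phase)

    magnitude = np.where(lumen, 100.0, 20.0)[None, :, :] * np.ones((spec.n_phases, 1, 1))

    return CineSeries(magnitude=magnitude, phase=phase, venc=spec.venc,
                      pixel_spacing=spec.pixel_spacing, heart_rate=140.0,
                      slice_thickness=spec.slice_thickness)


def analytic_phantom_flow(spec: PhantomSpec) -> float:
    """Closed-form mean volumetric flow (mL/min) of a parabolic-profile phantom."""
    r_cm = spec.vessel_radius_px * spec.pixel_spacing / 10.0
    mean_v = spec.peak_velocity / 2.0 * float(np.mean(spec.waveform_array()))
    return np.pi * r_cm**2 * mean_v * 60.0   # cm^3/s -> mL/min


def make_t2_phantom(spec: T2PhantomSpec) -> T2Series:
    """Synthesize a T2-prepared series: in-vessel S(t) = s0 exp(-t/T2) + noise."""
    rng = np.random.default_rng(spec.seed)
    margin = 6
    side = 2 * (spec.vessel_radius_px + margin) + 1
    lumen = disk_mask((side, side), spec.vessel_radius_px)

    prep = np.asarray(spec.prep_times_ms, dtype=float)
    decay = spec.s0 * np.exp(-prep / spec.t2_ms)
    images = np.where(lumen[None, :, :], decay[:, None, None], 0.05 * spec.s0)
    if spec.noise_sd > 0:
        images = images + rng.normal(0.0, spec.noise_sd, size=images.shape)
    return T2Series(images=images, prep_times_ms=prep)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf,
                      max_tries: int = 10000) -> float:
    """One truncated-normal draw by rejection (no point mass at the bounds)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("rejection sampling failed; check means vs bounds")


def make_cohort(config: CohortConfig) -> List[Subject]:
    """Simulate a two-group, two-state repeated-measures cohort.

    Each subject receives one :class:`CirculationState` per oxygenation state.
    Flows are drawn for the directly measured vessels; MPA is then set to
    DA + LPA + RPA exactly, and the foramen-ovale flow implied by the drawn
    values (AAo - LPA - RPA) is recorded as ``programmed_fo`` so end-to-end
    tests can verify the derivation chain reproduces it.
    """
    rng = np.random.default_rng(config.seed)
    subjects: List[Subject] = []
    counts = {"control": config.n_control, "FGR": config.n_fgr}
    for group in GROUPS:
        for i in range(counts[group]):
            sid = f"{'C' if group == 'control' else 'F'}{i + 1:02d}"
            weight = _truncated_normal(rng, config.weight_mean_g[group],
                                       config.weight_sd_g[group], lo=1.0)
            brain = _truncated_normal(rng, config.brain_weight_mean_g[group],
                                      config.brain_weight_sd_g[group],
                                      lo=0.0, hi=weight)
            subject = Subject(subject_id=sid, group=group, weight_g=weight,
                              brain_weight_g=brain)
            for state in STATES:
                flows: Dict[str, float] = {}
                for vessel in DRAWN_FLOW_VESSELS:
                    flows[vessel] = _truncated_normal(
                        rng, config.flow_means[group][state][vessel],
                        config.flow_sds[group][state][vessel], lo=0.0)
                flows["MPA"] = flows["DA"] + flows["LPA"] + flows["RPA"]
                sats: Dict[str, float] = {}
                for vessel in SAT_VESSELS:
                    sats[vessel] = _truncated_normal(
                        rng, config.sat_means[group][state][vessel],
                        config.sat_sds[group][state][vessel], lo=0.0, hi=1.0)
                hb = _truncated_normal(rng, config.hb_mean[group][state],
                                       config.hb_sd[group][state], lo=1.0)
                hr = _truncated_normal(rng, config.hr_mean[group][state],
                                       config.hr_sd[group][state], lo=30.0)
                subject.states[state] = CirculationState(
                    subject_id=sid, group=group, state=state, flows=flows,
                    saturations=sats, hb_g_per_l=hb, heart_rate=hr,
                    programmed_fo=flows["AAo"] - flows["LPA"] - flows["RPA"])
            subjects.append(subject)
    return subjects


def make_label_volume(shape: tuple[int, int, int], fetal_voxels: int,
                      brain_voxels: int, voxel_size_mm: tuple[float, float, float],
                      ) -> VolumeSegmentation:
    """Build a label volume with exactly the requested voxel counts.

    ``fetal_voxels`` counts the whole fetal body including the brain
    (brain ⊂ body); labels are laid out contiguously in row-major order,
    which is sufficient for volumetry.
    """
    total = int(np.prod(shape))
    if not 0 <= brain_voxels <= fetal_voxels <= total:
        raise ValidationError(
            "need 0 <= brain_voxels <= fetal_voxels <= grid size")
    flat = np.zeros(total, dtype=np.int16)
    flat[:brain_voxels] = 2
    flat[brain_voxels:fetal_voxels] = 1
    voxel_mm3 = float(np.prod(voxel_size_mm))
    return VolumeSegmentation(label_map=flat.reshape(shape),
                              voxel_size_mm3=voxel_mm3)
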