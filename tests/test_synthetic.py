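"""Phantom and cohort generators: signal models, determinism, design structure."""

import numpy as np
import pytest

from fetalflux.types import (CohortConfig, PhantomSpec, T2PhantomSpec,
                             SAT_VESSELS, STATES, ValidationError)
from fetalflux.synthetic import (analytic_phantom_flow, disk_mask,
                                 make_cohort, make_flow_phantom,
                                 make_label_volume, make_t2_phantom,
                                 wrap_phase)
from fetalflux.biometry import measure_volumes


class TestFlowPhantom:
    def test_zero_flow_gives_zero_phase(self):
        spec = PhantomSpec(vessel_radius_px=8, peak_velocity=0.0,
                           noise_sd_phase=0.0, background_offset=0.0)
        series = make_flow_phantom(spec)
        assert np.all(series.phase == 0.0)

    def test_velocity_at_venc_maps_to_pi_at_centre(self):
        spec = PhantomSpec(vessel_radius_px=8, peak_velocity=150.0, venc=150.0,
                           noise_sd_phase=0.0, background_offset=0.0)
        series = make_flow_phantom(spec)
        centre = series.phase.shape[1] // 2
        assert series.phase[0, centre, centre] == pytest.approx(np.pi)

    def test_parabolic_phantom_matches_poiseuille_flow(self):
        """Discretised parabolic profile integrates to pi r^2 v_peak / 2."""
        from fetalflux.pc_flow import integrate_flow, phase_to_velocity
        spec = PhantomSpec(vessel_radius_px=10, peak_velocity=20.0,
                           pixel_spacing=1.0, noise_sd_phase=0.0)
        series = make_flow_phantom(spec)
        roi = disk_mask(series.phase.shape[1:], spec.vessel_radius_px)
        flow = integrate_flow(phase_to_velocity(series), roi, 1.0, 140.0)
        assert flow.mean_flow == pytest.approx(analytic_phantom_flow(spec),
                                               rel=0.02)

    def test_seed_determinism(self):
        spec = PhantomSpec(vessel_radius_px=8, noise_sd_phase=0.1, seed=42)
        a = make_flow_phantom(spec)
        b = make_flow_phantom(spec)
        assert np.array_equal(a.phase, b.phase)
        assert np.array_equal(a.magnitude, b.magnitude)

    def test_aliasing_guard(self):
        with pytest.raises(Exception):
            PhantomSpec(vessel_radius_px=8, peak_velocity=200.0, venc=150.0)
        PhantomSpec(vessel_radius_px=8, peak_velocity=200.0, venc=150.0,
                    allow_aliasing=True)   # explicitly permitted

    def test_wrap_phase_range(self):
        x = np.linspace(-10, 10, 1001)
        w = wrap_phase(x)
        assert np.all(w > -np.pi) and np.all(w <= np.pi)
        assert wrap_phase(np.pi) == pytest.approx(np.pi)


class TestT2Phantom:
    def test_exponential_decay_value(self):
        spec = T2PhantomSpec(t2_ms=120.0, s0=200.0, noise_sd=0.0)
        series = make_t2_phantom(spec)
        centre = series.images.shape[1] // 2
        idx = list(spec.prep_times_ms).index(96.0)
        assert series.images[idx, centre, centre] == pytest.approx(
            200.0 * np.exp(-0.8), abs=1e-9)   # 89.866

    def test_no_decay_limit(self):
        spec = T2PhantomSpec(t2_ms=1e12, s0=150.0, noise_sd=0.0)
        series = make_t2_phantom(spec)
        centre = series.images.shape[1] // 2
        assert series.images[0, centre, centre] == pytest.approx(150.0)

    def test_seed_determinism(self):
        spec = T2PhantomSpec(t2_ms=120.0, s0=200.0, noise_sd=5.0, seed=7)
        assert np.array_equal(make_t2_phantom(spec).images,
                              make_t2_phantom(spec).images)

    def test_prep_times_must_increase(self):
        with pytest.raises(Exception):
            T2PhantomSpec(t2_ms=100.0, s0=1.0, prep_times_ms=[64, 32])


class TestCohort:
    def test_degenerate_sds_reproduce_means_exactly(self):
        cfg = CohortConfig(n_control=3, n_fgr=2, seed=0)
        for g in ("control", "FGR"):
            for s in STATES:
                cfg.flow_sds[g][s] = {v: 0.0 for v in cfg.flow_sds[g][s]}
                cfg.sat_sds[g][s] = {v: 0.0 for v in cfg.sat_sds[g][s]}
        subjects = make_cohort(cfg)
        for subj in subjects:
            for s in STATES:
                st = subj.states[s]
                for v, q in cfg.flow_means[subj.group][s].items():
                    assert st.flows[v] == pytest.approx(q)
                for v, y in cfg.sat_means[subj.group][s].items():
                    assert st.saturations[v] == pytest.approx(y)

    def test_repeated_measures_structure(self, default_cohort):
        assert len(default_cohort) == 21
        groups = [s.group for s in default_cohort]
        assert groups.count("control") == 12 and groups.count("FGR") == 9
        for subj in default_cohort:
            assert set(subj.states) == set(STATES)
            for s in STATES:
                assert subj.states[s].subject_id == subj.subject_id
                assert set(SAT_VESSELS) <= set(subj.states[s].saturations)

    def test_cohort_seed_determinism(self):
        cfg = CohortConfig(seed=5)
        a, b = make_cohort(cfg), make_cohort(cfg)
        for sa, sb in zip(a, b):
            assert sa.weight_g == sb.weight_g
            for s in STATES:
                assert sa.states[s].flows == sb.states[s].flows
                assert sa.states[s].saturations == sb.states[s].saturations

    def test_sample_mean_near_configured_aao_saturation(self, default_cohort):
        """Control-normoxia arterial saturation draws centre on 0.585."""
        vals = [s.states["normoxia"].saturations["AAo"]
                for s in default_cohort if s.group == "control"]
        se = 0.07 / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.585) < 3 * se

    def test_distributional_fidelity_large_sample(self):
        cfg = CohortConfig(n_control=1000, n_fgr=1, seed=11)
        subjects = [s for s in make_cohort(cfg) if s.group == "control"]
        uv = [s.states["normoxia"].flows["UV"] for s in subjects]
        se = 45.0 / np.sqrt(len(uv))
        assert abs(np.mean(uv) - 350.0) < 3 * se

    def test_truncation_respects_physical_ranges(self):
        cfg = CohortConfig(seed=3)
        for subj in make_cohort(cfg):
            for s in STATES:
                st = subj.states[s]
                assert all(q >= 0 for q in st.flows.values())
                assert all(0 <= y <= 1 for y in st.saturations.values())

    def test_pbf_effect_off_gives_nominal_type1_rate(self):
        """With the FGR-PBF effect disabled, group t-tests on PBF reject ~5%."""
        from fetalflux.stats import unpaired_t_test
        base = CohortConfig(seed=0, fgr_lowers_pbf_normoxia_only=False)
        rejections = 0
        n_rep = 1000
        for rep in range(n_rep):
            cohort = make_cohort(base.model_copy(update={"seed": rep}))
            pbf = {"control": [], "FGR": []}
            for subj in cohort:
                st = subj.states["normoxia"]
                pbf[subj.group].append(st.flows["LPA"] + st.flows["RPA"])
            _, _, p = unpaired_t_test(pbf["control"], pbf["FGR"])
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_nonpositive_n_rejected(self):
        with pytest.raises(Exception):
            CohortConfig(n_control=0)


class TestLabelVolume:
    def test_voxel_arithmetic(self):
        seg = make_label_volume((10, 10, 10), 1000, 0, (1.0, 1.0, 1.0))
        fetal_ml, brain_ml = measure_volumes(seg)
        assert fetal_ml == pytest.approx(1.0)
        assert brain_ml == 0.0

    def test_anisotropic_voxels(self):
        seg = make_label_volume((70, 70, 70), 276_923, 0, (1.5, 1.5, 2.0))
        fetal_ml, _ = measure_volumes(seg)
        assert fetal_ml == pytest.approx(1246.2, abs=0.05)

    def test_requested_counts_recovered(self):
        seg = make_label_volume((20, 20, 20), 500, 120, (1.0, 1.0, 1.0))
        assert int(np.count_nonzero(seg.label_map == 2)) == 120
        assert int(np.count_nonzero(seg.label_map >= 1)) == 500

    def test_counts_exceeding_grid_rejected(self):
        with pytest.raises(ValidationError):
            make_label_volume((5, 5, 5), 200, 0, (1.0, 1.0, 1.0))
        with pytest.raises(ValidationError):
            make_label_volume((5, 5, 5), 100, 120, (1.0, 1.0, 1.0))
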