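"""Closed-loop simulator: structure, control, conservation, determinism."""

import numpy as np
import pytest

from circwave.metrics import MMHG, Waveform
from circwave.pipeline import analyze_result
from circwave.simulator import (LMIN, ML, REC_CHANNELS, Model, ScenarioConfig,
                                build_model, homeostatic_update,
                                simulate_scenario, valve_flow)


class TestBuildModel:
    def test_structural_counts(self):
        m = build_model(ScenarioConfig())
        assert len(m.chambers) == 4
        assert len(m.tree.segments) >= 10
        assert m.qv.size == 4  # four valves

    def test_delta_k_applied_to_every_segment(self):
        base = build_model(ScenarioConfig())
        stiff = build_model(ScenarioConfig(delta_k=12.0))
        np.testing.assert_allclose(stiff.ck, base.ck + 12.0)

    def test_p0_override_rebases_arterial_reference_pressures(self):
        m = build_model(ScenarioConfig(p0_art_mmhg=102.0))
        for name, seg in m.tree.segments.items():
            if "vein" not in name and "cava" not in name:
                assert seg.p0 == pytest.approx(102.0 * MMHG)
        # and the homeostatic pressure target follows the operating point
        assert m.config.map_target == pytest.approx(102.0 * MMHG)

    def test_invalid_delta_k_rejected(self):
        with pytest.raises(ValueError):
            build_model(ScenarioConfig(delta_k=-10.0))


class TestValve:
    def test_closed_valve_blocks_reverse_flow(self):
        q = 0.0
        for _ in range(2000):
            q = valve_flow(-6000.0, open_fraction=0.0, q_prev=q)
        assert abs(q) < 1e-7  # below the leak tolerance

    def test_forward_flow_with_positive_gradient(self):
        q = 0.0
        for _ in range(5000):
            q = valve_flow(2000.0, open_fraction=1.0, q_prev=q)
        # equilibrium of the Bernoulli orifice: q = A sqrt(2 dp / rho)
        expected = 5e-4 * np.sqrt(2 * 2000.0 / 1050.0)
        assert q == pytest.approx(expected, rel=0.01)
        assert q > 0

    def test_aortic_flow_integrates_to_stroke_volume(self, ref_run):
        wf = ref_run.waveforms
        sv_flow = np.trapezoid(wf.q_av_m3_s.values, dx=ref_run.dt) / ML
        sv_vol = wf.v_lv_ml.max() - wf.v_lv_ml.min()
        assert sv_flow == pytest.approx(sv_vol, rel=0.03)

    def test_no_diastolic_aortic_flow(self, ref_run):
        wf = ref_run.waveforms
        q = wf.q_av_m3_s.values
        late = q[int(0.6 * q.size):]  # well after ejection
        assert np.max(np.abs(late)) < 0.005 * np.max(q)


class TestHomeostasis:
    def test_fixed_point_leaves_model_unchanged(self):
        m = build_model(ScenarioConfig())
        homeostatic_update(m, m.config.map_target, m.config.co_target)
        assert m.resistance_scale == pytest.approx(1.0)
        assert m.q_inj == pytest.approx(0.0)

    def test_high_map_reduces_resistance(self):
        m = build_model(ScenarioConfig())
        homeostatic_update(m, 1.10 * m.config.map_target, m.config.co_target)
        assert m.resistance_scale < 1.0

    def test_reference_targets_reached(self, ref_run):
        cfg = ref_run.config
        assert ref_run.converged
        assert ref_run.achieved_map_mmhg == pytest.approx(
            cfg.map_target_mmhg, rel=0.01)
        assert ref_run.achieved_co_lmin == pytest.approx(
            cfg.co_target_lmin, rel=0.01)


class TestConservationAndStationarity:
    def test_blood_volume_conserved_over_analysis_beat(self, ref_run):
        v = ref_run.waveforms.v_total_ml.values
        drift = abs(v[-1] - v[0]) / v[0]
        assert drift <= 1e-3

    def test_steady_state_is_stationary(self, ref_run):
        model = ref_run.model
        p_prev = ref_run.waveforms.p_ao_mmHg.values
        maps = []
        for _ in range(5):
            rec = model.run_beat()
            maps.append(np.mean(rec[REC_CHANNELS.index("p_ao")]) / MMHG)
            p_now = rec[REC_CHANNELS.index("p_ao")] / MMHG
        # five extra beats move beat-averaged MAP by < 0.1 %
        assert abs(maps[-1] - ref_run.achieved_map_mmhg) \
            < 1e-3 * ref_run.achieved_map_mmhg
        # and the trace stays periodic to < 0.5 % of pulse pressure
        rms = np.sqrt(np.mean((p_now - p_prev) ** 2))
        assert rms < 0.005 * np.ptp(p_prev)


class TestDeterminism:
    def test_beats_are_bit_identical_across_rebuilds(self):
        cfg = ScenarioConfig()
        recs = []
        for _ in range(2):
            m = build_model(cfg)
            r = [m.run_beat() for _ in range(3)]
            recs.append(np.concatenate([x.ravel() for x in r]))
        assert np.array_equal(recs[0], recs[1])


class TestCardiacCouplingEffects:
    def test_zero_activation_gives_zero_stroke_work(self):
        m = build_model(ScenarioConfig())
        m.hcmax[:] = 0.0  # silence every wall
        for _ in range(5):
            rec = m.run_beat()
        p_lv = rec[REC_CHANNELS.index("p_lv")] / MMHG
        v_lv = rec[REC_CHANNELS.index("v_lv")] / ML
        w = 0.5 * abs(np.dot(v_lv * ML, np.roll(p_lv * MMHG, -1))
                      - np.dot(np.roll(v_lv * ML, -1), p_lv * MMHG))
        assert w < 0.01  # J; no active work without activation

    def test_reduced_shortening_velocity_reduces_pssr_magnitude(
            self, scenario_reports):
        ref = scenario_reports["ref"].pssr
        slow = scenario_reports["vslow"].pssr
        assert ref < 0 and slow < 0
        assert abs(slow) < 0.85 * abs(ref)  # >= 15 % magnitude reduction


class TestScenarioOrdering:
    def test_aix_ordering(self, scenario_reports):
        aix = {k: v.aix for k, v in scenario_reports.items()}
        assert aix["combined"] > aix["stiff"] > aix["ref"]
        assert aix["combined"] > aix["vslow"] > aix["ref"]
        assert abs(aix["stiff"] - aix["vslow"]) < 10.0  # approximately equal

    def test_ejection_duration_ordering(self, scenario_reports):
        t = {k: v.t_ej for k, v in scenario_reports.items()}
        assert t["ref"] < t["vslow"] < t["combined"]

    def test_backward_amplitude_increases_with_stiffening(self, scenario_reports):
        assert scenario_reports["stiff"].p_bw_amp \
            > scenario_reports["ref"].p_bw_amp

    def test_reference_has_largest_pssr_magnitude(self, scenario_reports):
        mags = {k: abs(v.pssr) for k, v in scenario_reports.items()}
        assert mags["ref"] == max(mags.values())
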