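"""Landmark detection and scalar pulse-wave indices on analytic waveforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circwave.metrics import (MMHG, FlatSignalError, Landmarks,
                              UndefinedIndexError, Waveform,
                              augmentation_index, augmentation_index_prime,
                              detect_foot, detect_inflection,
                              ejection_duration, peak_systolic_strain_rate,
                              pwv_foot_to_foot, stroke_work)
from circwave.synthetic import (SyntheticSpec, make_delayed_pair,
                                make_inflected_pressure, make_pv_loop)


@pytest.fixture
def inflected():
    spec = SyntheticSpec()
    p, truth = make_inflected_pressure(spec)
    return spec, p, truth


class TestFoot:
    def test_analytic_foot_position(self, inflected):
        spec, p, truth = inflected
        t_foot = detect_foot(p)
        assert abs(t_foot - truth["t_foot"]) <= 2 * spec.dt + 1e-12

    def test_translation_equivariance(self, inflected):
        spec, p, truth = inflected
        shift = 40  # samples
        p2 = Waveform(np.roll(p.values, shift), p.dt, p.unit, p.kind)
        assert detect_foot(p2) == pytest.approx(detect_foot(p) + shift * p.dt,
                                                abs=0.05 * p.dt)

    def test_amplitude_scale_invariance(self, inflected):
        _, p, _ = inflected
        p2 = Waveform(5.0 * p.values - 100.0, p.dt, p.unit, p.kind)
        assert detect_foot(p2) == pytest.approx(detect_foot(p), abs=1e-12)

    def test_flat_signal_raises(self):
        flat = Waveform(np.full(500, 80.0), 1e-3, "mmHg", "pressure")
        with pytest.raises(FlatSignalError):
            detect_foot(flat)


class TestInflection:
    def test_constructed_inflection_time(self, inflected):
        # a 50 Hz detector cutoff keeps the smoothing bias of the shallow
        # second-derivative crossing below the 2-sample tolerance
        spec, p, truth = inflected
        t_foot = detect_foot(p, cutoff_hz=50.0)
        t_i = detect_inflection(p, t_foot, t_end=truth["t_end_sys"],
                                cutoff_hz=50.0)
        assert t_i is not None
        assert abs(t_i - truth["t_i"]) <= 2 * spec.dt

    def test_monotone_upstroke_has_no_inflection(self):
        spec = SyntheticSpec()
        p, truth = make_inflected_pressure(spec, with_inflection=False)
        t_foot = detect_foot(p)
        assert detect_inflection(p, t_foot, t_end=truth["t_end_sys"]) is None

    def test_detected_aix_matches_construction(self, inflected):
        spec, p, truth = inflected
        t_foot = detect_foot(p)
        t_i = detect_inflection(p, t_foot, t_end=truth["t_end_sys"])
        p_i = float(np.interp(t_i, p.t, p.values))
        lm = Landmarks(t_foot=t_foot, t_sys_peak=float(np.argmax(p.values)) * p.dt,
                       p_dia=float(p.values.min()), p_sys=float(p.values.max()),
                       t_inflection=t_i, p_i=p_i)
        assert augmentation_index(lm) == pytest.approx(truth["aix"], abs=1.0)
        assert augmentation_index_prime(lm) == pytest.approx(truth["aix_prime"],
                                                             abs=2.0)


class TestAugmentationIndex:
    def test_direct_formula(self):
        lm = Landmarks(t_foot=0.05, t_sys_peak=0.2, p_dia=60.0, p_sys=127.0,
                       t_inflection=0.15, p_i=111.5)
        assert augmentation_index(lm) == pytest.approx(100 * 15.5 / 67.0)

    @pytest.mark.parametrize("p_i,expected", [(60.0, 100.0), (127.0, 0.0)])
    def test_boundaries(self, p_i, expected):
        lm = Landmarks(t_foot=0.05, t_sys_peak=0.2, p_dia=60.0, p_sys=127.0,
                       t_inflection=0.15, p_i=p_i)
        assert augmentation_index(lm) == pytest.approx(expected)

    def test_prime_identity_with_aix(self):
        # AIx' = 100*AIx/(100-AIx) whenever both are defined
        lm = Landmarks(t_foot=0.05, t_sys_peak=0.25, p_dia=60.0, p_sys=127.0,
                       t_inflection=0.15, p_i=112.9)
        aix = augmentation_index(lm)
        assert augmentation_index_prime(lm) == pytest.approx(
            100.0 * aix / (100.0 - aix), abs=1e-9)

    def test_missing_inflection_is_undefined_not_zero(self):
        lm = Landmarks(t_foot=0.05, t_sys_peak=0.2, p_dia=60.0, p_sys=127.0)
        with pytest.raises(UndefinedIndexError):
            augmentation_index(lm)
        with pytest.raises(UndefinedIndexError):
            augmentation_index_prime(lm)


class TestEjectionDuration:
    @staticmethod
    def _trapezoid(dt=1e-3, period=0.8, on=0.100, off=0.338, ramp=0.03):
        t = np.arange(int(period / dt)) * dt
        up = np.clip((t - on) / ramp, 0, 1)
        down = np.clip((off - t) / ramp, 0, 1)
        return Waveform(0.9 * np.minimum(up, down), dt, "m/s", "flow-velocity")

    def test_trapezoid_duration(self):
        q = self._trapezoid()
        t_ej, t_on, t_off = ejection_duration(q)
        assert t_ej == pytest.approx(0.238, abs=0.010)

    def test_amplitude_invariance(self):
        q = self._trapezoid()
        q2 = Waveform(2.0 * q.values, q.dt, q.unit, q.kind)
        assert ejection_duration(q2)[0] == ejection_duration(q)[0]

    def test_flat_flow_raises(self):
        q = Waveform(np.zeros(800), 1e-3, "m/s", "flow-velocity")
        with pytest.raises(FlatSignalError):
            ejection_duration(q)


class TestPWV:
    def test_constructed_delay(self):
        spec = SyntheticSpec(delay=0.020)
        p1, p2, truth = make_delayed_pair(spec)
        assert pwv_foot_to_foot(p1, p2, 0.13) == pytest.approx(6.5, rel=0.02)

    def test_proportional_in_path(self):
        spec = SyntheticSpec(delay=0.020)
        p1, p2, _ = make_delayed_pair(spec)
        assert pwv_foot_to_foot(p1, p2, 0.26) == pytest.approx(
            2 * pwv_foot_to_foot(p1, p2, 0.13))

    def test_halved_delay_doubles_pwv(self):
        a = make_delayed_pair(SyntheticSpec(delay=0.020))
        b = make_delayed_pair(SyntheticSpec(delay=0.010))
        pwv_a = pwv_foot_to_foot(a[0], a[1], 0.13)
        pwv_b = pwv_foot_to_foot(b[0], b[1], 0.13)
        assert pwv_b == pytest.approx(2 * pwv_a, rel=0.05)

    def test_noise_robustness(self):
        spec = SyntheticSpec(delay=0.020, noise_sd=0.67, seed=7)  # ~1% of pulse
        p1, p2, _ = make_delayed_pair(spec)
        assert pwv_foot_to_foot(p1, p2, 0.13) == pytest.approx(6.5, rel=0.05)

    def test_misaligned_beats_raise(self):
        spec = SyntheticSpec(delay=0.020)
        p1, p2, _ = make_delayed_pair(spec)
        with pytest.raises(ValueError):
            pwv_foot_to_foot(p2, p1, 0.13)


class TestStrokeWork:
    def test_rectangle(self):
        p, v, area = make_pv_loop(SyntheticSpec(pv_shape="rectangle"))
        assert area == pytest.approx(100 * MMHG * 70e-6)
        assert stroke_work(p, v) == pytest.approx(area, rel=1e-6)

    def test_ellipse(self):
        p, v, area = make_pv_loop(SyntheticSpec(pv_shape="ellipse",
                                                dp_loop=40.0, dv_loop=35.0))
        assert area == pytest.approx(np.pi * 40 * MMHG * 35e-6)
        assert stroke_work(p, v) == pytest.approx(area, rel=0.005)

    def test_degenerate_line_is_zero(self):
        p, v, area = make_pv_loop(SyntheticSpec(pv_shape="line"))
        assert area == 0.0
        assert abs(stroke_work(p, v)) < 1e-12

    def test_open_loop_raises(self):
        p, v, _ = make_pv_loop(SyntheticSpec(pv_shape="rectangle"))
        v_open = Waveform(v.values + np.linspace(0, 30, v.values.size),
                          v.dt, "ml", "volume")
        with pytest.raises(ValueError):
            stroke_work(p, v_open)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.floats(40, 200), st.floats(0, 150)),
                    min_size=4, max_size=12, unique=True))
    def test_matches_shoelace_oracle_on_polygons(self, pts):
        # independent oracle: textbook shoelace sum over polygon vertices
        v = np.array([x for x, _ in pts])
        p = np.array([y for _, y in pts])
        oracle = 0.5 * sum(
            v[i] * 1e-6 * p[(i + 1) % len(pts)] * MMHG
            - v[(i + 1) % len(pts)] * 1e-6 * p[i] * MMHG
            for i in range(len(pts)))
        got = stroke_work(Waveform(p, 1e-3, "mmHg", "pressure"),
                          Waveform(v, 1e-3, "ml", "volume"),
                          closure_rtol=np.inf)
        assert got == pytest.approx(oracle, abs=1e-10 * max(1.0, abs(oracle)))


class TestPSSR:
    def test_linear_ramp(self):
        dt = 1e-3
        strain = -0.9 * np.arange(300) * dt
        w = Waveform(strain, dt, "", "strain")
        assert peak_systolic_strain_rate(w) == pytest.approx(-0.9, rel=1e-3)

    def test_constant_strain_is_zero(self):
        w = Waveform(np.full(300, 0.1), 1e-3, "", "strain")
        assert peak_systolic_strain_rate(w) == pytest.approx(0.0, abs=1e-12)
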