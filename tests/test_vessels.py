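"""Tube constitutive law, wave speed, and 1-D pulse propagation."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from circwave.metrics import MMHG, Waveform, detect_foot
from circwave.separation import RHO_BLOOD
from circwave.vessels import (InvalidAreaError, NoSolutionError,
                              PeripheralBed, VesselSegment, area_from_pressure,
                              bed_flow, dp_dA, reference_tree,
                              simulate_uniform_tube, transmural_pressure,
                              wave_speed)


def make_seg(k=8.0, b=0.02, A0=3e-4, p0=92 * MMHG, length=1.5):
    return VesselSegment("test", length, A0, p0, k, b)


class TestTubeLaw:
    def test_reference_point_power_law_limit(self):
        seg = make_seg(b=0.0)
        assert transmural_pressure(seg.A0, seg) == pytest.approx(seg.p0)

    def test_pure_power_law_doubling(self):
        seg = make_seg(b=0.0)
        ratio = transmural_pressure(2 * seg.A0, seg) / transmural_pressure(seg.A0, seg)
        assert ratio == pytest.approx(2 ** (1 + seg.k / 3))

    def test_matches_independent_symbolic_evaluation(self):
        # independent route: evaluate the same grouping through sympy
        seg = make_seg(k=8.0, b=0.02)
        A, A0, p0, k, b = sympy.symbols("A A0 p0 k b", positive=True)
        expr = p0 * ((1 + b) * (A / A0) ** (1 + k / 3) - b * (1 + A0 / A))
        for a_frac in (0.6, 1.0, 1.7):
            expected = float(expr.subs({A: a_frac * seg.A0, A0: seg.A0,
                                        p0: seg.p0, k: 8, b: sympy.Rational(1, 50)}))
            assert transmural_pressure(a_frac * seg.A0, seg) == pytest.approx(
                expected, rel=1e-12)

    def test_strictly_increasing_and_collapse_divergence(self):
        seg = make_seg()
        a = np.geomspace(1e-3 * seg.A0, 3 * seg.A0, 200)
        p = transmural_pressure(a, seg)
        assert np.all(np.diff(p) > 0)
        assert p[0] < -10 * seg.p0  # diverges toward -inf as A -> 0

    def test_invalid_area_raises(self):
        with pytest.raises(InvalidAreaError):
            transmural_pressure(-1e-5, make_seg())


class TestInverse:
    def test_round_trip_at_reference(self):
        seg = make_seg()
        p = transmural_pressure(seg.A0, seg)
        assert area_from_pressure(p, seg) == pytest.approx(seg.A0, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.3, 3.0), st.sampled_from([8.0, 14.0, 16.0, 18.0, 20.0]))
    def test_round_trip_randomized(self, a_frac, k):
        seg = make_seg(k=k)
        p = transmural_pressure(a_frac * seg.A0, seg)
        a = area_from_pressure(p, seg)
        assert transmural_pressure(a, seg) == pytest.approx(p, rel=1e-10)

    def test_power_law_inversion(self):
        seg = make_seg(b=0.0)
        p = seg.p0 * 2 ** (1 + seg.k / 3)
        assert area_from_pressure(p, seg) == pytest.approx(2 * seg.A0, rel=1e-9)

    def test_below_image_raises(self):
        with pytest.raises(NoSolutionError):
            area_from_pressure(-1e9, make_seg())


class TestWaveSpeed:
    def test_power_law_closed_form(self):
        # b -> 0, k = 8, p = 92 mmHg: c = sqrt((1 + k/3) p / rho) ~ 6.54 m/s
        seg = make_seg(b=0.0)
        c = wave_speed(seg.A0, seg)
        expected = np.sqrt((1 + 8 / 3) * 92 * MMHG / RHO_BLOOD)
        assert c == pytest.approx(expected, rel=1e-12)
        assert c == pytest.approx(6.54, abs=0.01)

    def test_quadrupling_pressure_doubles_speed(self):
        seg = make_seg(b=0.0)
        a1 = seg.A0
        a2 = area_from_pressure(4 * transmural_pressure(a1, seg), seg)
        assert wave_speed(a2, seg) == pytest.approx(2 * wave_speed(a1, seg),
                                                    rel=1e-9)

    def test_analytic_slope_matches_finite_difference(self):
        seg = make_seg()
        for a in (0.7 * seg.A0, seg.A0, 1.5 * seg.A0):
            h = 1e-7 * seg.A0
            fd = (transmural_pressure(a + h, seg)
                  - transmural_pressure(a - h, seg)) / (2 * h)
            assert dp_dA(a, seg) == pytest.approx(fd, rel=1e-6)


class TestBed:
    def test_zero_flow_at_equal_pressures(self):
        bed = PeripheralBed("b", resistance=1e8)
        assert bed_flow(1000.0, 1000.0, bed) == 0.0

    def test_ohmic_relation(self):
        bed = PeripheralBed("b", resistance=2e8)
        assert bed_flow(3000.0, 1000.0, bed) == pytest.approx(1e-5)

    def test_invalid_resistance(self):
        with pytest.raises(ValueError):
            PeripheralBed("b", resistance=-1.0)


class TestReferenceTree:
    def test_stiffness_taper(self):
        tree = reference_tree()
        k = {n: s.k for n, s in tree.segments.items()}
        assert k["aorta_asc"] == k["vena_cava_asc"] == 8
        assert k["subclavian_art"] == 14
        assert k["carotid_art"] == k["carotid_vein"] == 16
        assert k["brachial_art"] == 18
        assert k["femoral_art"] == 20

    def test_delta_k_applied_everywhere(self):
        base = reference_tree()
        stiff = reference_tree(delta_k=12.0)
        for name in base.segments:
            assert stiff.segments[name].k == base.segments[name].k + 12.0

    def test_every_terminal_artery_paired_with_vein(self):
        tree = reference_tree()
        for bed, (art, vein) in tree.bed_pairs.items():
            assert art in tree.segments and vein in tree.segments
            assert art.endswith("_art") and vein.endswith("_vein")

    def test_path_difference_realistic(self):
        assert 0.4 <= reference_tree().path_difference <= 0.5

    def test_excessive_negative_delta_k_rejected(self):
        with pytest.raises(ValueError):
            reference_tree(delta_k=-8.0)


def _inflow_pulse(t, t0=0.02, width=0.025, amp=4e-6):
    x = (t - t0) / width
    return amp * np.sin(np.pi * x) ** 2 if 0 <= x <= 1 else 0.0


class TestWavePropagation:
    def test_pulse_foot_travels_at_wave_speed(self):
        seg = make_seg(length=2.0)
        p_init = 80 * MMHG
        t, p, x = simulate_uniform_tube(seg, p_init, _inflow_pulse,
                                        duration=0.40, termination="matched")
        c_ref = wave_speed(area_from_pressure(p_init, seg), seg)
        i1, i2 = 20, 160
        f1 = detect_foot(Waveform(p[i1], t[1] - t[0], "Pa", "pressure"))
        f2 = detect_foot(Waveform(p[i2], t[1] - t[0], "Pa", "pressure"))
        c_meas = (x[i2] - x[i1]) / (f2 - f1)
        assert c_meas == pytest.approx(c_ref, rel=0.05)

    def test_closed_end_reflects_with_same_sign(self):
        seg = make_seg(length=1.5)
        p_init = 80 * MMHG
        t, p, x = simulate_uniform_tube(seg, p_init, _inflow_pulse,
                                        duration=0.6, termination="closed")
        mid = p.shape[0] // 2
        trace = p[mid] - p_init
        c = wave_speed(area_from_pressure(p_init, seg), seg)
        # incident peak, then reflected peak after bouncing off the far end
        t_arrive = x[mid] / c
        t_return = (2 * seg.length - x[mid]) / c
        inc = trace[(t > t_arrive - 0.05) & (t < t_arrive + 0.05)].max()
        refl = trace[(t > t_return - 0.05) & (t < t_return + 0.05)].max()
        assert inc > 0 and refl > 0
        assert refl / inc > 0.7  # |reflection coefficient| -> 1, same sign

    def test_matched_termination_absorbs(self):
        seg = make_seg(length=1.5)
        p_init = 80 * MMHG
        t, p, x = simulate_uniform_tube(seg, p_init, _inflow_pulse,
                                        duration=0.6, termination="matched")
        mid = p.shape[0] // 2
        trace = p[mid] - p_init
        c = wave_speed(area_from_pressure(p_init, seg), seg)
        t_return = (2 * seg.length - x[mid]) / c
        inc = np.abs(trace[t < x[mid] / c + 0.06]).max()
        refl = np.abs(trace[(t > t_return - 0.03) & (t < t_return + 0.06)]).max()
        assert refl < 0.02 * inc
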