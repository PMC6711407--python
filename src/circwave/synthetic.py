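"""Synthetic waveform generators with machine-precision ground truth.

Every generator returns both the sampled signals and the exact construction
truth (landmark times, component amplitudes, loop areas), so each analysis
operation can be tested without running the closed-loop simulator.

Pulse primitives are quintic smoothsteps and raised cosines: infinitely
differentiable in the interior where second-derivative landmarks are probed,
with analytically known curvature structure.  The quintic smoothstep
S(x) = 6x^5 - 15x^4 + 10x^3 has its maximal second derivative at the interior
point x = (3 - sqrt(3))/6, which pins the detected "foot" analytically, and
joins flat segments with continuous first and second derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import MMHG, ML, Waveform
from .separation import RHO_BLOOD

#: location of max S'' of the quintic smoothstep on [0, 1]
FOOT_FRACTION = (3.0 - np.sqrt(3.0)) / 6.0


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * x * (10.0 + x * (-15.0 + 6.0 * x))


def _raised_cosine_decay(x: np.ndarray) -> np.ndarray:
    """1 -> 0 with zero slope at both ends, for x in [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * x))


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic beat family (times s, pressures mmHg)."""

    period: float = 0.8                  # beat period (s)
    dt: float = 0.001                    # sampling step
    rho: float = RHO_BLOOD               # blood density kg/m^3
    c: float = 6.5                       # wave speed m/s
    # forward / backward pulse pair
    fw_amp: float = 40.0                 # mmHg
    bw_amp: float = 20.0                 # mmHg
    fw_onset: float = 0.10               # s
    fw_width: float = 0.30               # s, forward lobe duration
    bw_delay: float = 0.12               # s, backward lobe lag behind forward
    offset: float = 80.0                 # mmHg, pressure at t = 0
    # inflected pressure landmarks
    p_dia: float = 60.0
    p_i: float = 111.5
    p_sys: float = 127.0
    t_foot: float = 0.06
    t_i: float = 0.156                   # absolute inflection time
    # PV loop
    pv_shape: str = "rectangle"          # rectangle | ellipse | line
    dp_loop: float = 100.0               # mmHg (rectangle height / 2a ellipse)
    dv_loop: float = 70.0                # ml (rectangle width / 2b ellipse)
    # delayed pair
    delay: float = 0.020                 # s
    noise_sd: float = 0.0                # mmHg, optional additive Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.period / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dt must divide the beat period")

    @property
    def n_samples(self) -> int:
        return int(round(self.period / self.dt))

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


def _half_sine_lobe(t: np.ndarray, onset: float, width: float) -> np.ndarray:
    """sin^2 lobe: zero outside [onset, onset+width], C^1 everywhere."""
    x = (t - onset) / width
    lobe = np.sin(np.pi * np.clip(x, 0.0, 1.0)) ** 2
    return lobe


def make_forward_backward(spec: SyntheticSpec):
    """Pressure and velocity with a known forward/backward decomposition.

    p = offset + p_fw + p_bw and U = (p_fw - p_bw) / (rho c), so that the
    water-hammer relations hold exactly at the specified wave speed.
    Returns ``(p, U, truth)``; truth carries the exact components, amplitudes
    and backward/forward ratio.
    """
    t = spec.t
    p_fw = spec.fw_amp * _half_sine_lobe(t, spec.fw_onset, spec.fw_width)
    p_bw = spec.bw_amp * _half_sine_lobe(
        t, spec.fw_onset + spec.bw_delay, spec.fw_width)
    p = spec.offset + p_fw + p_bw
    u = (p_fw - p_bw) * MMHG / (spec.rho * spec.c)
    truth = {
        "p_fw": p_fw,
        "p_bw": p_bw,
        "p_fw_amp": float(np.ptp(p_fw)),
        "p_bw_amp": float(np.ptp(p_bw)),
        "ratio": 100.0 * spec.bw_amp / spec.fw_amp,
        "c": spec.c,
        "offset": spec.offset,
    }
    return (Waveform(p, spec.dt, unit="mmHg", kind="pressure"),
            Waveform(u, spec.dt, unit="m/s", kind="flow-velocity"),
            truth)


def make_inflected_pressure(spec: SyntheticSpec, with_inflection: bool = True):
    """Pressure beat with analytically placed foot and inflection point.

    The incident upstroke is a quintic smoothstep from p_dia to p_i whose
    second derivative peaks at the foot time; when ``with_inflection`` the
    reflected rise (a second smoothstep from p_i to p_sys) starts exactly
    where the incident step ends, so the second derivative crosses zero
    upward exactly at t_i.  Without the reflected component the waveform
    rises to its peak and decays with no re-acceleration in systole.
    Returns ``(p, truth)``; truth carries exact AIx and AIx'.
    """
    if not (spec.p_dia < spec.p_i < spec.p_sys):
        raise ValueError("landmark pressures must satisfy p_dia < p_i < p_sys")
    if not (spec.t_foot < spec.t_i):
        raise ValueError("t_foot must precede t_i")
    t = spec.t
    w1 = (spec.t_i - spec.t_foot) / (1.0 - FOOT_FRACTION)
    t_a = spec.t_foot - FOOT_FRACTION * w1
    if t_a < 0:
        raise ValueError("foot too early for the requested rise time")
    if with_inflection:
        w2 = 0.9 * w1
        t_peak = spec.t_i + w2
        p = spec.p_dia \
            + (spec.p_i - spec.p_dia) * _smoothstep((t - t_a) / w1) \
            + (spec.p_sys - spec.p_i) * _smoothstep((t - spec.t_i) / w2)
        p_sys = spec.p_sys
    else:
        t_peak = t_a + w1
        p = spec.p_dia + (spec.p_sys - spec.p_dia) * _smoothstep((t - t_a) / w1)
        p_sys = spec.p_sys
    # diastolic decay back to p_dia, C^1 at the peak
    w3 = spec.period - t_peak - 2.0 * spec.dt
    decay = (t > t_peak)
    p = np.where(decay,
                 spec.p_dia + (p_sys - spec.p_dia)
                 * _raised_cosine_decay((t - t_peak) / max(w3, spec.dt)),
                 p)
    aix = 100.0 * (spec.p_sys - spec.p_i) / (spec.p_sys - spec.p_dia)
    aix_prime = 100.0 * (spec.p_sys - spec.p_i) / (spec.p_i - spec.p_dia)
    truth = {
        "t_foot": spec.t_foot,
        "t_i": spec.t_i if with_inflection else None,
        "p_dia": spec.p_dia,
        "p_i": spec.p_i if with_inflection else None,
        "p_sys": p_sys,
        "t_end_sys": t_peak + 0.02,
        "aix": aix if with_inflection else None,
        "aix_prime": aix_prime if with_inflection else None,
    }
    return Waveform(p, spec.dt, unit="mmHg", kind="pressure"), truth


def make_pv_loop(spec: SyntheticSpec):
    """Closed LV pressure-volume loop with analytically exact area in joules.

    Rectangle and ellipse loops are traversed counterclockwise in the (V, p)
    plane (fill at low pressure, eject at high pressure); ``line`` is the
    degenerate zero-area loop.  Returns ``(p_lv, v_lv, exact_area_J)``.
    """
    n = spec.n_samples
    p0, v0 = 10.0, 60.0  # base corner, mmHg / ml
    if spec.pv_shape == "rectangle":
        # equal number of samples per edge, corners included once
        m = n // 4
        s = np.linspace(0.0, 1.0, m, endpoint=False)
        v = np.concatenate([v0 + spec.dv_loop * s,
                            np.full(m, v0 + spec.dv_loop),
                            v0 + spec.dv_loop * (1.0 - s),
                            np.full(n - 3 * m, v0)])
        p = np.concatenate([np.full(m, p0),
                            p0 + spec.dp_loop * s,
                            np.full(m, p0 + spec.dp_loop),
                            p0 + spec.dp_loop * (1.0 - np.linspace(0.0, 1.0, n - 3 * m, endpoint=False))])
        area = spec.dp_loop * MMHG * spec.dv_loop * ML
    elif spec.pv_shape == "ellipse":
        a = spec.dp_loop  # pressure semi-axis, mmHg
        b = spec.dv_loop  # volume semi-axis, ml
        th = 2.0 * np.pi * np.arange(n) / n
        v = v0 + b + b * np.cos(th)    # rightmost point first, then up: CCW
        p = p0 + a + a * np.sin(th)
        area = np.pi * a * MMHG * b * ML
    elif spec.pv_shape == "line":
        s = np.concatenate([np.linspace(0, 1, n // 2, endpoint=False),
                            np.linspace(1, 0, n - n // 2, endpoint=False)])
        v = v0 + spec.dv_loop * s
        p = p0 + spec.dp_loop * s
        area = 0.0
    else:
        raise ValueError(f"unknown pv_shape {spec.pv_shape!r}")
    return (Waveform(p, spec.dt, unit="mmHg", kind="pressure"),
            Waveform(v, spec.dt, unit="ml", kind="volume"),
            float(area))


def make_delayed_pair(spec: SyntheticSpec):
    """Two identical pressure beats with an exact relative time shift.

    Site 2 lags site 1 by ``spec.delay`` seconds (the delay must be an
    integer number of samples so the shift is exact).  Optional seeded
    Gaussian noise is added to both sites.  Returns
    ``(p_site1, p_site2, truth)`` with the exact transit time.
    """
    if spec.delay <= 0:
        raise ValueError("delay must be positive")
    shift = spec.delay / spec.dt
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError("delay must be an integer number of samples")
    shift = int(round(shift))
    t = spec.t
    w1 = 0.12
    t_a = 0.05
    t_peak = t_a + w1
    w3 = 0.45
    base = spec.p_dia + (spec.p_sys - spec.p_dia) * _smoothstep((t - t_a) / w1)
    base = np.where(t > t_peak,
                    spec.p_dia + (spec.p_sys - spec.p_dia)
                    * _raised_cosine_decay((t - t_peak) / w3),
                    base)
    p1 = base.copy()
    p2 = np.roll(base, shift)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        p1 = p1 + rng.normal(0.0, spec.noise_sd, size=p1.size)
        p2 = p2 + rng.normal(0.0, spec.noise_sd, size=p2.size)
    truth = {"delay": spec.delay}
    return (Waveform(p1, spec.dt, unit="mmHg", kind="pressure"),
            Waveform(p2, spec.dt, unit="mmHg", kind="pressure"),
            truth)
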