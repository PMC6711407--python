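"""Pulse-wave analysis: landmark detection and scalar indices.

Operates on uniformly sampled pressure / flow / volume / strain traces of a
single steady-state beat and extracts the indices used in clinical pulse-wave
analysis:

* augmentation index AIx = 100 * (p_sys - p_i) / (p_sys - p_dia), where p_i is
  the pressure at the inflection point marking reflected-wave arrival,
* AIx' = 100 * (p_sys - p_i) / (p_i - p_dia)  (augmentation over incident
  pressure),
* time-to-inflection t_i (foot to inflection point),
* LV ejection duration t_ej from aortic-valve flow velocity,
* carotid-femoral foot-to-foot pulse wave velocity,
* LV stroke work (closed pressure-volume loop area),
* peak systolic strain rate (PSSR).

Landmarks follow the second-derivative conventions: the waveform foot is the
maximum of the second time-derivative and the inflection point is the first
re-acceleration zero-crossing (negative-to-positive) of the second derivative
after the foot's acceleration lobe.  Derivatives are taken by central
differences after zero-phase low-pass smoothing (Butterworth, default 25 Hz),
so that landmark positions are stable under refinement of the sampling step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

MMHG = 133.322  # Pa per mmHg
ML = 1e-6       # m^3 per ml

#: default cutoff for zero-phase smoothing before differentiation (Hz)
DEFAULT_SMOOTH_HZ = 25.0


class FlatSignalError(ValueError):
    """Raised when a landmark is requested on a degenerate (flat) trace."""


class UndefinedIndexError(ValueError):
    """Raised when an index is requested but its landmark is absent.

    Absence of an inflection point is a valid analysis outcome; this error is
    the signal that AIx/AIx' are undefined for the beat and must be propagated
    as a missing value, never as zero.
    """


@dataclass
class Waveform:
    """One uniformly sampled signal with an explicit unit tag."""

    values: np.ndarray
    dt: float
    unit: str = ""
    kind: str = ""  # pressure | flow-velocity | flow | volume | strain

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 4:
            raise ValueError("waveform must be a 1-D array with >= 4 samples")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


@dataclass
class Landmarks:
    """Pressure-waveform landmarks of one beat (times in s, pressures in mmHg)."""

    t_foot: float
    t_sys_peak: float
    p_dia: float
    p_sys: float
    t_inflection: Optional[float] = None
    p_i: Optional[float] = None


@dataclass
class ReflectionReport:
    """All derived indices of one simulation / one analyzed beat."""

    p_sys: float = np.nan      # mmHg
    p_dia: float = np.nan      # mmHg
    p_pulse: float = np.nan    # mmHg
    p_mean: float = np.nan     # mmHg, time average over the beat
    aix: float = np.nan        # %
    aix_prime: float = np.nan  # %
    t_i: float = np.nan        # ms
    t_ej: float = np.nan       # ms
    pwv: float = np.nan        # m/s
    p_fw_amp: float = np.nan   # mmHg
    p_bw_amp: float = np.nan   # mmHg
    ratio_bw_fw: float = np.nan  # %
    w_stroke: float = np.nan   # J
    pssr: float = np.nan       # 1/s
    c_est: float = np.nan      # m/s (PU-loop estimate)
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# smoothing and derivatives
# ---------------------------------------------------------------------------

def smooth(values: np.ndarray, dt: float, cutoff_hz: float = DEFAULT_SMOOTH_HZ) -> np.ndarray:
    """Zero-phase low-pass (2nd-order Butterworth applied forward-backward)."""
    values = np.asarray(values, dtype=float)
    nyq = 0.5 / dt
    if cutoff_hz <= 0 or cutoff_hz >= 0.95 * nyq:
        return values.copy()
    b, a = signal.butter(2, cutoff_hz / nyq)
    padlen = min(3 * max(len(a), len(b)), values.size - 1)
    return signal.filtfilt(b, a, values, padlen=padlen)


def second_derivative(values: np.ndarray, dt: float,
                      cutoff_hz: float = DEFAULT_SMOOTH_HZ) -> np.ndarray:
    """Second time-derivative by repeated central differences after smoothing."""
    s = smooth(values, dt, cutoff_hz)
    return np.gradient(np.gradient(s, dt), dt)


def _window_to_indices(n: int, dt: float, window) -> tuple[int, int]:
    if window is None:
        return 0, n
    i0 = int(round(window[0] / dt))
    i1 = int(round(window[1] / dt)) + 1
    return max(i0, 0), min(i1, n)


# ---------------------------------------------------------------------------
# landmark detection
# ---------------------------------------------------------------------------

def detect_foot(p: Waveform, beat_window=None,
                cutoff_hz: float = DEFAULT_SMOOTH_HZ,
                refine_halfwidth: int = 8) -> float:
    """Foot of the pressure wave: maximum of the second derivative.

    ``beat_window`` is an optional (t0, t1) span in seconds restricting the
    search (late diastole through early systole); by default the whole trace
    is searched, where the steep systolic upstroke dominates the curvature.
    """
    v = p.values
    if np.ptp(v) <= 1e-12 * (abs(np.mean(v)) + 1.0):
        raise FlatSignalError("cannot detect a foot on a flat waveform")
    d2 = second_derivative(v, p.dt, cutoff_hz)
    i0, i1 = _window_to_indices(v.size, p.dt, beat_window)
    if cutoff_hz > DEFAULT_SMOOTH_HZ:
        # two-stage search: localize coarsely at the heavily smoothed
        # (noise-robust) bandwidth, then sharpen within +-1 smoothing period
        d2_coarse = second_derivative(v, p.dt, DEFAULT_SMOOTH_HZ)
        ic = i0 + int(np.argmax(d2_coarse[i0:i1]))
        halo = int(round(1.0 / DEFAULT_SMOOTH_HZ / p.dt))
        i0 = max(i0, ic - halo)
        i1 = min(i1, ic + halo + 1)
    i = i0 + int(np.argmax(d2[i0:i1]))
    # sub-sample refinement: least-squares parabola through the peak
    k = refine_halfwidth
    lo, hi = max(i - k, 0), min(i + k + 1, v.size)
    xs = np.arange(lo, hi, dtype=float)
    if xs.size >= 5:
        coef = np.polyfit(xs - i, d2[lo:hi], 2)
        if coef[0] < 0:
            vertex = -coef[1] / (2.0 * coef[0])
            if abs(vertex) <= k:
                return (i + vertex) * p.dt
    return i * p.dt


def detect_inflection(p: Waveform, t_foot: float, t_end: Optional[float] = None,
                      cutoff_hz: float = DEFAULT_SMOOTH_HZ) -> Optional[float]:
    """Systolic inflection point, or ``None`` when absent.

    The foot is a maximum of d2p/dt2; along the upstroke the second derivative
    then falls through zero as the initial rise decelerates.  Arrival of the
    reflected compression wave re-accelerates the pressure rise, producing an
    upward (negative-to-positive) zero-crossing of the second derivative: the
    inflection point.  The first such crossing after the foot and before
    ``t_end`` (end of systole) is returned.  Waveforms whose rise simply
    decays without re-acceleration have no such crossing within systole, and
    ``None`` is returned (a valid outcome, not an error).
    """
    d2 = second_derivative(p.values, p.dt, cutoff_hz)
    n = p.values.size
    i_foot = int(round(t_foot / p.dt))
    i_end = n - 1 if t_end is None else min(n - 1, int(round(t_end / p.dt)))
    # step past the foot's positive acceleration lobe
    i = i_foot
    while i < i_end and d2[i] >= 0:
        i += 1
    # first upward zero-crossing of d2 after the lobe
    while i < i_end:
        if d2[i] < 0 and d2[i + 1] >= 0:
            # linear interpolation of the crossing instant
            frac = -d2[i] / (d2[i + 1] - d2[i])
            return (i + frac) * p.dt
        i += 1
    return None


def pressure_landmarks(p: Waveform, t_end: Optional[float] = None,
                       cutoff_hz: float = DEFAULT_SMOOTH_HZ) -> Landmarks:
    """Foot, inflection and pressure levels of one pressure beat."""
    t_foot = detect_foot(p, cutoff_hz=cutoff_hz)
    t_infl = detect_inflection(p, t_foot, t_end=t_end, cutoff_hz=cutoff_hz)
    v = p.values
    i_peak = int(np.argmax(v))
    lm = Landmarks(
        t_foot=t_foot,
        t_sys_peak=i_peak * p.dt,
        p_dia=float(np.min(v)),
        p_sys=float(np.max(v)),
    )
    if t_infl is not None:
        lm.t_inflection = t_infl
        lm.p_i = float(np.interp(t_infl, p.t, v))
    return lm


# ---------------------------------------------------------------------------
# scalar indices
# ---------------------------------------------------------------------------

def augmentation_index(lm: Landmarks) -> float:
    """AIx = 100 * (p_sys - p_i) / (p_sys - p_dia), in percent."""
    if lm.t_inflection is None or lm.p_i is None:
        raise UndefinedIndexError("no inflection point: AIx undefined")
    if lm.p_sys <= lm.p_dia:
        raise UndefinedIndexError("non-positive pulse pressure")
    return 100.0 * (lm.p_sys - lm.p_i) / (lm.p_sys - lm.p_dia)


def augmentation_index_prime(lm: Landmarks) -> float:
    """AIx' = 100 * (p_sys - p_i) / (p_i - p_dia): augmentation over incident."""
    if lm.t_inflection is None or lm.p_i is None:
        raise UndefinedIndexError("no inflection point: AIx' undefined")
    if lm.p_i <= lm.p_dia:
        raise UndefinedIndexError("p_i equals p_dia: AIx' undefined")
    return 100.0 * (lm.p_sys - lm.p_i) / (lm.p_i - lm.p_dia)


def ejection_duration(q_av: Waveform, cutoff_hz: float = DEFAULT_SMOOTH_HZ,
                      shoulder_fraction: float = 0.1) -> tuple[float, float, float]:
    """Ejection duration from aortic-valve flow velocity, in seconds.

    Onset and end of ejection are the second-derivative maxima bracketing the
    ejection lobe (the sharp upward-curvature corners where flow leaves and
    rejoins the baseline).  Because those corners lie where the lobe meets
    the baseline, the search on each side of the flow peak is restricted to
    samples below ``shoulder_fraction`` of the peak flow; this keeps interior
    deceleration knees (e.g. reflected-wave loading) from masquerading as
    the end of ejection.  Returns ``(t_ej, t_onset, t_offset)``.
    """
    v = q_av.values
    vmax = float(np.max(v))
    if vmax <= 0 or vmax - np.min(v) <= 1e-12:
        raise FlatSignalError("no ejection lobe in the flow trace")
    d2 = second_derivative(v, q_av.dt, cutoff_hz)
    vs = smooth(v, q_av.dt, cutoff_hz)
    i_peak = int(np.argmax(vs))
    if i_peak < 2 or i_peak > v.size - 3:
        raise FlatSignalError("ejection lobe not interior to the trace")
    thresh = shoulder_fraction * float(np.max(vs))
    d2_on = np.where(vs[:i_peak] <= thresh, d2[:i_peak], -np.inf)
    d2_off = np.where(vs[i_peak + 1:] <= thresh, d2[i_peak + 1:], -np.inf)
    if not np.any(np.isfinite(d2_on)) or not np.any(np.isfinite(d2_off)):
        raise FlatSignalError("ejection lobe has no baseline shoulders")
    i_on = int(np.argmax(d2_on))
    i_off = i_peak + 1 + int(np.argmax(d2_off))
    t_on = i_on * q_av.dt
    t_off = i_off * q_av.dt
    if t_off <= t_on:
        raise FlatSignalError("could not bracket the ejection lobe")
    return t_off - t_on, t_on, t_off


def _hf_residual_fraction(p: Waveform) -> float:
    """Robust high-frequency content estimate, as a fraction of pulse height."""
    r = p.values - smooth(p.values, p.dt, DEFAULT_SMOOTH_HZ)
    mad = float(np.median(np.abs(r - np.median(r))))
    span = float(np.ptp(p.values))
    return mad / span if span > 0 else 0.0


#: smoothing cutoff for transit timing: the foot must be localized sharply,
#: so the PWV detector uses a wider bandwidth than the 25 Hz morphology
#: default (heavier smoothing biases the detected foot up the upstroke, and
#: by different amounts at sites with different upstroke steepness, which
#: biases the transit time)
PWV_SMOOTH_HZ = 60.0


def pwv_foot_to_foot(p_site1: Waveform, p_site2: Waveform,
                     path_difference: float,
                     cutoff_hz: float = PWV_SMOOTH_HZ,
                     refine_halfwidth: int = 3) -> float:
    """Foot-to-foot pulse wave velocity between a proximal and a distal site.

    ``path_difference`` is the extra travel distance of site 2 relative to
    site 1 (carotid-femoral convention: combined aorta-to-femoral length minus
    aorta-to-carotid length).  Feet are second-derivative maxima with a
    narrow sub-sample refinement; see ``PWV_SMOOTH_HZ`` for the bandwidth
    rationale.
    """
    if path_difference <= 0:
        raise ValueError("path_difference must be positive")
    # auto-bandwidth: sharp localization has no useful SNR on noisy records,
    # so fall back to the heavily smoothed morphology detector when the
    # high-frequency residual exceeds ~0.3% of the pulse amplitude
    noise = max(_hf_residual_fraction(p_site1), _hf_residual_fraction(p_site2))
    if noise > 0.003:
        cutoff_hz = min(cutoff_hz, DEFAULT_SMOOTH_HZ)
        refine_halfwidth = max(refine_halfwidth, 8)
    t1 = detect_foot(p_site1, cutoff_hz=cutoff_hz,
                     refine_halfwidth=refine_halfwidth)
    t2 = detect_foot(p_site2, cutoff_hz=cutoff_hz,
                     refine_halfwidth=refine_halfwidth)
    transit = t2 - t1
    if transit <= 0:
        raise ValueError("non-positive transit time: beats are mis-aligned")
    return path_difference / transit


def stroke_work(p_lv: Waveform, v_lv: Waveform, closure_rtol: float = 0.05) -> float:
    """Stroke work W = closed-loop integral p dV of one beat, in joules.

    Evaluated as the signed shoelace area of the (V, p) polygon; positive for
    the physiological counterclockwise (ejecting) loop.  Accepts pressure in
    mmHg or Pa and volume in ml or m^3 according to the waveform unit tags.
    """
    p = p_lv.values * (MMHG if p_lv.unit.lower() in ("mmhg",) else 1.0)
    v = v_lv.values * (ML if v_lv.unit.lower() in ("ml",) else 1.0)
    if p.size != v.size:
        raise ValueError("pressure and volume traces must be aligned")
    p_span = np.ptp(p)
    v_span = np.ptp(v)
    if v_span > 0 and p_span > 0:
        gap_v = abs(v[-1] - v[0]) / v_span
        gap_p = abs(p[-1] - p[0]) / p_span
        if max(gap_v, gap_p) > closure_rtol:
            raise ValueError("pressure-volume loop is not closed")
    # shoelace over the closed polygon (x=V, y=p)
    x = np.append(v, v[0])
    y = np.append(p, p[0])
    return 0.5 * float(np.dot(x[:-1], y[1:]) - np.dot(x[1:], y[:-1]))


def peak_systolic_strain_rate(strain: Waveform, window=None,
                              cutoff_hz: float = DEFAULT_SMOOTH_HZ) -> float:
    """Most negative strain rate d(strain)/dt (1/s) within the systolic window.

    Shortening is negative by convention, so the returned value is negative
    for a contracting ventricle.
    """
    ds = np.gradient(smooth(strain.values, strain.dt, cutoff_hz), strain.dt)
    i0, i1 = _window_to_indices(strain.values.size, strain.dt, window)
    # guard band against zero-phase-filter edge transients
    guard = int(round(1.0 / max(cutoff_hz, 1.0) / strain.dt)) if cutoff_hz > 0 else 0
    i0 = max(i0, guard)
    i1 = min(i1, strain.values.size - guard)
    if i1 <= i0:
        i0, i1 = _window_to_indices(strain.values.size, strain.dt, window)
    return float(np.min(ds[i0:i1]))
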