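"""Wave separation analysis (water-hammer decomposition).

Splits an aortic pressure / flow-velocity beat into forward- and
backward-travelling components using the water-hammer relations for
incremental wave fronts,

    dp_fw = (dp + rho*c*dU) / 2,
    dp_bw = (dp - rho*c*dU) / 2,

and running summation of the increments.  The local wave speed c is either
supplied (e.g. the simulator's known value, for validation) or estimated from
the slope of the early-systolic linear portion of the pressure-velocity (PU)
loop, c = (dp/dU)/rho, where the backward component has not yet arrived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import MMHG, Waveform, detect_foot, ejection_duration

RHO_BLOOD = 1050.0  # kg/m^3

#: PU-loop fitting window: samples between the pressure foot and this
#: fraction of the ejection duration are used for the linear fit.
PU_LOOP_FRACTION = 0.30


@dataclass
class SeparatedWaves:
    """Forward/backward pressure and velocity components of one beat."""

    p_fw: np.ndarray        # mmHg, forward pressure component (starts at 0)
    p_bw: np.ndarray        # mmHg, backward pressure component (starts at 0)
    u_fw: np.ndarray        # m/s
    u_bw: np.ndarray        # m/s
    c_est: float            # m/s, wave speed used
    offset: float           # mmHg, pressure at t = 0
    p_fw_amp: float         # mmHg, max - min of forward component
    p_bw_amp: float         # mmHg
    ratio: float            # %, 100 * p_bw_amp / p_fw_amp
    c_supplied: bool = False  # True when c was given externally

    def reconstruct_pressure(self) -> np.ndarray:
        """offset + p_fw + p_bw; equals the input pressure sample-by-sample."""
        return self.offset + self.p_fw + self.p_bw


def _pressure_in_mmhg(p: Waveform) -> np.ndarray:
    if p.unit.lower() == "mmhg":
        return p.values
    return p.values / MMHG


def estimate_wave_speed(p: Waveform, u: Waveform, rho: float = RHO_BLOOD,
                        fit_fraction: float = PU_LOOP_FRACTION) -> float:
    """PU-loop wave speed: slope of the early-systolic p-U relation over rho.

    The fitting window runs from the pressure foot to ``fit_fraction`` of the
    ejection duration, before reflected waves arrive.
    """
    if p.values.size != u.values.size:
        raise ValueError("pressure and velocity must have equal length")
    pv = _pressure_in_mmhg(p) * MMHG
    t_foot = detect_foot(p)
    t_ej, t_on, _ = ejection_duration(u)
    i0 = int(round(min(t_foot, t_on) / p.dt))
    i1 = int(round((min(t_foot, t_on) + fit_fraction * t_ej) / p.dt)) + 1
    i1 = min(i1, p.values.size)
    du = u.values[i0:i1] - u.values[i0]
    dp = pv[i0:i1] - pv[i0]
    denom = float(np.dot(du, du))
    if denom <= 1e-12 * max(1.0, float(np.dot(dp, dp))):
        raise ValueError("no usable early-systolic PU-loop window "
                         "(velocity does not rise with pressure)")
    slope = float(np.dot(du, dp)) / denom
    c = slope / rho
    if c <= 0:
        raise ValueError("PU-loop slope is non-positive")
    return c


def separate(p: Waveform, u: Waveform, c: float,
             rho: float = RHO_BLOOD, c_supplied: bool = False) -> SeparatedWaves:
    """Water-hammer separation of one beat into forward/backward components.

    Components are running sums of the incremental wave fronts and start at
    zero; the reconstruction offset is the measured pressure at the first
    sample.  Amplitudes are max - min of each component over the beat.
    """
    if c <= 0:
        raise ValueError("wave speed must be positive")
    if p.values.size != u.values.size:
        raise ValueError("pressure and velocity must have equal length")
    pv = _pressure_in_mmhg(p)
    zc = rho * c / MMHG  # characteristic impedance in mmHg per (m/s)
    dp = np.diff(pv)
    du = np.diff(u.values)
    dp_fw = 0.5 * (dp + zc * du)
    dp_bw = 0.5 * (dp - zc * du)
    p_fw = np.concatenate(([0.0], np.cumsum(dp_fw)))
    p_bw = np.concatenate(([0.0], np.cumsum(dp_bw)))
    u_fw = p_fw * MMHG / (rho * c)
    u_bw = -p_bw * MMHG / (rho * c)
    amp_fw = float(np.ptp(p_fw))
    amp_bw = float(np.ptp(p_bw))
    ratio = 100.0 * amp_bw / amp_fw if amp_fw > 0 else np.nan
    return SeparatedWaves(
        p_fw=p_fw, p_bw=p_bw, u_fw=u_fw, u_bw=u_bw,
        c_est=c, offset=float(pv[0]),
        p_fw_amp=amp_fw, p_bw_amp=amp_bw, ratio=ratio,
        c_supplied=c_supplied,
    )
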