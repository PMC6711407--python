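"""Sarcomere-level contraction model and one-fiber chamber mechanics.

The myocardial wall is represented by a single representative sarcomere
(modified Hill model): a contractile element of length L_si in series with a
series-elastic element of length L_se (total sarcomere length
L_s = L_si + L_se), in parallel with a passive elastic element loaded by L_s.
The contractile element length evolves as

    dL_si/dt = v_s * (L_se - L_se_iso) / L_se_iso,

with v_s the maximum unloaded sarcomere shortening velocity (the
contractility parameter, 7 um/s for the reference left ventricle) and
L_se_iso the relaxed series-element length.  These dynamics relax L_se
toward L_se_iso; because the actively generated myofiber stress

    sigma_act = S_act * C * (L_si - L_si,ref) * (L_se / L_se_iso)

is proportional to the series-element extension, rapid wall shortening
(L_se < L_se_iso) depresses stress while stretch augments it -- a linear
force-velocity relation whose unloaded intercept is exactly v_s.  C is the
phenomenological mechanical activation, a smooth single-twitch function of
time since activation with a sarcomere-length-dependent amplitude and
duration.

Cavity mechanics use a one-fiber model: with myofiber stress sigma_f
homogeneous in the wall, cavity (transmural) pressure is

    p = (sigma_f / 3) * ln(1 + V_wall / V_cav),

and the sarcomere stretch is the exactly work-conjugate strain
eps(z) = (1/3) [ z ln(1 + 1/z) + ln(1 + z) ], z = V_cav / V_wall, so that
fiber work V_wall * sigma_f * d(eps) equals pump work p * dV_cav
identically.  The heart is enclosed by the pericardium, a compliant sac
whose external pressure rises steeply once total heart volume exceeds its
reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import MMHG


class InvalidParameterError(ValueError):
    pass


class InvalidStateError(ValueError):
    pass


@dataclass
class SarcomereState:
    """Kinematic state of the representative sarcomere (lengths in um)."""

    L_s: float          # total sarcomere length
    L_si: float         # contractile element length
    L_se_iso: float     # relaxed series-element length
    C: float = 0.0      # mechanical activation (dimensionless, >= 0)
    t_act: float = 0.0  # time since chamber activation onset (s)

    @property
    def L_se(self) -> float:
        return self.L_s - self.L_si

    def check(self) -> None:
        if self.L_s <= 0 or self.L_si <= 0 or self.L_se_iso <= 0:
            raise InvalidStateError("sarcomere lengths must be positive")
        if self.C < 0:
            raise InvalidStateError("activation C must be non-negative")


@dataclass
class ActivationParams:
    """Shape of the activation twitch C(t_act, L_s)."""

    c_max: float = 1.0        # peak activation scale
    t_rise: float = 0.06      # s, rise time constant
    t_decay: float = 0.035    # s, decay time constant
    t_dur0: float = 0.28      # s, twitch duration at L_s = L_s,ref
    dur_slope: float = 0.4    # 1/um, lengthening of duration with L_s
    ls_gate: float = 1.5      # um, zero-activation sarcomere length
    gate_gain: float = 3.0    # 1/um, steepness of the length dependence
    L_s_ref: float = 2.0      # um


@dataclass
class WallProperties:
    """Constitutive and geometric parameters of one myocardial wall."""

    wall_volume: float        # ml
    v_s: float = 7.0          # um/s, max unloaded shortening velocity
    L_si_ref: float = 1.51    # um, zero-active-stress contractile length
    L_se_iso: float = 0.04    # um
    L_s_ref: float = 2.0      # um, sarcomere length at the reference volume
    V_cav_ref: float = 70.0   # ml, cavity volume at L_s = L_s_ref
    sigma_act_scale: float = 90e3   # Pa/um, active stress scale S_act
    sigma_pas_scale: float = 50.0   # Pa, passive stress scale
    k_pas: float = 10.0       # 1/um, passive exponential steepness
    L_s_slack: float = 1.8    # um, passive slack length
    activation: ActivationParams = field(default_factory=ActivationParams)

    def __post_init__(self) -> None:
        if self.v_s <= 0 or self.wall_volume <= 0:
            raise InvalidParameterError("v_s and wall_volume must be positive")


@dataclass
class Pericardium:
    """Compliant sac around the four chambers."""

    V_ref: float = 950.0      # ml, reference (slack-limit) heart volume
    p_ref: float = 0.5 * MMHG  # Pa, external pressure at V_heart = V_ref
    exponent: float = 8.0     # stiffness exponent


@dataclass
class Chamber:
    """One cardiac chamber: a cavity enclosed by a one-fiber wall."""

    name: str
    wall: WallProperties
    cavity_volume: float      # ml
    sarcomere: SarcomereState = None
    cavity_pressure: float = 0.0  # Pa

    def __post_init__(self) -> None:
        if self.sarcomere is None:
            ls = sarcomere_length_from_volume(self.cavity_volume, self.wall)
            self.sarcomere = SarcomereState(
                L_s=ls, L_si=ls - self.wall.L_se_iso,
                L_se_iso=self.wall.L_se_iso)


# ---------------------------------------------------------------------------
# one-fiber kinematics
# ---------------------------------------------------------------------------

def _conjugate_strain(z):
    """eps(z) = (1/3)[z ln(1+1/z) + ln(1+z)], z = V_cav / V_wall."""
    z = np.asarray(z, dtype=float)
    return (z * np.log1p(1.0 / z) + np.log1p(z)) / 3.0


def sarcomere_length_from_volume(V_cav: float, wall: WallProperties) -> float:
    """Sarcomere length (um) implied by cavity volume via the one-fiber map."""
    if V_cav <= 0:
        raise InvalidStateError("cavity volume must be positive")
    eps = _conjugate_strain(V_cav / wall.wall_volume)
    eps_ref = _conjugate_strain(wall.V_cav_ref / wall.wall_volume)
    return wall.L_s_ref * float(np.exp(eps - eps_ref))


# ---------------------------------------------------------------------------
# sarcomere operations
# ---------------------------------------------------------------------------

def contractile_rate(state: SarcomereState, wall: WallProperties) -> float:
    """dL_si/dt = v_s (L_se - L_se_iso)/L_se_iso, in um/s."""
    if state.L_se_iso <= 0:
        raise InvalidParameterError("L_se_iso must be positive")
    return wall.v_s * (state.L_se - state.L_se_iso) / state.L_se_iso


def activation(t_act: float, L_s: float, params: ActivationParams) -> float:
    """Mechanical activation C >= 0: a single smooth twitch per beat.

    C = c_max * f_len(L_s) * rise(t) * decay(t): a saturating rise
    1 - exp(-(t/t_rise)^2), a sigmoidal decay centred at the
    length-dependent twitch duration, and a monotone length gate
    tanh(gate_gain * (L_s - ls_gate)) clipped at zero (longer sarcomeres
    activate more strongly and twitch longer).
    """
    if t_act < 0:
        raise InvalidParameterError("t_act must be non-negative")
    if t_act == 0.0:
        return 0.0
    f_len = max(0.0, float(np.tanh(params.gate_gain * (L_s - params.ls_gate))))
    t_dur = params.t_dur0 * (1.0 + params.dur_slope * (L_s - params.L_s_ref))
    rise = 1.0 - np.exp(-((t_act / params.t_rise) ** 2))
    decay = 1.0 / (1.0 + np.exp((t_act - t_dur) / params.t_decay))
    return float(params.c_max * f_len * rise * decay)


def passive_stress(L_s: float, wall: WallProperties) -> float:
    """Passive myofiber stress (Pa): exponential in stretch above slack."""
    x = max(L_s - wall.L_s_slack, 0.0)
    return wall.sigma_pas_scale * float(np.expm1(wall.k_pas * x))


def myofiber_stress(state: SarcomereState, wall: WallProperties) -> float:
    """Total myofiber stress sigma_f = active + passive component (Pa)."""
    state.check()
    active = (wall.sigma_act_scale * state.C
              * max(state.L_si - wall.L_si_ref, 0.0)
              * max(state.L_se, 0.0) / state.L_se_iso)
    return active + passive_stress(state.L_s, wall)


def cavity_pressure(sigma_f: float, V_cav: float, V_wall: float) -> float:
    """One-fiber transmural cavity pressure p = (sigma_f/3) ln(1 + Vw/Vc), Pa."""
    if V_cav <= 0 or V_wall <= 0:
        raise InvalidStateError("cavity and wall volumes must be positive")
    return sigma_f / 3.0 * float(np.log1p(V_wall / V_cav))


def pericardial_pressure(V_heart: float, peri: Pericardium) -> float:
    """External pressure (Pa) of the pericardial sac at total heart volume."""
    if V_heart <= 0:
        raise InvalidStateError("heart volume must be positive")
    return peri.p_ref * (V_heart / peri.V_ref) ** peri.exponent


def isometric_twitch(wall: WallProperties, L_s: float, period: float,
                     dt: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Stress trace of one isometric twitch at prescribed sarcomere length.

    Integrates the contractile-element dynamics with L_s held fixed and
    returns ``(t, sigma_f)`` over one beat period.
    """
    n = int(round(period / dt))
    t = np.arange(n) * dt
    sigma = np.empty(n)
    lsi = L_s - wall.L_se_iso
    st = SarcomereState(L_s=L_s, L_si=lsi, L_se_iso=wall.L_se_iso)
    for i in range(n):
        st.t_act = t[i]
        st.C = activation(t[i], L_s, wall.activation)
        sigma[i] = myofiber_stress(st, wall)
        st.L_si += dt * contractile_rate(st, wall)
    return t, sigma
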