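"""Elastic-tube vascular network: constitutive law, geometry, wave speed.

Each vessel segment is a straight elastic tube whose transmural pressure and
cross-sectional lumen area are related by the nonlinear power law

    p_trans(A) = p0 * [ (1+b) (A/A0)^(1+k/3) - b (1 + A0/A) ],

with reference pressure p0, reference area A0, stiffness coefficient k
(larger k = stiffer wall; "elastic taper" is the increase of k from central
to peripheral vessels), and a small collapse-prevention fraction b that makes
the law diverge to -inf as the tube empties.  In the b -> 0 limit the law is
the pure power law p0 (A/A0)^(1+k/3) and the wave speed obeys
c^2 = (1 + k/3) p_trans / rho.

The printed form of this law in the source material is typographically
ambiguous in how the b-terms group; the grouping above is chosen so that it
(i) reduces to the power law as b -> 0, (ii) is strictly increasing in A,
and (iii) diverges as A -> 0.  At A = A0 it evaluates to p0 (1 - b), an
O(b) = 2% offset from the reference point.

Wave propagation is linear (convective acceleration neglected): on a
staggered grid, cell areas obey mass conservation in flux form and face
flows obey  rho/A * dq/dt = -dp/dx  with Poiseuille wall friction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
from scipy.optimize import brentq

from .metrics import MMHG
from .separation import RHO_BLOOD

MU_BLOOD = 0.0035  # Pa s, dynamic viscosity of blood

#: stiffness coefficients of the reference tree (aorta & vena cava 8,
#: subclavian 14, carotid 16, brachial 18, femoral 20)
K_AORTA, K_SUBCLAVIAN, K_CAROTID, K_BRACHIAL, K_FEMORAL = 8.0, 14.0, 16.0, 18.0, 20.0

#: collapse-prevention fraction of every segment
B_DEFAULT = 0.02

P0_ART_MMHG = 92.0  # arterial reference pressure = MAP operating point
P0_VEN_MMHG = 8.0   # venous reference pressure


class InvalidAreaError(ValueError):
    pass


class NoSolutionError(ValueError):
    pass


@dataclass
class VesselSegment:
    """Geometric and constitutive parameters of one arterial/venous tube."""

    name: str
    length: float        # m
    A0: float            # m^2, reference cross-sectional area
    p0: float            # Pa, reference pressure
    k: float             # stiffness coefficient
    b: float = B_DEFAULT
    p_ext: float = 0.0   # Pa, prescribed external pressure

    def __post_init__(self) -> None:
        if self.k <= 0 or self.A0 <= 0 or self.length <= 0:
            raise ValueError(f"{self.name}: k, A0 and length must be positive")
        if not (0.0 <= self.b < 1.0):
            raise ValueError(f"{self.name}: b must lie in [0, 1)")


@dataclass
class PeripheralBed:
    """Arteriovenous impedance bed terminating an artery-vein pair.

    Three-element structure: a characteristic-impedance entry ``z_entry``
    (matched to the terminal artery to absorb high-frequency numerical
    ringing), a resistive core (the control-loop actuator), and a small
    storage compliance between them.  ``resistance`` is the total DC
    resistance z_entry + r_core; in the purely resistive limit the bed flow
    is (p_art - p_ven) / resistance.
    """

    name: str
    resistance: float        # Pa s / m^3, total DC resistance
    z_entry: float = 0.0     # Pa s / m^3
    compliance: float = 0.0  # m^3 / Pa (0 -> purely resistive)

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ValueError("bed resistance must be positive")
        if not (0.0 <= self.z_entry < self.resistance):
            raise ValueError("z_entry must lie in [0, resistance)")

    @property
    def r_core(self) -> float:
        return self.resistance - self.z_entry


# ---------------------------------------------------------------------------
# constitutive law
# ---------------------------------------------------------------------------

def transmural_pressure(A, seg: VesselSegment):
    """Transmural pressure (Pa) of the wall law at lumen area ``A`` (m^2)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise InvalidAreaError("lumen area must be positive")
    x = A / seg.A0
    p = seg.p0 * ((1.0 + seg.b) * x ** (1.0 + seg.k / 3.0)
                  - seg.b * (1.0 + 1.0 / x))
    return p if p.ndim else float(p)


def luminal_pressure(A, seg: VesselSegment):
    """Intraluminal pressure = transmural + prescribed external pressure."""
    return transmural_pressure(A, seg) + seg.p_ext


def dp_dA(A, seg: VesselSegment):
    """Analytic slope of the wall law, d p_trans / dA (Pa / m^2)."""
    A = np.asarray(A, dtype=float)
    x = A / seg.A0
    s = seg.p0 * ((1.0 + seg.b) * (1.0 + seg.k / 3.0) * x ** (seg.k / 3.0) / seg.A0
                  + seg.b * seg.A0 / (A * A))
    return s if s.ndim else float(s)


def area_from_pressure(p_trans: float, seg: VesselSegment) -> float:
    """Invert the wall law: unique lumen area at transmural pressure ``p_trans``.

    The law is strictly increasing in A, so the root is bracketed and unique.
    """
    lo, hi = 1e-6 * seg.A0, seg.A0
    f = lambda a: transmural_pressure(a, seg) - p_trans
    if f(lo) > 0:
        raise NoSolutionError("pressure below the image of the wall law")
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4 * seg.A0:
            raise NoSolutionError("pressure above the admissible range")
    return float(brentq(f, lo, hi, xtol=1e-18, rtol=1e-14))


def wave_speed(A, seg: VesselSegment, rho: float = RHO_BLOOD):
    """Local wave speed c = sqrt(A/rho * dp/dA) (m/s).

    In the b -> 0 power-law limit this reduces to
    c^2 = (1 + k/3) p_trans / rho.
    """
    slope = dp_dA(A, seg)
    if np.any(np.asarray(slope) <= 0):
        raise InvalidAreaError("non-positive constitutive slope")
    c = np.sqrt(np.asarray(A, dtype=float) / rho * slope)
    return c if c.ndim else float(c)


def bed_flow(p_art: float, p_ven: float, bed: PeripheralBed) -> float:
    """Steady (resistive-limit) bed flow q = (p_art - p_ven)/R (m^3/s)."""
    return (p_art - p_ven) / bed.resistance


# ---------------------------------------------------------------------------
# reference topology
# ---------------------------------------------------------------------------

# name, length (m), A0 (m^2), k ; bilateral vessels are merged into one
# equivalent segment.  A0 and lengths follow typical human values, with the
# aorta-to-femoral minus aorta-to-carotid path difference ~0.44 m.
_ARTERY_TABLE = [
    ("aorta_asc",      0.08, 8.0e-4, K_AORTA),
    ("aorta_desc",     0.20, 3.6e-4, K_AORTA),
    ("aorta_abd",      0.10, 2.4e-4, K_AORTA),
    ("carotid_art",    0.16, 0.6e-4, K_CAROTID),
    ("subclavian_art", 0.05, 1.0e-4, K_SUBCLAVIAN),
    ("brachial_art",   0.42, 0.5e-4, K_BRACHIAL),
    ("splanchnic_art", 0.14, 1.8e-4, K_SUBCLAVIAN),
    ("femoral_art",    0.30, 0.6e-4, K_FEMORAL),
]

#: venous lumen areas are this multiple of the paired arterial areas
VEIN_AREA_FACTOR = 2.5

#: fraction of total systemic conductance routed through each bed
BED_FRACTIONS = {"head": 0.20, "arm": 0.15, "trunk": 0.35, "leg": 0.30}

#: junction wiring of the arterial tree: node -> (segment, end) pairs,
#: end 0 = proximal, 1 = distal.  The venous tree mirrors it.
_ART_JUNCTIONS = {
    "J1": [("aorta_asc", 1), ("carotid_art", 0), ("subclavian_art", 0), ("aorta_desc", 0)],
    "J2": [("subclavian_art", 1), ("brachial_art", 0)],
    "J3": [("aorta_desc", 1), ("splanchnic_art", 0), ("aorta_abd", 0)],
    "J4": [("aorta_abd", 1), ("femoral_art", 0)],
}

#: bed -> (terminal artery, terminal vein)
_BED_PAIRS = {
    "head": ("carotid_art", "carotid_vein"),
    "arm": ("brachial_art", "brachial_vein"),
    "trunk": ("splanchnic_art", "splanchnic_vein"),
    "leg": ("femoral_art", "femoral_vein"),
}


@dataclass
class NetworkTopology:
    """Segments, junction wiring and bed pairing of the systemic tree."""

    segments: dict                      # name -> VesselSegment
    junctions: dict                     # node -> list of (segment name, end)
    beds: dict                          # bed name -> PeripheralBed
    bed_pairs: dict                     # bed name -> (artery name, vein name)
    root_artery: str = "aorta_asc"      # proximal end feeds the aortic valve
    root_vein: str = "vena_cava_asc"    # proximal end drains into the RA
    carotid_site: str = "carotid_art"   # distal end: carotid measurement site
    femoral_site: str = "femoral_art"   # distal end: femoral measurement site

    @property
    def path_difference(self) -> float:
        """PWV travel distance: (aorta->femoral) - (aorta->carotid) path (m)."""
        s = self.segments
        to_fem = (s["aorta_asc"].length + s["aorta_desc"].length
                  + s["aorta_abd"].length + s["femoral_art"].length)
        to_car = s["aorta_asc"].length + s["carotid_art"].length
        return to_fem - to_car


def reference_tree(delta_k: float = 0.0,
                   p0_art_mmhg: float = P0_ART_MMHG,
                   p0_ven_mmhg: float = P0_VEN_MMHG,
                   b: float = B_DEFAULT,
                   r_systemic: float = 1.35e8,
                   bed_tau: float = 0.27) -> NetworkTopology:
    """Build the reference systemic tree (aorta + vena cava + four branches).

    ``delta_k`` is added to every segment's stiffness coefficient (arterial
    stiffening scenarios).  ``r_systemic`` is the total systemic resistance
    distributed over the beds according to ``BED_FRACTIONS``; ``bed_tau`` is
    the storage time constant r_core * compliance of each bed.
    """
    p0a = p0_art_mmhg * MMHG
    p0v = p0_ven_mmhg * MMHG
    segments: dict[str, VesselSegment] = {}
    for name, length, a0, k in _ARTERY_TABLE:
        if k + delta_k <= 0:
            raise ValueError("delta_k drives a stiffness coefficient non-positive")
        segments[name] = VesselSegment(name, length, a0, p0a, k + delta_k, b)
        vname = (name.replace("_art", "_vein")
                 .replace("aorta", "vena_cava"))
        segments[vname] = VesselSegment(vname, length, a0 * VEIN_AREA_FACTOR,
                                        p0v, k + delta_k, b)
    junctions = {}
    for node, members in _ART_JUNCTIONS.items():
        junctions[node] = list(members)
        junctions[node + "v"] = [
            (nm.replace("_art", "_vein").replace("aorta", "vena_cava"), end)
            for nm, end in members]
    beds = {}
    for bname, frac in BED_FRACTIONS.items():
        r_total = r_systemic / frac
        art = segments[_BED_PAIRS[bname][0]]
        z = RHO_BLOOD * wave_speed(art.A0, art) / art.A0
        z = min(z, 0.5 * r_total)
        # bed storage represents distal small-artery compliance, which
        # stiffens with delta_k like the named segments do
        k_term = art.k - delta_k
        stiffen = (1.0 + k_term / 3.0) / (1.0 + art.k / 3.0)
        compliance = bed_tau * stiffen / (r_total - z) if bed_tau > 0 else 0.0
        beds[bname] = PeripheralBed(bname, resistance=r_total, z_entry=z,
                                    compliance=compliance)
    return NetworkTopology(segments=segments, junctions=junctions,
                           beds=beds, bed_pairs=dict(_BED_PAIRS))


# ---------------------------------------------------------------------------
# single-tube wave propagation (the network stepper on one uniform segment)
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _tube_loop(A, qf, nsteps, dt, dx, a0, p0, k, b, rho, mu,
               qin, r_term, p_out, rec_every, rec):  # pragma: no cover
    n = A.size
    exponent = 1.0 + k / 3.0
    irec = 0
    q_end = 0.0
    for step in range(nsteps):
        if step % rec_every == 0 and irec < rec.shape[1]:
            for j in range(n):
                x = A[j] / a0
                rec[j, irec] = p0 * ((1.0 + b) * x ** exponent
                                     - b * (1.0 + 1.0 / x))
            irec += 1
        # cell pressures
        p = np.empty(n)
        for j in range(n):
            x = A[j] / a0
            p[j] = p0 * ((1.0 + b) * x ** exponent - b * (1.0 + 1.0 / x))
        # internal face momentum (linear, with Poiseuille friction)
        for f in range(n - 1):
            af = 0.5 * (A[f] + A[f + 1])
            fric = 8.0 * np.pi * mu / (rho * af)
            force = -(af / rho) * (p[f + 1] - p[f]) / dx
            qf[f] = (qf[f] + dt * force) / (1.0 + dt * fric)
        # terminal flow: resistive load behind the half-cell inertia of the
        # last cell (r_term <= 0 means closed end)
        if r_term > 0.0:
            a_t = A[n - 1] / (rho * 0.5 * dx)
            fric = 8.0 * np.pi * mu / (rho * A[n - 1])
            q_end = (q_end + dt * a_t * (p[n - 1] - p_out)) \
                / (1.0 + dt * a_t * r_term + dt * fric)
        else:
            q_end = 0.0
        # mass conservation in flux form
        A[0] += dt * (qin[step] - qf[0]) / dx
        for j in range(1, n - 1):
            A[j] += dt * (qf[j - 1] - qf[j]) / dx
        A[n - 1] += dt * (qf[n - 2] - q_end) / dx


def simulate_uniform_tube(seg: VesselSegment, p_init: float, q_inflow,
                          duration: float, dt: float = 5e-5, dx: float = 0.01,
                          termination: str = "closed",
                          rho: float = RHO_BLOOD, mu: float = MU_BLOOD,
                          rec_dt: float = 1e-3):
    """Propagate a prescribed inflow pulse along one uniform tube.

    ``q_inflow(t)`` is the prescribed proximal inflow; ``termination`` is
    ``"closed"`` (q = 0 at the distal end) or ``"matched"`` (resistive load
    rho*c/A evaluated at the initial state, reflection-free in the linear
    limit).  Returns ``(t_rec, p_cells, x_centers)`` with pressures in Pa.

    The explicit scheme requires dt below the CFL bound dx / c_max; a
    stability violation is reported rather than integrated through.
    """
    n = max(int(round(seg.length / dx)), 4)
    dx = seg.length / n
    a_init = area_from_pressure(p_init, seg)
    c0 = wave_speed(a_init, seg, rho)
    nsteps = int(round(duration / dt))
    t = np.arange(nsteps) * dt
    qin = np.asarray([q_inflow(tt) for tt in t], dtype=float)
    if termination == "matched":
        r_term = rho * c0 / a_init
        p_out = p_init
    elif termination == "closed":
        r_term = -1.0
        p_out = 0.0
    else:
        raise ValueError("termination must be 'closed' or 'matched'")
    A = np.full(n, a_init)
    qf = np.zeros(n - 1)
    rec_every = max(int(round(rec_dt / dt)), 1)
    nrec = (nsteps + rec_every - 1) // rec_every
    rec = np.empty((n, nrec))
    _tube_loop(A, qf, nsteps, dt, dx, seg.A0, seg.p0, seg.k, seg.b, rho, mu,
               qin, r_term, p_out, rec_every, rec)
    if not np.all(np.isfinite(A)) or np.any(A <= 0):
        raise FloatingPointError(
            "tube integration went unstable: reduce dt below the CFL bound "
            f"dx/c ~ {dx / c0:.2e} s")
    c_max = wave_speed(float(np.max(A)), seg, rho)
    if c_max * dt / dx > 1.0:
        raise FloatingPointError("CFL bound violated during integration")
    t_rec = np.arange(nrec) * rec_every * dt
    x_centers = (np.arange(n) + 0.5) * dx
    return t_rec, rec, x_centers
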