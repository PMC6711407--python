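"""Closed-loop circulation: four chambers, valves, systemic tree, lungs.

Assembles the one-fiber chambers (``cardiac``) and the elastic-tube systemic
network (``vessels``) into a closed loop with four pressure-gated valves, a
lumped pulmonary circuit and a pericardial sac, enforces the homeostatic
targets (mean arterial pressure via systemic resistance, cardiac output via
circulating blood volume), runs beats to steady state, and emits uniformly
sampled waveforms of the final beat.

The numerical core is a single explicit time-stepping kernel (numba-compiled)
advancing, at a fixed step dt:

* vessel cell areas (mass conservation in flux form) and face flows (linear
  momentum with Poiseuille friction) on a staggered grid,
* junction flows with an algebraically solved single-valued node pressure
  that enforces exact mass conservation at every junction,
* arteriovenous beds (characteristic-impedance entry, resistive core,
  storage compliance),
* chamber volumes and contractile-element lengths,
* valve opening state and inertial Bernoulli flow,
* the lumped pulmonary artery/vein compliances.

Everything is deterministic: identical configurations produce bit-identical
results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numba
import numpy as np
import pandas as pd

from .metrics import MMHG
from .separation import RHO_BLOOD
from .vessels import (MU_BLOOD, NetworkTopology, area_from_pressure,
                      reference_tree, wave_speed)
from . import cardiac
from .cardiac import ActivationParams, Pericardium, WallProperties

ML = 1e-6
LMIN = 1e-3 / 60.0  # m^3/s per l/min

#: chamber ordering inside the kernel
LV, RV, LA, RA = 0, 1, 2, 3

#: valve ordering: mitral (LA->LV), aortic (LV->aorta), tricuspid (RA->RV),
#: pulmonic (RV->pulmonary artery)
MITRAL, AORTIC, TRICUSPID, PULMONIC = 0, 1, 2, 3

#: record channel ordering of the kernel output
REC_CHANNELS = ("time_s", "p_ao", "u_ao", "q_av", "p_lv", "v_lv",
                "strain_lv", "p_car", "p_fem", "v_total", "p_ra", "p_pa")


class NonConvergenceError(RuntimeError):
    pass


class StabilityError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Parameter set of one closed-loop simulation."""

    v_s_LV: float = 7.0            # um/s, LV sarcomere shortening velocity
    delta_k: float = 0.0           # added to every segment's stiffness k
    p0_art_mmhg: float = 92.0      # arterial reference pressure (= MAP level)
    heart_rate: float = 72.0       # beats/min
    map_target_mmhg: Optional[float] = None  # defaults to p0_art_mmhg
    co_target_lmin: float = 5.1    # l/min
    # numerics
    dt: float = 1.5e-4             # s, solver step (rounded to fit the beat)
    dx: float = 0.015              # m, target cell size
    rec_dt: float = 1.0e-3         # s, output sampling target
    max_beats: int = 220
    target_rtol: float = 0.005     # homeostatic target tolerance (0.5%)
    periodic_rtol: float = 0.005   # beat-to-beat RMS tolerance (of pulse pressure)
    settle_beats: int = 3          # consecutive in-tolerance beats required
    # control gains
    gain_resistance: float = 0.8
    gain_volume: float = 2.2
    # vascular/bed details
    p0_ven_mmhg: float = 8.0
    b: float = 0.02
    r_systemic: float = 1.35e8     # Pa s/m^3, initial total systemic resistance
    bed_tau: float = 0.27          # s, bed storage time constant

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")
        if self.co_target_lmin <= 0 or self.p0_art_mmhg <= 0:
            raise ValueError("targets must be positive")
        if self.map_target_mmhg is None:
            self.map_target_mmhg = self.p0_art_mmhg

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def map_target(self) -> float:
        return self.map_target_mmhg * MMHG

    @property
    def co_target(self) -> float:
        return self.co_target_lmin * LMIN


def _default_walls(v_s_LV: float) -> list[WallProperties]:
    """Wall properties of LV, RV, LA, RA (volumes in ml).

    Ventricles share activation timing; atria are weaker, twitch shorter and
    activate at a fixed offset before the ventricles.
    """
    vent_act = ActivationParams(c_max=1.0, t_rise=0.115, t_decay=0.045,
                                t_dur0=0.375, dur_slope=0.4)
    atri_act = ActivationParams(c_max=0.25, t_rise=0.035, t_decay=0.025,
                                t_dur0=0.12, dur_slope=0.4)
    lv = WallProperties(wall_volume=180.0, v_s=v_s_LV, V_cav_ref=70.0,
                        sigma_act_scale=130e3, activation=vent_act)
    rv = WallProperties(wall_volume=45.0, v_s=7.0, V_cav_ref=70.0,
                        sigma_act_scale=120e3, activation=vent_act)
    la = WallProperties(wall_volume=25.0, v_s=7.0, V_cav_ref=50.0,
                        sigma_act_scale=60e3, activation=atri_act)
    ra = WallProperties(wall_volume=25.0, v_s=7.0, V_cav_ref=50.0,
                        sigma_act_scale=60e3, activation=atri_act)
    return [lv, rv, la, ra]


#: atria activate this long before the ventricles (s)
ATRIAL_LEAD = 0.17


# ---------------------------------------------------------------------------
# the compiled stepping kernel
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _step_kernel(nsteps, dt, t_start, period, rec_every, rec,
                 # vessel cells
                 A, ca0, cp0, ck, cb, cpext, cdx,
                 # internal faces
                 qf, fL, fR,
                 # junction faces
                 qj, jcell, jnode, n_nodes,
                 # beds
                 pm, bac, bvc, bZ, bRc, bC,
                 # heart state
                 Vc, Lsi,
                 # heart params [4]
                 hvw, hepsref, hlsref, hlsiref, hlseiso, hsact, hvs,
                 hcmax, htrise, htdecay, htdur0, htdurs, hlsgate, hggain,
                 hsp, hkp, hls0, hact0,
                 # valves
                 xi, qv, vAopen, vleak, vleff, vtau, vdpw,
                 # lumped pulmonary: lump = [Vpa, Vpv] (m^3)
                 lump, cpa, ppa0, vpa0, cpv, ppv0, vpv0, rpul, rpvla, rvcra,
                 # pericardium
                 perivref, peripref, periexp,
                 # plumbing
                 ao_root, vc_root, car_cell, fem_cell,
                 q_inj, rho, mu):  # pragma: no cover - compiled
    nc = A.size
    nf = qf.size
    nj = qj.size
    nb = pm.size
    p = np.empty(nc)
    pcav = np.empty(4)
    dlsi = np.empty(4)
    ls_arr = np.empty(4)
    num = np.empty(n_nodes)
    den = np.empty(n_nodes)
    wallvol_total = hvw[0] + hvw[1] + hvw[2] + hvw[3]
    irec = 0
    for step in range(nsteps):
        t = t_start + step * dt
        # --- vessel cell pressures -------------------------------------
        for i in range(nc):
            x = A[i] / ca0[i]
            p[i] = cp0[i] * ((1.0 + cb[i]) * x ** (1.0 + ck[i] / 3.0)
                             - cb[i] * (1.0 + 1.0 / x)) + cpext[i]
        # --- heart: sarcomere mechanics and cavity pressures -----------
        vheart = Vc[0] + Vc[1] + Vc[2] + Vc[3] + wallvol_total
        pperi = peripref * (vheart / perivref) ** periexp
        for ch in range(4):
            z = Vc[ch] / hvw[ch]
            eps = (z * np.log(1.0 + 1.0 / z) + np.log(1.0 + z)) / 3.0
            ls = hlsref[ch] * np.exp(eps - hepsref[ch])
            ls_arr[ch] = ls
            lse = ls - Lsi[ch]
            tact = (t - hact0[ch]) % period
            # activation twitch
            flen = np.tanh(hggain[ch] * (ls - hlsgate[ch]))
            if flen < 0.0:
                flen = 0.0
            tdur = htdur0[ch] * (1.0 + htdurs[ch] * (ls - hlsref[ch]))
            rise = 1.0 - np.exp(-((tact / htrise[ch]) ** 2))
            decay = 1.0 / (1.0 + np.exp((tact - tdur) / htdecay[ch]))
            c_act = hcmax[ch] * flen * rise * decay
            dlsi[ch] = hvs[ch] * (lse - hlseiso[ch]) / hlseiso[ch]
            dlsi_act = Lsi[ch] - hlsiref[ch]
            if dlsi_act < 0.0:
                dlsi_act = 0.0
            lse_pos = lse if lse > 0.0 else 0.0
            sigma = hsact[ch] * c_act * dlsi_act * lse_pos / hlseiso[ch]
            xpas = ls - hls0[ch]
            if xpas > 0.0:
                sigma += hsp[ch] * (np.exp(hkp[ch] * xpas) - 1.0)
            pcav[ch] = sigma / 3.0 * np.log(1.0 + hvw[ch] / Vc[ch]) + pperi
        # --- lumped pulmonary pressures ---------------------------------
        p_pa = ppa0 + (lump[0] - vpa0) / cpa
        p_pv = ppv0 + (lump[1] - vpv0) / cpv
        # --- valves ------------------------------------------------------
        for v in range(4):
            if v == MITRAL:
                dp = pcav[LA] - pcav[LV]
            elif v == AORTIC:
                dp = pcav[LV] - p[ao_root]
            elif v == TRICUSPID:
                dp = pcav[RA] - pcav[RV]
            else:
                dp = pcav[RV] - p_pa
            target = 1.0 / (1.0 + np.exp(-dp / vdpw))
            xi[v] += dt * (target - xi[v]) / vtau
            av = vleak + xi[v] * vAopen[v]
            lin = rho * vleff / av
            bern = rho / (2.0 * av * av)
            qv[v] = (qv[v] + dt * dp / lin) / (1.0 + dt * bern * abs(qv[v]) / lin)
        q_lung = (p_pa - p_pv) / rpul
        q_pvla = (p_pv - pcav[LA]) / rpvla
        q_vcra = (p[vc_root] - pcav[RA]) / rvcra
        # --- recording (state at the start of the step) ------------------
        if step % rec_every == 0 and irec < rec.shape[1]:
            vtot = lump[0] + lump[1] + Vc[0] + Vc[1] + Vc[2] + Vc[3]
            for i in range(nc):
                vtot += A[i] * cdx[i]
            for bi in range(nb):
                vtot += bC[bi] * pm[bi]
            rec[0, irec] = t
            rec[1, irec] = p[ao_root]
            rec[2, irec] = qv[AORTIC] / A[ao_root]
            rec[3, irec] = qv[AORTIC]
            rec[4, irec] = pcav[LV]
            rec[5, irec] = Vc[LV]
            rec[6, irec] = np.log(ls_arr[LV] / hlsref[LV])
            rec[7, irec] = p[car_cell]
            rec[8, irec] = p[fem_cell]
            rec[9, irec] = vtot
            rec[10, irec] = pcav[RA]
            rec[11, irec] = p_pa
            irec += 1
        # --- internal face momentum --------------------------------------
        for f in range(nf):
            l = fL[f]
            r = fR[f]
            af = 0.5 * (A[l] + A[r])
            h = 0.5 * (cdx[l] + cdx[r])
            fric = 8.0 * np.pi * mu / (rho * af)
            qf[f] = (qf[f] - dt * (af / rho) * (p[r] - p[l]) / h) \
                / (1.0 + dt * fric)
        # --- junction faces: solve node pressures, then update flows -----
        for nd in range(n_nodes):
            num[nd] = 0.0
            den[nd] = 0.0
        for j in range(nj):
            c = jcell[j]
            a = A[c] / (rho * 0.5 * cdx[c])
            fric = 8.0 * np.pi * mu / (rho * A[c])
            w = 1.0 / (1.0 + dt * fric)
            num[jnode[j]] += (qj[j] + dt * a * p[c]) * w
            den[jnode[j]] += dt * a * w
        for j in range(nj):
            c = jcell[j]
            a = A[c] / (rho * 0.5 * cdx[c])
            fric = 8.0 * np.pi * mu / (rho * A[c])
            pn = num[jnode[j]] / den[jnode[j]]
            qj[j] = (qj[j] + dt * a * (p[c] - pn)) / (1.0 + dt * fric)
        # --- beds ---------------------------------------------------------
        for bi in range(nb):
            pa = p[bac[bi]]
            pv = p[bvc[bi]]
            if bC[bi] > 0.0:
                q_in = (pa - pm[bi]) / bZ[bi]
                q_out = (pm[bi] - pv) / bRc[bi]
                pm[bi] += dt * (q_in - q_out) / bC[bi]
            else:
                q_in = (pa - pv) / (bZ[bi] + bRc[bi])
                q_out = q_in
            A[bac[bi]] -= dt * q_in / cdx[bac[bi]]
            A[bvc[bi]] += dt * q_out / cdx[bvc[bi]]
        # --- mass updates --------------------------------------------------
        for f in range(nf):
            A[fL[f]] -= dt * qf[f] / cdx[fL[f]]
            A[fR[f]] += dt * qf[f] / cdx[fR[f]]
        for j in range(nj):
            A[jcell[j]] -= dt * qj[j] / cdx[jcell[j]]
        A[ao_root] += dt * qv[AORTIC] / cdx[ao_root]
        A[vc_root] += dt * (q_inj - q_vcra) / cdx[vc_root]
        Vc[LV] += dt * (qv[MITRAL] - qv[AORTIC])
        Vc[RV] += dt * (qv[TRICUSPID] - qv[PULMONIC])
        Vc[LA] += dt * (q_pvla - qv[MITRAL])
        Vc[RA] += dt * (q_vcra - qv[TRICUSPID])
        lump[0] += dt * (qv[PULMONIC] - q_lung)
        lump[1] += dt * (q_lung - q_pvla)
        for ch in range(4):
            Lsi[ch] += dt * dlsi[ch]
    return irec


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Waveforms and convergence metadata of one simulated scenario."""

    waveforms: pd.DataFrame            # final-beat traces, CSV dialect units
    dt: float                          # output sampling step (s)
    converged: bool
    achieved_map_mmhg: float
    achieved_co_lmin: float
    n_beats: int
    config: ScenarioConfig
    path_difference: float             # m, PWV travel distance of the tree
    beat_history: pd.DataFrame = None  # per-beat MAP / CO / control trace
    aortic_root_area: float = np.nan   # m^2, time-average A at the root
    model: object = None               # the integrated Model (for inspection)


class Model:
    """Discretized closed-loop model (built by :func:`build_model`)."""

    def __init__(self, config: ScenarioConfig, tree: NetworkTopology,
                 walls: list[WallProperties], pericardium: Pericardium):
        self.config = config
        self.tree = tree
        self.walls = walls
        self.pericardium = pericardium
        self.chambers = ["LV", "RV", "LA", "RA"]
        self._discretize()
        self._init_heart()
        self._init_lumped()
        self.t_now = 0.0
        self.resistance_scale = 1.0
        self.q_inj = 0.0

    # -- assembly ----------------------------------------------------------
    def _discretize(self) -> None:
        cfg = self.config
        names = list(self.tree.segments)
        self.cell_span: dict[str, tuple[int, int]] = {}
        ca0, cp0, ck, cb, cpext, cdx = [], [], [], [], [], []
        fL, fR = [], []
        i = 0
        for name in names:
            seg = self.tree.segments[name]
            n = max(int(round(seg.length / cfg.dx)), 2)
            d = seg.length / n
            self.cell_span[name] = (i, i + n)
            for j in range(n):
                ca0.append(seg.A0)
                cp0.append(seg.p0)
                ck.append(seg.k)
                cb.append(seg.b)
                cpext.append(seg.p_ext)
                cdx.append(d)
                if j > 0:
                    fL.append(i + j - 1)
                    fR.append(i + j)
            i += n
        self.n_cells = i
        self.ca0 = np.array(ca0)
        self.cp0 = np.array(cp0)
        self.ck = np.array(ck)
        self.cb = np.array(cb)
        self.cpext = np.array(cpext)
        self.cdx = np.array(cdx)
        self.fL = np.array(fL, dtype=np.int64)
        self.fR = np.array(fR, dtype=np.int64)
        # junction faces
        jcell, jnode = [], []
        self.node_names = list(self.tree.junctions)
        for nd, members in self.tree.junctions.items():
            for segname, end in members:
                lo, hi = self.cell_span[segname]
                jcell.append(lo if end == 0 else hi - 1)
                jnode.append(self.node_names.index(nd))
        self.jcell = np.array(jcell, dtype=np.int64)
        self.jnode = np.array(jnode, dtype=np.int64)
        # beds
        bac, bvc, bZ, bRc, bC = [], [], [], [], []
        self.bed_names = list(self.tree.beds)
        for bname in self.bed_names:
            art, vein = self.tree.bed_pairs[bname]
            bac.append(self.cell_span[art][1] - 1)
            bvc.append(self.cell_span[vein][1] - 1)
            bed = self.tree.beds[bname]
            bZ.append(bed.z_entry)
            bRc.append(bed.r_core)
            bC.append(bed.compliance)
        self.bac = np.array(bac, dtype=np.int64)
        self.bvc = np.array(bvc, dtype=np.int64)
        self.bZ = np.array(bZ)
        self.bRc0 = np.array(bRc)
        self.bC = np.array(bC)
        # plumbing indices
        self.ao_root = self.cell_span[self.tree.root_artery][0]
        self.vc_root = self.cell_span[self.tree.root_vein][0]
        self.car_cell = self.cell_span[self.tree.carotid_site][1] - 1
        self.fem_cell = self.cell_span[self.tree.femoral_site][1] - 1
        # initial vessel state: arteries at p0, veins at p0 (their own)
        A = np.empty(self.n_cells)
        for name in names:
            seg = self.tree.segments[name]
            lo, hi = self.cell_span[name]
            A[lo:hi] = area_from_pressure(0.9 * seg.p0, seg)
        self.A = A
        self.qf = np.zeros(self.fL.size)
        self.qj = np.zeros(self.jcell.size)
        # bed storage starts at the arterial-side pressure
        self.pm = np.array([0.9 * self.cp0[c] for c in self.bac])
        # timing: steps per beat, rounded to an integer multiple of rec_every
        period = cfg.period
        rec_every = max(int(round(cfg.rec_dt / cfg.dt)), 1)
        nsteps = int(math.ceil(period / cfg.dt / rec_every)) * rec_every
        self.rec_every = rec_every
        self.nsteps_beat = nsteps
        self.dt = period / nsteps
        self.rec_dt = self.dt * rec_every
        self.nrec_beat = nsteps // rec_every

    def _init_heart(self) -> None:
        v_init = np.array([120.0, 120.0, 60.0, 60.0]) * ML
        self.Vc = v_init.copy()
        self.hvw = np.array([w.wall_volume * ML for w in self.walls])
        self.hvcref = np.array([w.V_cav_ref * ML for w in self.walls])
        self.hepsref = np.array(
            [float(cardiac._conjugate_strain(w.V_cav_ref / w.wall_volume))
             for w in self.walls])
        self.hlsref = np.array([w.L_s_ref for w in self.walls])
        self.hlsiref = np.array([w.L_si_ref for w in self.walls])
        self.hlseiso = np.array([w.L_se_iso for w in self.walls])
        self.hsact = np.array([w.sigma_act_scale for w in self.walls])
        self.hvs = np.array([w.v_s for w in self.walls])
        acts = [w.activation for w in self.walls]
        self.hcmax = np.array([a.c_max for a in acts])
        self.htrise = np.array([a.t_rise for a in acts])
        self.htdecay = np.array([a.t_decay for a in acts])
        self.htdur0 = np.array([a.t_dur0 for a in acts])
        self.htdurs = np.array([a.dur_slope for a in acts])
        self.hlsgate = np.array([a.ls_gate for a in acts])
        self.hggain = np.array([a.gate_gain for a in acts])
        self.hsp = np.array([w.sigma_pas_scale for w in self.walls])
        self.hkp = np.array([w.k_pas for w in self.walls])
        self.hls0 = np.array([w.L_s_slack for w in self.walls])
        period = self.config.period
        self.hact0 = np.array([0.0, 0.0, period - ATRIAL_LEAD,
                               period - ATRIAL_LEAD])
        ls = np.array([cardiac.sarcomere_length_from_volume(
            v / ML, w) for v, w in zip(self.Vc, self.walls)])
        self.Lsi = ls - self.hlseiso
        self.xi = np.zeros(4)
        self.qv = np.zeros(4)
        self.vAopen = np.array([7e-4, 5e-4, 8e-4, 5.5e-4])
        self.vleak = 1e-8
        self.vleff = 0.030
        self.vtau = 0.006
        self.vdpw = 100.0

    def _init_lumped(self) -> None:
        self.cpa = 3.0e-8       # m^3/Pa, pulmonary artery compliance
        self.ppa0 = 15.0 * MMHG
        self.vpa0 = 80.0 * ML
        self.cpv = 1.2e-7       # pulmonary venous compliance
        self.ppv0 = 8.0 * MMHG
        self.vpv0 = 150.0 * ML
        self.rpul = 1.1e7       # Pa s/m^3
        self.rpvla = 3.0e6
        self.rvcra = 2.0e6
        self.lump = np.array([self.vpa0, self.vpv0])

    # -- stepping ----------------------------------------------------------
    def run_beat(self) -> np.ndarray:
        """Advance one beat; returns the record array (channels x samples)."""
        rec = np.empty((len(REC_CHANNELS), self.nrec_beat))
        bRc = self.bRc0 * self.resistance_scale
        _step_kernel(
            self.nsteps_beat, self.dt, self.t_now, self.config.period,
            self.rec_every, rec,
            self.A, self.ca0, self.cp0, self.ck, self.cb, self.cpext, self.cdx,
            self.qf, self.fL, self.fR,
            self.qj, self.jcell, self.jnode, len(self.node_names),
            self.pm, self.bac, self.bvc, self.bZ, bRc, self.bC,
            self.Vc, self.Lsi,
            self.hvw, self.hepsref, self.hlsref, self.hlsiref, self.hlseiso,
            self.hsact, self.hvs, self.hcmax, self.htrise, self.htdecay,
            self.htdur0, self.htdurs, self.hlsgate, self.hggain,
            self.hsp, self.hkp, self.hls0, self.hact0,
            self.xi, self.qv, self.vAopen, self.vleak, self.vleff,
            self.vtau, self.vdpw,
            self.lump, self.cpa, self.ppa0, self.vpa0, self.cpv, self.ppv0,
            self.vpv0, self.rpul, self.rpvla, self.rvcra,
            self.pericardium.V_ref * ML, self.pericardium.p_ref,
            self.pericardium.exponent,
            self.ao_root, self.vc_root, self.car_cell, self.fem_cell,
            self.q_inj, RHO_BLOOD, MU_BLOOD)
        self.t_now += self.config.period
        if not np.all(np.isfinite(self.A)) or np.any(self.A <= 0) \
                or np.any(self.Vc <= 0):
            raise StabilityError(
                "integration went unstable (non-physical state); "
                "reduce dt below the CFL bound")
        self._check_cfl()
        return rec

    def _check_cfl(self) -> None:
        x = self.A / self.ca0
        slope = self.cp0 * ((1.0 + self.cb) * (1.0 + self.ck / 3.0)
                            * x ** (self.ck / 3.0) / self.ca0
                            + self.cb * self.ca0 / self.A ** 2)
        c = np.sqrt(np.maximum(self.A * slope, 0.0) / RHO_BLOOD)
        courant = float(np.max(c * self.dt / self.cdx))
        if courant > 0.95:
            raise StabilityError(
                f"CFL number {courant:.2f} exceeds the stability bound; "
                "reduce dt or coarsen dx")


def build_model(config: ScenarioConfig) -> Model:
    """Assemble the closed-loop model for one scenario configuration."""
    tree = reference_tree(delta_k=config.delta_k,
                          p0_art_mmhg=config.p0_art_mmhg,
                          p0_ven_mmhg=config.p0_ven_mmhg,
                          b=config.b,
                          r_systemic=config.r_systemic,
                          bed_tau=config.bed_tau)
    walls = _default_walls(config.v_s_LV)
    return Model(config, tree, walls, Pericardium())


# ---------------------------------------------------------------------------
# valve characteristic (python mirror of the kernel, for unit tests)
# ---------------------------------------------------------------------------

def valve_flow(dp: float, open_fraction: float, q_prev: float = 0.0,
               dt: float = 1.5e-4, a_open: float = 5e-4, a_leak: float = 1e-8,
               l_eff: float = 0.012, rho: float = RHO_BLOOD) -> float:
    """One semi-implicit update of the inertial Bernoulli valve flow.

    The valve is a pressure-gated orifice: effective area
    a_leak + open_fraction * a_open, blood inertance rho*l_eff/area and a
    Bernoulli resistance rho/(2 area^2) * |q| q.  Iterating to equilibrium at
    constant dp yields q = sign(dp) * area * sqrt(2 |dp| / rho).
    """
    av = a_leak + open_fraction * a_open
    lin = rho * l_eff / av
    bern = rho / (2.0 * av * av)
    return (q_prev + dt * dp / lin) / (1.0 + dt * bern * abs(q_prev) / lin)


# ---------------------------------------------------------------------------
# homeostatic control and steady state
# ---------------------------------------------------------------------------

def homeostatic_update(model: Model, measured_map: float,
                       measured_co: float) -> None:
    """Damped proportional control toward the MAP and CO targets.

    Systemic bed (core) resistance is scaled toward the target resistance
    MAP_t / CO_t implied by the measurements; circulating volume is adjusted
    through a constant infusion/withdrawal flow proportional to the cardiac
    output error, applied over the next beat.
    """
    cfg = model.config
    ratio = (measured_map / measured_co) / (cfg.map_target / cfg.co_target)
    model.resistance_scale *= float(np.clip(ratio, 0.5, 2.0)) ** (-cfg.gain_resistance)
    model.resistance_scale = float(np.clip(model.resistance_scale, 0.15, 8.0))
    err_co = cfg.co_target - measured_co
    err_map = (cfg.map_target - measured_map) / cfg.map_target * cfg.co_target
    model.q_inj = float(np.clip(cfg.gain_volume * (err_co + 0.5 * err_map),
                                -4e-5, 4e-5))


def simulate_scenario(config: ScenarioConfig,
                      keep_history: bool = False) -> SimulationResult:
    """Run one scenario to steady state and return the final analysis beat.

    Beats are integrated with the homeostatic controller active until the
    mean arterial pressure and cardiac output are within tolerance of their
    targets and the aortic pressure trace is beat-to-beat periodic, sustained
    for ``settle_beats`` consecutive beats; controls are then frozen (no
    volume infusion) and one further beat is recorded for analysis, so the
    analysis beat conserves blood volume exactly.
    """
    model = build_model(config)
    cfg = config
    prev_pao = None
    prev_map = None
    ok_streak = 0
    history = []
    converged = False
    n_beats = 0
    for beat in range(cfg.max_beats):
        rec = model.run_beat()
        n_beats += 1
        pao = rec[REC_CHANNELS.index("p_ao")]
        qav = rec[REC_CHANNELS.index("q_av")]
        m_map = float(np.mean(pao))
        m_co = float(np.mean(qav))
        pp = float(np.ptp(pao))
        if prev_pao is not None and pp > 0:
            rms = float(np.sqrt(np.mean((pao - prev_pao) ** 2))) / pp
        else:
            rms = np.inf
        history.append((beat, m_map / MMHG, m_co / LMIN,
                        model.resistance_scale, model.q_inj, rms))
        target_ok = (abs(m_map - cfg.map_target) <= cfg.target_rtol * cfg.map_target
                     and abs(m_co - cfg.co_target) <= cfg.target_rtol * cfg.co_target)
        # stationarity: beat-to-beat MAP drift and residual volume control
        # must both be negligible, so freezing the controller for the
        # analysis beat does not perturb the steady state
        drift_ok = (prev_map is not None
                    and abs(m_map - prev_map) <= 4e-4 * cfg.map_target
                    and abs(model.q_inj) <= 0.005 * cfg.co_target)
        ok_streak = ok_streak + 1 if (target_ok and drift_ok
                                      and rms <= cfg.periodic_rtol) else 0
        prev_pao = pao.copy()
        prev_map = m_map
        if ok_streak >= cfg.settle_beats:
            converged = True
            break
        homeostatic_update(model, m_map, m_co)
    # final analysis beat with frozen controls
    model.q_inj = 0.0
    rec = model.run_beat()
    n_beats += 1
    df = pd.DataFrame({
        "time_s": rec[0] - rec[0, 0],
        "p_ao_mmHg": rec[1] / MMHG,
        "U_ao_m_s": rec[2],
        "q_av_m3_s": rec[3],
        "p_lv_mmHg": rec[4] / MMHG,
        "v_lv_ml": rec[5] / ML,
        "strain_lv": rec[6],
        "p_car_mmHg": rec[7] / MMHG,
        "p_fem_mmHg": rec[8] / MMHG,
        "v_total_ml": rec[9] / ML,
        "p_ra_mmHg": rec[10] / MMHG,
        "p_pa_mmHg": rec[11] / MMHG,
    })
    hist = pd.DataFrame(history, columns=["beat", "map_mmHg", "co_lmin",
                                          "r_scale", "q_inj", "rms"])
    return SimulationResult(
        waveforms=df,
        dt=model.rec_dt,
        converged=converged,
        achieved_map_mmhg=float(np.mean(rec[1])) / MMHG,
        achieved_co_lmin=float(np.mean(rec[3])) / LMIN,
        n_beats=n_beats,
        config=config,
        path_difference=model.tree.path_difference,
        beat_history=hist if keep_history else None,
        aortic_root_area=float(np.mean(model.A[model.ao_root])),
        model=model,
    )
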