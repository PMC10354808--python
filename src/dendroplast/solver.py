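"""Compartmental cable solver.

A morphology is discretized into one compartment per electrical segment plus
two per spine (neck, head). Voltages advance by a backward-Euler solve of
the tree-structured linear system using Hines elimination (children are
eliminated into their parents, linear cost, exact for trees). Synaptic and
channel conductances are evaluated at the step midpoint, which gives close
to second-order accuracy in dt for the recorded traces while keeping the
L-stable implicit voltage update.

Internal unit contract: mV, ms, nA, uS, nF, um, mM. With these choices
uS * mV = nA and nF * mV / ms = nA, so no stray conversion factors appear in
the stepping kernel. Conversions from the morphology units (Ohm*cm,
KOhm*cm^2, uF/cm^2) happen once, at graph construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import channels as ch
from .morphology import Morphology, SpineGeometry, spine_neck_resistance

try:  # numba accelerates the stepping kernel ~100x; pure python fallback works
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


__all__ = [
    "CompartmentGraph",
    "SimulationResult",
    "discretize",
    "simulate",
    "steady_state_profile",
    "transfer_resistance_matrix",
    "input_resistances",
]


@dataclass
class CompartmentGraph:
    """Discretized electrical system on a tree.

    ``parent[i] < i`` for all non-root compartments, so a single sweep in
    index order performs the tree-ordered elimination. ``g_axial[i]`` is the
    axial conductance (uS) of the edge joining compartment ``i`` to its
    parent; ``g_axial[0]`` is unused.
    """

    parent: np.ndarray  # int32, -1 at root
    g_axial: np.ndarray  # uS
    cap: np.ndarray  # nF
    g_leak: np.ndarray  # uS
    e_leak: np.ndarray  # mV
    area: np.ndarray  # um^2
    names: list[str]
    morph: Morphology
    # spine bookkeeping (aligned with morph.spines)
    spine_neck: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    spine_head: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    vgcc_gbar: np.ndarray = field(default_factory=lambda: np.empty(0))  # uS
    ca_volume: np.ndarray = field(default_factory=lambda: np.empty(0))  # um^3
    syn_onset: np.ndarray = field(default_factory=lambda: np.empty(0))  # ms, inf=never
    g_ampa: np.ndarray = field(default_factory=lambda: np.empty(0))  # uS
    ih_gbar: np.ndarray = field(default_factory=lambda: np.empty(0))  # uS per comp
    _seg_start: dict = field(default_factory=dict)  # section -> first comp index

    @property
    def n_comp(self) -> int:
        return self.parent.size

    @property
    def n_spines(self) -> int:
        return self.spine_head.size

    def comp_at(self, section: str, position: float) -> int:
        """Compartment index of the segment containing ``position`` of a section."""
        if section == self.morph.soma.name:
            return 0
        sec = self.morph.section(section)
        start = self._seg_start[section]
        k = min(int(position * sec.nseg), sec.nseg - 1)
        return start + k

    def index(self, name: str) -> int:
        return self.names.index(name)

    def total_area(self) -> float:
        """Summed shaft membrane area (um^2), spine compartments excluded."""
        spine_comps = set(self.spine_neck.tolist()) | set(self.spine_head.tolist())
        return float(sum(a for i, a in enumerate(self.area)
                         if i not in spine_comps))


def _axial_half_res_MOhm(diameter: float, half_len: float, Ra: float) -> float:
    """Axial resistance (MOhm) of a half-segment cylinder."""
    return 4.0 * Ra * half_len * 1e-4 / (math.pi * (diameter * 1e-4) ** 2) / 1e6


def discretize(
    morph: Morphology,
    ampa: ch.AMPAKinetics | None = None,
    vgcc: ch.VGCCKinetics | None = None,
    ih: ch.IhParams | None = None,
) -> CompartmentGraph:
    """Build the compartmental system for a morphology.

    Axial conductance between adjacent shaft compartments is the series sum
    of the two half-segment resistances. A spine's neck splits its fitted
    axial resistance into two equal halves (shaft->neck and neck->head), so
    the head-to-shaft resistance equals :func:`spine_neck_resistance`
    exactly; the spherical head itself is treated as isopotential.
    """
    ampa = ampa or ch.AMPAKinetics()
    vgcc = vgcc or ch.VGCCKinetics()
    ih = ih or ch.IhParams()
    p = morph.passive

    names: list[str] = []
    parent_idx: list[int] = []
    g_ax: list[float] = []
    cap: list[float] = []
    g_leak: list[float] = []
    area: list[float] = []
    seg_start: dict[str, int] = {}
    half_res: list[float] = []  # MOhm, half-segment resistance of each comp

    def add_comp(name, par, r_edge_MOhm, area_um2, Rm_K, Cm_uF, half_r):
        names.append(name)
        parent_idx.append(par)
        g_ax.append(0.0 if par < 0 else 1.0 / max(r_edge_MOhm, 1e-12))
        area.append(area_um2)
        g_leak.append(area_um2 / Rm_K * 1e-5)  # uS
        cap.append(Cm_uF * area_um2 * 1e-5)  # nF
        half_res.append(half_r)
        return len(names) - 1

    soma = morph.soma
    soma_half = _axial_half_res_MOhm(soma.diameter, soma.length / 2.0, p.Ra)
    add_comp("soma", -1, 0.0, soma.area, p.soma_Rm, p.soma_Cm, soma_half)

    # sections in declaration order; parents always precede children because
    # Morphology validation guarantees a rooted tree and builders emit
    # parents first.
    for sec in morph.sections:
        dx = sec.length / sec.nseg
        half = _axial_half_res_MOhm(sec.diameter, dx / 2.0, p.Ra)
        r_per_um = _axial_half_res_MOhm(sec.diameter, 1.0, p.Ra)
        seg_start[sec.name] = len(names)
        for k in range(sec.nseg):
            name = f"{sec.name}[{k}]"
            if k == 0:
                if sec.parent == soma.name:
                    par = 0
                    r_edge = half + half_res[0]
                else:
                    pstart = seg_start[sec.parent]
                    psec = morph.section(sec.parent)
                    pdx = psec.length / psec.nseg
                    pk = min(int(sec.parent_position * psec.nseg), psec.nseg - 1)
                    par = pstart + pk
                    # distance from parent's segment center to attachment point
                    resid = abs(sec.parent_position * psec.length - (pk + 0.5) * pdx)
                    pr = _axial_half_res_MOhm(psec.diameter, resid, p.Ra)
                    r_edge = half + pr
            else:
                par = len(names) - 1
                r_edge = 2.0 * half
            add_comp(name, par, r_edge, math.pi * sec.diameter * dx,
                     p.Rm_eff, p.Cm_eff, half)

    graph = CompartmentGraph(
        parent=np.array(parent_idx, dtype=np.int32),
        g_axial=np.array(g_ax),
        cap=np.array(cap),
        g_leak=np.array(g_leak),
        e_leak=np.full(len(names), p.Epas),
        area=np.array(area),
        names=names,
        morph=morph,
        _seg_start=seg_start,
    )

    # spines
    neck_i, head_i, gvgcc, vol, onset, gampa = [], [], [], [], [], []
    for si, sp in enumerate(morph.spines):
        geom: SpineGeometry = sp.geometry
        shaft = graph.comp_at(sp.section, sp.position)
        r_neck = spine_neck_resistance(geom, p.Ra)
        ni = add_comp(f"spine{si}_neck", shaft, r_neck / 2.0,
                      geom.neck_area, geom.spine_Rm, geom.spine_Cm, 0.0)
        hi = add_comp(f"spine{si}_head", ni, r_neck / 2.0,
                      geom.head_area, geom.spine_Rm, geom.spine_Cm, 0.0)
        neck_i.append(ni)
        head_i.append(hi)
        gvgcc.append(ch.vgcc_conductance_total(geom, vgcc) * 1e-3)  # nS -> uS
        vol.append(geom.head_volume)
        onset.append(np.inf if (not sp.has_synapse or sp.onset is None)
                     else sp.onset)
        gampa.append(ampa.g_max * 1e-3)  # nS -> uS

    graph.parent = np.array(parent_idx, dtype=np.int32)
    graph.g_axial = np.array(g_ax)
    graph.cap = np.array(cap)
    graph.g_leak = np.array(g_leak)
    graph.e_leak = np.full(len(names), p.Epas)
    graph.area = np.array(area)
    graph.spine_neck = np.array(neck_i, dtype=np.int32)
    graph.spine_head = np.array(head_i, dtype=np.int32)
    graph.vgcc_gbar = np.array(gvgcc)
    graph.ca_volume = np.array(vol)
    graph.syn_onset = np.array(onset)
    graph.g_ampa = np.array(gampa)
    graph.ih_gbar = graph.area * ih.density * 1e-6  # pS/um^2 * um^2 -> uS
    if ih.density == 0.0:
        graph.ih_gbar = np.zeros(len(names))
    return graph


# ---------------------------------------------------------------------------
# stepping kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def _hines(d, g_ax, parent, b):
    """Solve the symmetric tree system in place; returns voltages."""
    n = d.size
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = g_ax[i] / d[i]
        d[p] -= g_ax[i] * f
        b[p] += b[i] * f
    v = np.empty(n)
    v[0] = b[0] / d[0]
    for i in range(1, n):
        v[i] = (b[i] + g_ax[i] * v[parent[i]]) / d[i]
    return v


@njit(cache=False)
def _run_kernel(
    dt, nsteps, rec_every,
    parent, g_ax, cap, g_leak, e_leak, i_inj,
    head, gvgcc, onset, g_ampa, g_nmda_max,
    a_tr, a_td, a_norm, e_ampa,
    n_tr, n_td, n_norm, e_nmda,
    mg_ratio, mg_gamma,
    vhm, km, vhh, kh, mtau, htau, eca_coef, cao,
    pf_nmda, ca_gamma, tau_ca, min_ca, tau_eff, volume,
    theta_d, theta_p, gamma_d, gamma_p, rho_star, tau_ind_ms, rho0,
    ih_gbar, e_ih, use_ih,
    v_init,
):
    n = parent.size
    ns = head.size
    v = v_init.copy()
    m = np.empty(ns)
    h = np.empty(ns)
    for s in range(ns):
        vh = v[head[s]]
        m[s] = 1.0 / (1.0 + math.exp((vhm - vh) / km))
        h[s] = 1.0 / (1.0 + math.exp((vhh - vh) / kh))
    cai = np.full(ns, min_ca)
    eff = np.zeros(ns)
    rho = rho0.copy()
    mih = np.zeros(n)
    if use_ih:
        for i in range(n):
            x = v[i] + 154.9
            if abs(x) < 1e-6:
                x = 1e-6
            a = 0.001 * 6.43 * x / (math.exp(x / 11.9) - 1.0)
            bb = 0.001 * 193.0 * math.exp(v[i] / 33.1)
            mih[i] = a / (a + bb)

    nrec = nsteps // rec_every + 1
    t_rec = np.empty(nrec)
    v_rec = np.empty((nrec, n))
    inm_rec = np.zeros((nrec, ns))
    ivg_rec = np.zeros((nrec, ns))
    cai_rec = np.empty((nrec, ns))
    eff_rec = np.empty((nrec, ns))
    rho_rec = np.empty((nrec, ns))
    t_rec[0] = 0.0
    v_rec[0] = v
    cai_rec[0] = cai
    eff_rec[0] = eff
    rho_rec[0] = rho
    ri = 1

    em = math.exp(-dt / mtau)
    eh = math.exp(-dt / htau)
    eca_pool = math.exp(-dt / tau_ca)
    eeff = math.exp(-dt / tau_eff)
    # Crank-Nicolson via half-step backward Euler + extrapolation
    inv_cap_dt = cap / (0.5 * dt)

    ica_nmda = np.zeros(ns)
    ica_vgcc = np.zeros(ns)
    g_nmda_open = np.zeros(ns)

    for step in range(nsteps):
        t_mid = step * dt + 0.5 * dt

        d = inv_cap_dt + g_leak
        b = inv_cap_dt * v + g_leak * e_leak + i_inj

        # axial diagonal terms; the off-diagonals live in g_ax and are
        # consumed directly by the Hines elimination
        for i in range(1, n):
            d[i] += g_ax[i]
            d[parent[i]] += g_ax[i]

        if use_ih:
            for i in range(n):
                x = v[i] + 154.9
                if abs(x) < 1e-6:
                    x = 1e-6
                a = 0.001 * 6.43 * x / (math.exp(x / 11.9) - 1.0)
                bb = 0.001 * 193.0 * math.exp(v[i] / 33.1)
                tau = 1.0 / (a + bb)
                minf = a * tau
                mih[i] = minf + (mih[i] - minf) * math.exp(-dt / tau)
                gi = ih_gbar[i] * mih[i]
                d[i] += gi
                b[i] += gi * e_ih

        for s in range(ns):
            hd = head[s]
            vh = v[hd]
            # VGCC gates relax toward steady state at the pre-step voltage
            minf = 1.0 / (1.0 + math.exp((vhm - vh) / km))
            hinf = 1.0 / (1.0 + math.exp((vhh - vh) / kh))
            m[s] = minf + (m[s] - minf) * em
            h[s] = hinf + (h[s] - hinf) * eh
            gca = gvgcc[s] * m[s] * m[s] * h[s]
            ca_i = cai[s]
            if ca_i < 1e-12:
                ca_i = 1e-12
            eca = eca_coef * math.log(cao / ca_i)
            d[hd] += gca
            b[hd] += gca * eca

            te = t_mid - onset[s]
            g_nmda_open[s] = 0.0
            if te > 0.0:
                gA = g_ampa[s] * a_norm * (math.exp(-te / a_td)
                                           - math.exp(-te / a_tr))
                g_nmda_open[s] = g_nmda_max * n_norm * (
                    math.exp(-te / n_td) - math.exp(-te / n_tr))
                d[hd] += gA
                b[hd] += gA * e_ampa
            ica_vgcc[s] = gca

        # two-pass fixed point on the voltage-dependent Mg block: predictor
        # uses the pre-step voltage, corrector re-solves with the block at
        # the midstep voltage from the predictor (second order through the
        # regenerative plateau edges)
        any_nmda = False
        for s in range(ns):
            if g_nmda_open[s] > 0.0:
                any_nmda = True
                break
        if any_nmda:
            d_base = d.copy()
            b_base = b.copy()
            for s in range(ns):
                if g_nmda_open[s] > 0.0:
                    hd = head[s]
                    mgb = 1.0 / (1.0 + mg_ratio
                                 * math.exp(-mg_gamma * v[hd]))
                    g = g_nmda_open[s] * mgb
                    d[hd] += g
                    b[hd] += g * e_nmda
            v_pred = _hines(d, g_ax, parent, b)
            d = d_base
            b = b_base
            for s in range(ns):
                g_eff = 0.0
                if g_nmda_open[s] > 0.0:
                    hd = head[s]
                    mgb = 1.0 / (1.0 + mg_ratio
                                 * math.exp(-mg_gamma * v_pred[hd]))
                    g_eff = g_nmda_open[s] * mgb
                    d[hd] += g_eff
                    b[hd] += g_eff * e_nmda
                ica_nmda[s] = g_eff
            v_half = _hines(d, g_ax, parent, b)
        else:
            for s in range(ns):
                ica_nmda[s] = 0.0
            v_half = _hines(d, g_ax, parent, b)
        v = 2.0 * v_half - v

        for s in range(ns):
            hd = head[s]
            vh = v[hd]
            ca_i = cai[s]
            if ca_i < 1e-12:
                ca_i = 1e-12
            eca = eca_coef * math.log(cao / ca_i)
            i_nm = pf_nmda * ica_nmda[s] * (vh - 40.0)
            i_vg = ica_vgcc[s] * (vh - eca)
            ica_nmda[s] = i_nm
            ica_vgcc[s] = i_vg
            influx = -(i_nm + i_vg) * 1e-9 * ca_gamma / (
                1e-15 * volume[s] * 2.0 * 96485.332)
            if influx < 0.0:
                influx = 0.0
            target = min_ca + influx * tau_ca
            cai[s] = target + (cai[s] - target) * eca_pool
            drive = cai[s] - min_ca
            eff_target = drive * tau_eff
            eff[s] = eff_target + (eff[s] - eff_target) * eeff
            if eff[s] < 0.0:
                eff[s] = 0.0
            dep = 1.0 if eff[s] >= theta_d else 0.0
            pot = 1.0 if eff[s] >= theta_p else 0.0
            r = rho[s]
            drho = (-r * (1.0 - r) * (rho_star - r)
                    + pot * gamma_p * (1.0 - r)
                    - dep * gamma_d * r) / tau_ind_ms
            r += dt * drho
            if r < 0.0:
                r = 0.0
            elif r > 1.0:
                r = 1.0
            rho[s] = r

        if (step + 1) % rec_every == 0:
            t_rec[ri] = (step + 1) * dt
            v_rec[ri] = v
            inm_rec[ri] = ica_nmda
            ivg_rec[ri] = ica_vgcc
            cai_rec[ri] = cai
            eff_rec[ri] = eff
            rho_rec[ri] = rho
            ri += 1

    return t_rec, v_rec, inm_rec, ivg_rec, cai_rec, eff_rec, rho_rec


@dataclass
class SimulationResult:
    """Recorded traces on a uniform time base.

    All compartment voltages and all per-spine quantities are recorded, so
    any probe is a view. ``meta`` carries the resolved configuration.
    """

    t: np.ndarray  # ms
    v: np.ndarray  # [nt, n_comp] mV
    ica_nmda: np.ndarray  # [nt, n_spines] nA
    ica_vgcc: np.ndarray  # [nt, n_spines] nA
    cai: np.ndarray  # [nt, n_spines] mM
    eff_ca: np.ndarray  # [nt, n_spines] A.U.
    rho: np.ndarray  # [nt, n_spines]
    graph: CompartmentGraph
    meta: dict = field(default_factory=dict)

    def v_at(self, name: str) -> np.ndarray:
        return self.v[:, self.graph.index(name)]

    def v_spine_head(self, spine_index: int) -> np.ndarray:
        return self.v[:, self.graph.spine_head[spine_index]]

    def peak_eff_ca(self) -> np.ndarray:
        """Peak effective calcium per spine over the whole trace (A.U.)."""
        if self.eff_ca.size == 0:
            return np.zeros(self.graph.n_spines)
        return self.eff_ca.max(axis=0)


def simulate(
    graph: CompartmentGraph,
    tstop: float,
    dt: float = 0.0125,
    *,
    nmda: ch.NMDAKinetics | None = None,
    ampa: ch.AMPAKinetics | None = None,
    vgcc: ch.VGCCKinetics | None = None,
    pool: ch.CalciumPool | None = None,
    plasticity=None,
    ih: ch.IhParams | None = None,
    i_inj: np.ndarray | None = None,
    rho0: np.ndarray | None = None,
    rec_dt: float = 0.1,
    settle: float | None = None,
    meta: dict | None = None,
) -> SimulationResult:
    """Integrate the graph from rest for ``tstop`` ms.

    Deterministic: identical inputs give bitwise identical traces. With Ih
    enabled, a 200 ms settling run precedes t=0 so recordings start from the
    shifted resting state.
    """
    from .plasticity import PlasticityParams

    if dt <= 0:
        raise ValueError("dt must be positive")
    nmda = nmda or ch.NMDAKinetics()
    ampa = ampa or ch.AMPAKinetics()
    vgcc = vgcc or ch.VGCCKinetics()
    pool = pool or ch.CalciumPool()
    plast = plasticity or PlasticityParams()
    ih = ih or ch.IhParams()
    use_ih = bool(np.any(graph.ih_gbar > 0))
    if settle is None:
        settle = 200.0 if use_ih else 0.0

    nsteps = int(round(tstop / dt))
    rec_every = max(int(round(rec_dt / dt)), 1)
    n = graph.n_comp
    ns = graph.n_spines
    if i_inj is None:
        i_inj = np.zeros(n)
    v0 = np.full(n, graph.morph.passive.Epas)
    rho_init = (np.full(ns, plast.rho_init) if rho0 is None
                else np.asarray(rho0, dtype=float))

    eca_coef = (ch.GAS_CONSTANT * (vgcc.celsius + 273.15)
                / (2.0 * ch.FARADAY) * 1e3)
    a_norm = ch._dual_exp_norm(ampa.tau_rise, ampa.tau_decay)
    n_norm = ch._dual_exp_norm(nmda.tau_rise, nmda.tau_decay)

    def kernel_args(onset, nsteps_, rec_every_, v_start):
        return (
            dt, nsteps_, rec_every_,
            graph.parent, graph.g_axial, graph.cap,
            graph.g_leak, graph.e_leak, i_inj,
            graph.spine_head, graph.vgcc_gbar, onset,
            graph.g_ampa, nmda.g_max * 1e-3,
            ampa.tau_rise, ampa.tau_decay, a_norm, ampa.E_rev,
            nmda.tau_rise, nmda.tau_decay, n_norm, nmda.E_rev,
            nmda.mg_conc / nmda.mg_K0, nmda.mg_gamma,
            vgcc.vhm, vgcc.km, vgcc.vhh, vgcc.kh,
            vgcc.mtau, vgcc.htau, eca_coef, vgcc.cao,
            nmda.ca_fraction, pool.gamma, pool.tau_ca,
            pool.min_ca, pool.tau_eff, graph.ca_volume,
            plast.theta_D, plast.theta_P, plast.gamma_d, plast.gamma_p,
            plast.rho_star, plast.tau_rho, rho_init,
            graph.ih_gbar, ih.E_rev, use_ih, v_start,
        )

    if settle > 0:
        # advance to the resting state with all stimuli out of reach
        n_settle = int(round(settle / dt))
        far = np.full(ns, np.inf)
        out = _run_kernel(*kernel_args(far, n_settle, max(n_settle, 1), v0))
        v0 = out[1][-1].copy()

    out = _run_kernel(*kernel_args(graph.syn_onset, nsteps, rec_every, v0))

    t_rec, v_rec, inm, ivg, cai, eff, rho = out
    md = {"dt": dt, "tstop": tstop, "rec_dt": rec_dt, "settle": settle,
          "n_comp": n, "n_spines": ns}
    if meta:
        md.update(meta)
    res = SimulationResult(t=t_rec, v=v_rec, ica_nmda=inm, ica_vgcc=ivg,
                           cai=cai, eff_ca=eff, rho=rho, graph=graph, meta=md)
    vmax, vmin = float(res.v.max()), float(res.v.min())
    if not np.isfinite(res.v).all() or vmin < -100.0 or vmax > 60.0:
        raise RuntimeError(
            f"voltage left the sanity band [-100, 60] mV: [{vmin:.1f}, {vmax:.1f}]")
    return res


# ---------------------------------------------------------------------------
# steady-state / passive analysis
# ---------------------------------------------------------------------------


def _conductance_matrix(graph: CompartmentGraph) -> np.ndarray:
    """Dense passive conductance matrix (uS): leak + axial Laplacian."""
    n = graph.n_comp
    G = np.diag(graph.g_leak.astype(float))
    for i in range(1, n):
        p = graph.parent[i]
        g = graph.g_axial[i]
        G[i, i] += g
        G[p, p] += g
        G[i, p] -= g
        G[p, i] -= g
    return G


def steady_state_profile(graph: CompartmentGraph, inject: int | str,
                         I: float = 1.0) -> np.ndarray:
    """Steady-state voltage deflection (mV) per compartment for a constant
    current ``I`` (nA) injected at one site, passive membrane only."""
    if isinstance(inject, str):
        inject = graph.index(inject)
    G = _conductance_matrix(graph)
    if not np.any(np.abs(G) > 0):
        raise np.linalg.LinAlgError("singular system: all conductances zero")
    rhs = np.zeros(graph.n_comp)
    rhs[inject] = I
    return np.linalg.solve(G, rhs)


def transfer_resistance_matrix(graph: CompartmentGraph) -> np.ndarray:
    """K[i, j] = steady voltage at j per unit current at i, in MOhm.

    Symmetric for any passive tree (reciprocity); the diagonal holds input
    resistances.
    """
    G = _conductance_matrix(graph)
    return np.linalg.inv(G)


def input_resistances(graph: CompartmentGraph) -> np.ndarray:
    """Per-compartment input resistance (MOhm)."""
    return np.diag(transfer_resistance_matrix(graph)).copy()
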