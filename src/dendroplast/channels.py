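"""Membrane and synaptic mechanisms.

The synapse is a glutamatergic spine synapse with AMPA and NMDA receptor
conductances (dual-exponential waveforms, voltage-dependent Mg2+ block on
the NMDA component), an R-type voltage-gated calcium channel (VGCC)
population on every spine head, and an effective-calcium accumulator that
drives the bistable plasticity rule. Kinetic constants follow the published
Blue Brain glutamatergic synapse mechanism with four modifications: neutral
initial AMPA conductance of 1.5 nS, NMDA gmax of 1.31 nS, VGCC unitary
conductance of 20 pS at 20 channels/um^2, and spine geometry taken from the
explicit neck + spherical-head model.

Calcium bookkeeping: the NMDA calcium current is a fixed fraction of the
NMDA conductance driven toward +40 mV (a GHK-motivated approximation); it
feeds the calcium pool only, since the electrical NMDA current already flows
through its own reversal potential. The VGCC calcium current is a real
membrane current, ohmic toward the Nernst calcium potential.

Units: mV, ms, nA, uS (so uS * mV = nA), um, mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphology import SpineGeometry

__all__ = [
    "AMPAKinetics",
    "NMDAKinetics",
    "VGCCKinetics",
    "CalciumPool",
    "IhParams",
    "FARADAY",
    "mg_block",
    "dual_exp_conductance",
    "dual_exp_peak_time",
    "vgcc_minf",
    "vgcc_hinf",
    "vgcc_step",
    "vgcc_conductance_total",
    "nernst_ca",
    "nmda_ca_fraction",
    "calcium_step",
    "ih_gate_inf",
    "ih_gate_tau",
    "ih_current",
]

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.3144626  # J/(mol*K)


@dataclass(frozen=True)
class AMPAKinetics:
    """AMPA receptor: fast dual-exponential conductance."""

    g_max: float = 1.5  # nS; plastic between 1 (DOWN) and 2 (UP)
    tau_rise: float = 0.2  # ms
    tau_decay: float = 1.7  # ms
    E_rev: float = 0.0  # mV

    def __post_init__(self):
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")


@dataclass(frozen=True)
class NMDAKinetics:
    """NMDA receptor: slow dual-exponential conductance with Mg2+ block.

    The block follows 1 / (1 + (mg/K0) * exp(-gamma*v)). ``ca_fraction`` is
    the fraction of the open-channel conductance treated as calcium current
    toward ``E_ca_nmda``.
    """

    g_max: float = 1.31  # nS
    tau_rise: float = 0.29  # ms
    tau_decay: float = 43.0  # ms
    E_rev: float = -3.0  # mV
    mg_conc: float = 1.0  # mM
    mg_K0: float = 2.552  # mM
    mg_gamma: float = 0.072  # 1/mV
    E_ca_nmda: float = 40.0  # mV
    cao: float = 2.0  # mM

    def __post_init__(self):
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")

    @property
    def ca_fraction(self) -> float:
        return nmda_ca_fraction(self.cao)


def nmda_ca_fraction(cao: float = 2.0) -> float:
    """Fraction of NMDA conductance carrying Ca2+, Pf = 4*cao/(4*cao + 120/1.38) * 0.6.

    GHK-derived permeability-ratio approximation used by the synapse
    mechanism; ~0.0505 at cao = 2 mM.
    """
    return (4.0 * cao) / (4.0 * cao + 120.0 / 1.38) * 0.6


@dataclass(frozen=True)
class VGCCKinetics:
    """R-type high-voltage-activated calcium channel, gates m^2 * h.

    Boltzmann steady states with fixed time constants; the per-spine maximal
    conductance is ``unitary_g * density * head sphere area``. The driving
    force is ohmic toward the Nernst calcium potential computed from the
    instantaneous pool concentration.
    """

    unitary_g: float = 20.0  # pS per channel
    density: float = 20.0  # channels/um^2
    vhm: float = -5.9  # mV, activation half-voltage
    km: float = 9.5  # mV, activation slope
    vhh: float = -39.0  # mV, inactivation half-voltage
    kh: float = -9.2  # mV, inactivation slope (negative: closes with depolarization)
    mtau: float = 1.0  # ms
    htau: float = 27.0  # ms
    cao: float = 2.0  # mM
    celsius: float = 34.0


def mg_block(v: float | np.ndarray, kin: NMDAKinetics) -> float | np.ndarray:
    """Fraction of NMDA conductance unblocked by Mg2+ at voltage ``v`` (mV).

    Strictly increasing in v; tends to 1 as v -> +inf.
    """
    return 1.0 / (1.0 + (kin.mg_conc / kin.mg_K0) * np.exp(-kin.mg_gamma * v))


def _dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    tp = dual_exp_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def dual_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the dual-exponential maximum: tr*td/(td-tr) * ln(td/tr)."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError("require 0 < tau_rise < tau_decay")
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * math.log(tau_decay / tau_rise))


def dual_exp_conductance(t_since_onset, kin) -> float | np.ndarray:
    """Dual-exponential conductance (nS), peak-normalized to ``kin.g_max``."""
    if kin.tau_rise >= kin.tau_decay:
        raise ValueError("require tau_rise < tau_decay")
    t = np.asarray(t_since_onset, dtype=float)
    n = _dual_exp_norm(kin.tau_rise, kin.tau_decay)
    g = kin.g_max * n * (np.exp(-t / kin.tau_decay) - np.exp(-t / kin.tau_rise))
    g = np.where(t < 0, 0.0, g)
    return float(g) if np.isscalar(t_since_onset) else g


def vgcc_minf(v, kin: VGCCKinetics):
    """Activation steady state, Boltzmann midpoint at ``kin.vhm``."""
    return 1.0 / (1.0 + np.exp((kin.vhm - v) / kin.km))


def vgcc_hinf(v, kin: VGCCKinetics):
    """Inactivation steady state (decreasing in v since kh < 0)."""
    return 1.0 / (1.0 + np.exp((kin.vhh - v) / kin.kh))


def vgcc_step(gates: tuple[float, float], v: float, dt: float,
              kin: VGCCKinetics) -> tuple[float, float]:
    """Advance (m, h) one step by exponential relaxation to steady state.

    The exponential-Euler update keeps gates in [0, 1] for any dt.
    """
    m, h = gates
    em = math.exp(-dt / kin.mtau)
    eh = math.exp(-dt / kin.htau)
    minf = float(vgcc_minf(v, kin))
    hinf = float(vgcc_hinf(v, kin))
    return (minf + (m - minf) * em, hinf + (h - hinf) * eh)


def vgcc_conductance_total(geom: SpineGeometry, kin: VGCCKinetics) -> float:
    """Open-channel maximal VGCC conductance per spine head in nS.

    unitary_g [pS] * density [/um^2] * pi*d^2 [um^2]; scaled by m^2*h at
    run time.
    """
    return kin.unitary_g * kin.density * geom.head_area * 1e-3


def nernst_ca(cai: float, cao: float = 2.0, celsius: float = 34.0) -> float:
    """Calcium Nernst potential (mV) for internal ``cai`` (mM)."""
    cai = max(cai, 1e-12)
    return (GAS_CONSTANT * (celsius + 273.15) / (2.0 * FARADAY)
            * math.log(cao / cai) * 1e3)


@dataclass(frozen=True)
class CalciumPool:
    """Spine-head calcium pool and effective-calcium accumulator.

    ``cai`` is a free-calcium concentration (mM) in the head volume; only a
    fraction ``gamma`` of the carried charge stays free. ``eff_ca`` low-pass
    integrates (cai - min_ca) with time constant ``tau_eff``; it is the
    dimensionless "effective [Ca2+]" on the same arbitrary-unit scale as the
    plasticity thresholds theta_D/theta_P.
    """

    cai: float = 70e-6  # mM
    eff_ca: float = 0.0  # A.U.
    gamma: float = 0.04  # free fraction of carried calcium
    tau_ca: float = 12.213  # ms, pool extrusion
    min_ca: float = 70e-6  # mM, resting concentration
    tau_eff: float = 278.318  # ms, effective-calcium decay
    volume: float = math.pi * 0.4**3 / 6.0  # um^3, spherical head


def calcium_step(pool: CalciumPool, I_ca_nmda: float, I_ca_vgcc: float,
                 dt: float) -> CalciumPool:
    """Advance the pool one step given calcium currents in nA (inward < 0).

    dcai/dt = -(I_nmda + I_vgcc) * gamma / (2*F*volume) - (cai - min_ca)/tau_ca
    deff/dt = (cai - min_ca) - eff/tau_eff

    Inward currents are negative, so the influx term is positive; cai never
    falls below min_ca and eff_ca never below 0.
    """
    influx = (-(I_ca_nmda + I_ca_vgcc) * 1e-9 * pool.gamma
              / (1e-15 * pool.volume * 2.0 * FARADAY))  # mM/ms
    influx = max(influx, 0.0)
    # exponential Euler toward the instantaneous fixed point
    target = pool.min_ca + influx * pool.tau_ca
    cai = target + (pool.cai - target) * math.exp(-dt / pool.tau_ca)
    drive = cai - pool.min_ca
    eff_target = drive * pool.tau_eff
    eff = eff_target + (pool.eff_ca - eff_target) * math.exp(-dt / pool.tau_eff)
    return CalciumPool(cai=cai, eff_ca=max(eff, 0.0), gamma=pool.gamma,
                       tau_ca=pool.tau_ca, min_ca=pool.min_ca,
                       tau_eff=pool.tau_eff, volume=pool.volume)


@dataclass(frozen=True)
class IhParams:
    """Hyperpolarization-activated cation current, uniform density."""

    density: float = 0.0  # pS/um^2; 0 disables
    E_rev: float = -45.0  # mV

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("Ih density must be >= 0")


def ih_gate_inf(v):
    """Ih activation steady state (HCN kinetics of the L5PC model)."""
    a = _ih_alpha(v)
    b = _ih_beta(v)
    return a / (a + b)


def ih_gate_tau(v):
    """Ih activation time constant in ms."""
    return 1.0 / (_ih_alpha(v) + _ih_beta(v))


def _ih_alpha(v):
    v = np.asarray(v, dtype=float)
    x = v + 154.9
    x = np.where(np.abs(x) < 1e-6, 1e-6, x)
    return 0.001 * 6.43 * x / (np.exp(x / 11.9) - 1.0)


def _ih_beta(v):
    return 0.001 * 193.0 * np.exp(np.asarray(v, dtype=float) / 33.1)


def ih_current(v: float, density: float, area: float, gate: float | None = None,
               E_rev: float = -45.0) -> float:
    """Ih current in nA for a compartment of ``area`` um^2.

    ``density`` in pS/um^2; if ``gate`` is None the steady-state activation
    at v is used. Zero density gives exactly zero current.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if density == 0.0:
        return 0.0
    m = float(ih_gate_inf(v)) if gate is None else gate
    g_uS = density * area * 1e-6  # pS -> uS
    return g_uS * m * (v - E_rev)
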