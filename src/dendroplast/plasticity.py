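"""Calcium-threshold bistable plasticity.

The synaptic efficacy variable rho follows the Graupner–Brunel bistable
first-order dynamics

    tau_rho * drho/dt = -rho (1 - rho) (rho* - rho)
                        + gamma_p (1 - rho) * [c > theta_P]
                        - gamma_d rho       * [c > theta_D]

where c is the effective spine calcium (arbitrary units). rho = 0 and
rho = 1 are stable fixed points separated by the unstable point rho* = 0.5;
without noise a synapse initialized exactly at rho* stays there until
calcium crosses a threshold. AMPA conductance maps linearly onto rho
between the DOWN (1 nS) and UP (2 nS) states; the neutral initial state is
1.5 nS. theta_P > theta_D throughout (the cortical/hippocampal ordering).

Outcome classification: the default, peak-based rule labels a spine by the
largest effective calcium it reached — N below theta_D, D in
[theta_D, theta_P), P at or above theta_P (threshold comparisons are
inclusive). An alternative rho-based rule integrates the rho dynamics along
the calcium trace and labels by the sign of the net rho change with a small
dead band; it is provided for fidelity to the underlying bistable model.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "PlasticityParams",
    "SynapseWeightState",
    "Outcome",
    "rho_step",
    "gmax_from_rho",
    "classify_outcome",
    "classify_outcome_rho",
    "threshold_sweep",
    "outcome_map",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Thresholds and rate constants of the plasticity rule.

    ``theta_D``/``theta_P`` are on the effective-calcium A.U. scale;
    ``tau_rho`` is the induction time constant in ms (70 s), so rho moves
    only a few percent during a single 300 ms induction event — the label,
    not the magnitude, is the model's output.
    """

    theta_D: float = 0.5  # A.U.
    theta_P: float = 1.0  # A.U.
    gamma_p: float = 216.2
    gamma_d: float = 101.5
    tau_rho: float = 70_000.0  # ms
    rho_star: float = 0.5
    rho_init: float = 0.5
    g_down: float = 1.0  # nS
    g_up: float = 2.0  # nS
    dead_band: float = 1e-4  # |drho| below this counts as no change

    def __post_init__(self):
        if not self.theta_P > self.theta_D:
            raise ValueError("require theta_P > theta_D")
        if not self.g_up > self.g_down:
            raise ValueError("require g_up > g_down")


@dataclass(frozen=True)
class SynapseWeightState:
    rho: float
    g_ampa: float  # nS


class Outcome(str, Enum):
    """Plasticity label; ordered N < D < P by peak calcium."""

    N = "N"
    D = "D"
    P = "P"

    @property
    def rank(self) -> int:
        return {"N": 0, "D": 1, "P": 2}[self.value]


def rho_step(rho: float, c: float, params: PlasticityParams, dt: float) -> float:
    """Advance rho by one explicit-Euler step given effective calcium ``c``."""
    pot = 1.0 if c >= params.theta_P else 0.0
    dep = 1.0 if c >= params.theta_D else 0.0
    drho = (-rho * (1.0 - rho) * (params.rho_star - rho)
            + pot * params.gamma_p * (1.0 - rho)
            - dep * params.gamma_d * rho) / params.tau_rho
    return float(np.clip(rho + dt * drho, 0.0, 1.0))


def gmax_from_rho(rho: float | np.ndarray, params: PlasticityParams):
    """AMPA conductance (nS): linear map g_down + rho * (g_up - g_down)."""
    return params.g_down + np.asarray(rho, dtype=float) * (
        params.g_up - params.g_down)


def classify_outcome(c_trace: np.ndarray, params: PlasticityParams) -> Outcome:
    """Peak-based label of one effective-calcium trace."""
    c = np.asarray(c_trace, dtype=float)
    if c.size == 0:
        raise ValueError("empty calcium trace")
    peak = float(c.max())
    if peak >= params.theta_P:
        return Outcome.P
    if peak >= params.theta_D:
        return Outcome.D
    return Outcome.N


def classify_outcome_rho(c_trace: np.ndarray, params: PlasticityParams,
                         dt: float) -> Outcome:
    """Rho-based label: integrate the bistable dynamics along the trace."""
    c = np.asarray(c_trace, dtype=float)
    if c.size == 0:
        raise ValueError("empty calcium trace")
    rho = params.rho_init
    for ci in c:
        rho = rho_step(rho, ci, params, dt)
    d = rho - params.rho_init
    if d > params.dead_band:
        return Outcome.P
    if d < -params.dead_band:
        return Outcome.D
    return Outcome.N


def threshold_sweep(c_traces: np.ndarray,
                    grid: list[tuple[float, float]],
                    params: PlasticityParams | None = None,
                    ) -> dict[tuple[float, float], list[Outcome]]:
    """Classify cached calcium traces under each (theta_D, theta_P) pair.

    The thresholds do not feed back into the calcium dynamics during the
    induction window, so no re-simulation is needed: the same traces are
    reclassified for every grid point. Pairs with theta_P <= theta_D are
    rejected.
    """
    base = params or PlasticityParams()
    traces = np.atleast_2d(np.asarray(c_traces, dtype=float))
    out: dict[tuple[float, float], list[Outcome]] = {}
    for thd, thp in grid:
        if thp <= thd:
            raise ValueError(f"grid point ({thd}, {thp}) has theta_P <= theta_D")
        p = PlasticityParams(
            theta_D=thd, theta_P=thp, gamma_p=base.gamma_p,
            gamma_d=base.gamma_d, tau_rho=base.tau_rho,
            rho_star=base.rho_star, rho_init=base.rho_init,
            g_down=base.g_down, g_up=base.g_up, dead_band=base.dead_band)
        out[(thd, thp)] = [classify_outcome(tr, p) for tr in traces]
    return out


def outcome_map(result, params: PlasticityParams | None = None,
                rule: str = "peak") -> tuple[list[Outcome], np.ndarray]:
    """Per-spine labels and peak effective calcium for a simulation result.

    ``rule`` selects the peak-based classifier (default) or the rho-based
    one. Raises if the result recorded no spines.
    """
    params = params or PlasticityParams()
    if result.graph.n_spines == 0:
        raise ValueError("result contains no spine calcium probes")
    peaks = result.peak_eff_ca()
    if rule == "peak":
        labels = [classify_outcome(result.eff_ca[:, s], params)
                  for s in range(result.graph.n_spines)]
    elif rule == "rho":
        dt = float(result.t[1] - result.t[0])
        labels = [classify_outcome_rho(result.eff_ca[:, s], params, dt)
                  for s in range(result.graph.n_spines)]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return labels, peaks
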