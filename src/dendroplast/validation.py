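"""Built-in physics validation suite.

Five checks that must hold for any correct configuration of the solver and
plasticity rule, independent of parameter choices:

1. transfer-resistance reciprocity (passive trees are symmetric systems);
2. sealed-cable input resistance against the closed form R_inf*coth(L/lambda);
3. dt-refinement stability of recorded voltage traces;
4. forbidden homo/hetero outcome pairs {DP, NP, ND} never occur when
   theta_P > theta_D;
5. activated spines accumulate at least as much calcium as nonactivated
   spines at every recorded time point.
"""

from __future__ import annotations

import math

import numpy as np

from . import protocols
from .morphology import PassiveParams, SectionSpec, Morphology
from .plasticity import outcome_map
from .solver import discretize, input_resistances, transfer_resistance_matrix

__all__ = ["run_all", "check_reciprocity", "check_cable_closed_form",
           "check_dt_refinement", "check_forbidden_pairs",
           "check_calcium_ordering", "sealed_cable_input_resistance"]


def check_reciprocity(tol: float = 1e-6) -> bool:
    """||K - K^T||_inf < tol * max(K) on both morphology presets."""
    from .morphology import build_ball_and_stick, build_symmetric_tree

    for morph in (build_ball_and_stick(), build_symmetric_tree()):
        K = transfer_resistance_matrix(discretize(morph))
        if np.abs(K - K.T).max() >= tol * K.max():
            return False
    return True


def sealed_cable_input_resistance(length: float, diameter: float,
                                  Rm: float, Ra: float) -> float:
    """Closed-form input resistance (MOhm) of a sealed finite cable,
    R_inf * coth(L / lambda), injected at one sealed end."""
    rm = Rm * 1e3 / (math.pi * diameter * 1e-4)  # Ohm*cm
    ri = 4.0 * Ra / (math.pi * (diameter * 1e-4) ** 2)  # Ohm/cm
    lam = math.sqrt(rm / ri)  # cm
    r_inf = math.sqrt(rm * ri)
    return r_inf / math.tanh(length * 1e-4 / lam) / 1e6


def check_cable_closed_form(tol: float = 0.01) -> bool:
    """Discretized sealed cable (no soma) matches R_inf*coth(L/lambda) to
    better than ``tol`` relative."""
    passive = PassiveParams(spine_compensation=False)
    # a lone cable: root section with a vanishing stub soma would change the
    # boundary condition, so build the tree with a tiny soma of negligible
    # membrane and huge Rm acting as a sealed end.
    soma = SectionSpec("soma", length=1e-3, diameter=0.75, nseg=1)
    dend = SectionSpec("b0", length=200.0, diameter=0.75, nseg=400,
                       parent="soma", parent_position=1.0)
    morph = Morphology(soma=soma, sections=[dend], passive=PassiveParams(
        Rm=44.0, spine_compensation=False, soma_Rm=1e9))
    graph = discretize(morph)
    rn = input_resistances(graph)[graph.comp_at("b0", 0.0)]
    expected = sealed_cable_input_resistance(200.0, 0.75, 44.0, passive.Ra)
    return abs(rn - expected) / expected < tol


def check_dt_refinement(tol_mv: float = 0.1) -> bool:
    """Halving dt changes recorded voltages by < tol on the NMDA-spike preset."""
    spec = protocols.preset_fig2(n=18)
    a = protocols.run_experiment(spec)
    spec2 = protocols.preset_fig2(n=18)
    spec2.dt = spec.dt / 2.0
    b = protocols.run_experiment(spec2)
    return float(np.abs(a.v - b.v).max()) < tol_mv


def _label_pairs(spec) -> set[str]:
    res = protocols.run_experiment(spec)
    labels, _ = outcome_map(res, spec.plasticity)
    homo = [l for sp, l in zip(res.graph.morph.spines, labels)
            if sp.onset is not None]
    hetero = [l for sp, l in zip(res.graph.morph.spines, labels)
              if sp.onset is None]
    if not homo or not hetero:
        return set()
    h = max(homo, key=lambda l: l.rank)  # strongest homosynaptic label
    return {h.value + l.value for l in hetero}


def check_forbidden_pairs() -> bool:
    """(homo, hetero) pairs DP, NP, ND never occur across the preset suite."""
    forbidden = {"DP", "NP", "ND"}
    specs = [protocols.preset_fig3(),
             protocols.preset_fig4(1, 40),
             protocols.preset_fig4(3, 20)]
    for spec in specs:
        if _label_pairs(spec) & forbidden:
            return False
    return True


def check_calcium_ordering() -> bool:
    """min over activated spines of eff_ca >= max over nonactivated spines,
    at every recorded time, on the asymmetric-plasticity preset."""
    spec = protocols.preset_fig3()
    res = protocols.run_experiment(spec)
    act = np.array([sp.onset is not None for sp in res.graph.morph.spines])
    if not act.any() or act.all():
        return True
    lo_act = res.eff_ca[:, act].min(axis=1)
    hi_non = res.eff_ca[:, ~act].max(axis=1)
    # absolute float tolerance on the A.U. scale (thresholds are 0.1-1)
    return bool(np.all(lo_act >= hi_non - 1e-6))


def run_all(echo=print) -> int:
    """Run every check; returns the number of failures."""
    checks = [
        ("transfer-resistance reciprocity", check_reciprocity),
        ("sealed-cable closed form", check_cable_closed_form),
        ("dt-refinement stability", check_dt_refinement),
        ("forbidden outcome pairs", check_forbidden_pairs),
        ("activated >= nonactivated calcium", check_calcium_ordering),
    ]
    failures = 0
    for name, fn in checks:
        ok = fn()
        echo(f"[{'ok' if ok else 'FAIL'}] {name}")
        failures += 0 if ok else 1
    return failures
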