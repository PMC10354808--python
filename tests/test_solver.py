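"""Solver correctness: discretization bookkeeping, analytic oracles for the
passive system, reciprocity, determinism, and dt stability."""

import math

import numpy as np
import pytest
import scipy.linalg

from dendroplast import channels as ch
from dendroplast import morphology as mo
from dendroplast import protocols as pr
from dendroplast import solver as sv
from dendroplast.validation import sealed_cable_input_resistance


def test_compartment_count_with_spine():
    m = mo.build_ball_and_stick()
    m = mo.attach_spine(m, mo.SpineSite("b0", 0.5))
    g = sv.discretize(m)
    assert g.n_comp == 53  # soma + 50 segments + neck + head


def test_neck_resistance_consistency():
    m = mo.attach_spine(mo.build_ball_and_stick(), mo.SpineSite("b0", 0.5))
    g = sv.discretize(m)
    r_graph = 1.0 / g.g_axial[g.spine_neck[0]] + 1.0 / g.g_axial[g.spine_head[0]]
    r_formula = mo.spine_neck_resistance(m.spines[0].geometry, m.passive.Ra)
    assert abs(r_graph - r_formula) / r_formula < 1e-9


def test_refinement_preserves_total_area():
    a = sv.discretize(mo.build_ball_and_stick(nseg=25)).total_area()
    b = sv.discretize(mo.build_ball_and_stick(nseg=50)).total_area()
    assert a == pytest.approx(b, rel=1e-12)


class TestPassiveOracles:
    def test_rc_charging_single_compartment(self):
        """Isopotential soma under a current step follows the RC closed form."""
        m = mo.Morphology(soma=mo.SectionSpec("soma", 23, 718), sections=[])
        g = sv.discretize(m)
        I = 0.1  # nA
        res = sv.simulate(g, 120.0, 0.025, i_inj=np.array([I]), rec_dt=0.025)
        R = mo.soma_input_resistance(718, 23, 30)  # MOhm -> mV/nA
        tau = 30e3 * 1e-6 * 1e3  # Rm*Cm in ms
        expected = -77.0 + I * R * (1.0 - np.exp(-res.t / tau))
        err = np.abs(res.v[:, 0] - expected)
        assert err.max() / (I * R) < 0.005

    def test_resting_fixed_point(self):
        m = mo.build_ball_and_stick()
        res = sv.simulate(sv.discretize(m), 500.0)
        assert np.abs(res.v - (-77.0)).max() < 1e-3  # < 1 uV

    def test_three_compartment_chain_vs_matrix_exponential(self):
        """Brute-force oracle: dense expm solution of the linear cable ODE."""
        m = mo.Morphology(soma=mo.SectionSpec("soma", 23, 718),
                          sections=[mo.SectionSpec("b0", 100, 0.75, nseg=2,
                                                   parent="soma")])
        g = sv.discretize(m)
        assert g.n_comp == 3
        I = np.array([0.0, 0.0, 0.05])
        res = sv.simulate(g, 100.0, 0.0125, i_inj=I, rec_dt=0.5)
        G = sv._conductance_matrix(g)
        C = np.diag(g.cap)
        v_inf = np.linalg.solve(G, g.g_leak * (-77.0) + I)
        A = np.linalg.solve(C, G)
        v0 = np.full(3, -77.0)
        for k, t in enumerate(res.t):
            vt = v_inf + scipy.linalg.expm(-A * t) @ (v0 - v_inf)
            assert np.abs(res.v[k] - vt).max() < 0.01  # 10 uV

    def test_sealed_cable_matches_coth_formula(self):
        soma = mo.SectionSpec("soma", 1e-3, 0.75)
        dend = mo.SectionSpec("b0", 200.0, 0.75, nseg=400, parent="soma")
        m = mo.Morphology(soma=soma, sections=[dend],
                          passive=mo.PassiveParams(Rm=44.0,
                                                   spine_compensation=False,
                                                   soma_Rm=1e9))
        g = sv.discretize(m)
        rn = sv.input_resistances(g)[g.comp_at("b0", 0.0)]
        expected = sealed_cable_input_resistance(200.0, 0.75, 44.0, 150.0)
        assert abs(rn - expected) / expected < 0.01


class TestTreeSolveEquivalence:
    @pytest.mark.parametrize("builder", [mo.build_ball_and_stick,
                                         mo.build_symmetric_tree])
    def test_hines_equals_dense(self, builder):
        m = builder()
        m = mo.attach_spine(m, mo.SpineSite("b0", 0.5))
        g = sv.discretize(m)
        d = g.g_leak.copy()
        for i in range(1, g.n_comp):
            d[i] += g.g_axial[i]
            d[g.parent[i]] += g.g_axial[i]
        rhs = g.g_leak * (-77.0)
        rhs[g.comp_at("b0", 0.9)] += 1.0
        v_tree = sv._hines(d.copy(), g.g_axial, g.parent, rhs.copy())
        v_dense = np.linalg.solve(sv._conductance_matrix(g), rhs)
        assert np.abs(v_tree - v_dense).max() < 1e-9 * np.abs(v_dense).max()


class TestTransferResistance:
    def test_isolated_soma_ohm(self):
        m = mo.Morphology(soma=mo.SectionSpec("soma", 23, 718), sections=[])
        g = sv.discretize(m)
        dv = sv.steady_state_profile(g, 0, 1.0)
        assert dv[0] == pytest.approx(mo.soma_input_resistance(718, 23, 30),
                                      rel=1e-9)

    @pytest.mark.parametrize("builder", [mo.build_ball_and_stick,
                                         mo.build_symmetric_tree])
    def test_reciprocity(self, builder):
        g = sv.discretize(builder())
        K = sv.transfer_resistance_matrix(g)
        assert np.abs(K - K.T).max() < 1e-6 * K.max()

    def test_injection_symmetry_tip_vs_soma(self):
        g = sv.discretize(mo.build_ball_and_stick())
        tip = g.comp_at("b0", 1.0)
        a = sv.steady_state_profile(g, tip, 1.0)[0]
        b = sv.steady_state_profile(g, 0, 1.0)[tip]
        assert a == pytest.approx(b, rel=1e-9)

    def test_input_resistance_rises_toward_tip(self):
        g = sv.discretize(mo.build_ball_and_stick())
        diag = sv.input_resistances(g)
        shaft = diag[1:51]
        assert np.all(np.diff(shaft) > 0)  # falls toward the somatic sink

    def test_attenuation_asymmetric_despite_symmetric_K(self):
        g = sv.discretize(mo.build_ball_and_stick())
        K = sv.transfer_resistance_matrix(g)
        i = g.comp_at("b0", 0.5)
        toward_soma = K[i, g.comp_at("b0", 0.25)] / K[i, i]
        toward_tip = K[i, g.comp_at("b0", 0.75)] / K[i, i]
        assert toward_tip > 0.95
        assert toward_soma < 0.8


class TestDynamics:
    def test_bitwise_determinism(self):
        a = pr.run_experiment(pr.preset_fig2(n=2))
        b = pr.run_experiment(pr.preset_fig2(n=2))
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.eff_ca, b.eff_ca)

    def test_epsp_peak_ordering(self, fig2_epsp):
        res = fig2_epsp
        g = res.graph
        head = res.v[:, g.spine_head[2]].max()
        base = res.v[:, g.comp_at("b0", 0.5)].max()
        soma = res.v[:, 0].max()
        assert head > base > soma

    def test_asymmetric_attenuation_to_probe_spines(self, fig2_epsp):
        """Hardly any loss from activated base to the distal 200 um spine
        head; strong loss toward the proximal 60 um spine."""
        res = fig2_epsp
        g = res.graph
        rest = -77.0
        base = res.v[:, g.comp_at("b0", 0.5)].max() - rest
        distal = res.v[:, g.spine_head[1]].max() - rest
        proximal = res.v[:, g.spine_head[0]].max() - rest
        assert distal / base > 0.9
        assert proximal / base < 0.75
        assert proximal < distal

    def test_dt_halving_trace_stability(self, fig2_spike):
        spec = pr.preset_fig2(n=18)
        spec.dt = spec.dt / 2.0
        fine = pr.run_experiment(spec)
        assert np.abs(fig2_spike.v - fine.v).max() < 0.1

    def test_voltage_sanity_band(self, fig2_spike, fig3_result):
        for res in (fig2_spike, fig3_result[1]):
            assert res.v.min() >= -100.0 and res.v.max() <= 60.0

    def test_nmda_current_zero_without_release(self, fig2_spike):
        non = [i for i, sp in enumerate(fig2_spike.graph.morph.spines)
               if sp.onset is None]
        assert np.all(fig2_spike.ica_nmda[:, non] == 0.0)


class TestIhVariant:
    def test_resting_state_depolarized_and_asymmetry_kept(self):
        spec = pr.preset_fig2(n=18)
        res = pr.run_experiment(spec, ih=ch.IhParams(density=2.0))
        # settled resting potential sits above the passive -77 mV
        assert res.v[0, 0] > -77.0
        from dendroplast.analysis import attenuation_profile, asymmetry_index
        prof = attenuation_profile(res)
        assert asymmetry_index(prof, 100.0, 40.0) > 1.0
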