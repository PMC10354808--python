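"""Bistable rho dynamics, the rho -> conductance map, and outcome
classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendroplast import plasticity as pl
from dendroplast.analysis import outcome_table


P = pl.PlasticityParams()


class TestRhoDynamics:
    def test_unstable_fixed_point_holds_without_calcium(self):
        rho = 0.5
        for _ in range(10000):
            rho = pl.rho_step(rho, 0.0, P, 1.0)
        assert rho == 0.5

    def test_sustained_high_calcium_potentiates_to_up_state(self):
        # ODE oracle: with c >> theta_P, drho/dt = (gp(1-r) - gd r - cubic)/tau
        rho = 0.5
        for _ in range(300_000):  # 300 s at dt = 1 ms
            rho = pl.rho_step(rho, 10.0, P, 1.0)
        expected = P.gamma_p / (P.gamma_p + P.gamma_d)  # cubic term ~ 0 nearby
        assert rho == pytest.approx(expected, abs=0.02)
        assert rho > 0.6
        assert pl.gmax_from_rho(1.0, P) == 2.0

    def test_intermediate_calcium_depresses(self):
        rho = pl.rho_step(0.5, 0.7, P, 1.0)
        assert rho < 0.5

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 20), min_size=1, max_size=200))
    def test_rho_bounded_for_any_calcium_input(self, calcium):
        rho = 0.5
        for c in calcium:
            rho = pl.rho_step(rho, c, P, 5.0)
            assert 0.0 <= rho <= 1.0


@pytest.mark.parametrize("rho,expected", [(0.0, 1.0), (0.5, 1.5), (1.0, 2.0)])
def test_gmax_endpoints(rho, expected):
    assert pl.gmax_from_rho(rho, P) == pytest.approx(expected)


class TestClassification:
    @pytest.mark.parametrize("peak,label", [
        (0.3, "N"), (0.7, "D"), (1.2, "P"),
        (0.5, "D"),  # inclusive threshold tie-break
        (1.0, "P"),
    ])
    def test_peak_rule(self, peak, label):
        trace = np.array([0.0, peak / 2, peak, peak / 3])
        assert pl.classify_outcome(trace, P).value == label

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            pl.classify_outcome(np.array([]), P)

    def test_monotone_in_trace(self):
        base = np.linspace(0, 0.8, 50)
        lo = pl.classify_outcome(base, P)
        hi = pl.classify_outcome(base * 2, P)
        assert hi.rank >= lo.rank


class TestThresholdSweep:
    def test_raising_theta_p_never_promotes(self):
        traces = np.array([[0.0, 0.6, 0.3], [0.0, 1.4, 0.2]])
        lo = pl.threshold_sweep(traces, [(0.5, 1.0)])[(0.5, 1.0)]
        hi = pl.threshold_sweep(traces, [(0.5, 2.0)])[(0.5, 2.0)]
        for a, b in zip(lo, hi):
            assert b.rank <= a.rank

    def test_invalid_grid_point_rejected(self):
        with pytest.raises(ValueError):
            pl.threshold_sweep(np.zeros((1, 3)), [(1.0, 0.5)])

    def test_fig3_trace_set_reference_thresholds(self, fig3_result):
        """27 synapses at 100 um: potentiation at activated and distal
        spines, depression only at the nearest proximal spine."""
        spec, res = fig3_result
        sweep = pl.threshold_sweep(res.eff_ca.T, [(0.5, 1.0)])[(0.5, 1.0)]
        spines = res.graph.morph.spines
        for sp, label in zip(spines, sweep):
            if sp.onset is not None or sp.path_distance >= 100.0:
                assert label is pl.Outcome.P
            elif sp.path_distance == 90.0:
                assert label is pl.Outcome.D
            else:
                assert label is pl.Outcome.N

    def test_forbidden_pairs_absent(self, fig3_result):
        spec, res = fig3_result
        labels, _ = pl.outcome_map(res, spec.plasticity)
        spines = res.graph.morph.spines
        homo = max((l for sp, l in zip(spines, labels) if sp.onset is not None),
                   key=lambda l: l.rank)
        pairs = {homo.value + l.value
                 for sp, l in zip(spines, labels) if sp.onset is None}
        assert not pairs & {"DP", "NP", "ND"}


class TestOutcomeMap:
    def test_quiet_run_all_no_change(self, quiet_result):
        labels, peaks = pl.outcome_map(quiet_result, P)
        assert all(l is pl.Outcome.N for l in labels)
        # resting VGCC flux leaves a tiny baseline, far below theta_D
        assert np.all(peaks < 1e-3)

    def test_activated_calcium_dominates(self, fig3_result):
        spec, res = fig3_result
        _, peaks = pl.outcome_map(res, spec.plasticity)
        act = [i for i, sp in enumerate(res.graph.morph.spines)
               if sp.onset is not None]
        non = [i for i, sp in enumerate(res.graph.morph.spines)
               if sp.onset is None]
        assert min(peaks[a] for a in act) >= max(peaks[n] for n in non) - 1e-9

    def test_peak_and_rho_rules_agree_up_to_threshold_zone(self, fig3_result):
        """The rho-based rule can relabel a peak-rule P as D when a brief
        excursion above theta_P rides on a long tail inside the depression
        window; that is the only permissible disagreement, and below
        theta_P the two rules coincide exactly."""
        spec, res = fig3_result
        peak_labels, peaks = pl.outcome_map(res, spec.plasticity, rule="peak")
        rho_labels, _ = pl.outcome_map(res, spec.plasticity, rule="rho")
        disagreements = {(p.value, r.value)
                         for p, r in zip(peak_labels, rho_labels) if p is not r}
        assert disagreements <= {("P", "D")}
        for p, r, pk in zip(peak_labels, rho_labels, peaks):
            if pk < spec.plasticity.theta_P:
                assert p is r

    def test_missing_probes_rejected(self):
        from dendroplast.morphology import build_ball_and_stick
        from dendroplast.solver import discretize, simulate

        res = simulate(discretize(build_ball_and_stick()), 10.0)
        with pytest.raises(ValueError):
            pl.outcome_map(res, P)


def test_outcome_table_columns(fig3_result):
    spec, res = fig3_result
    tab = outcome_table(res, spec.plasticity)
    assert set(tab.columns) >= {"spine_id", "branch", "path_distance_um",
                                "peak_ca", "label"}
    assert set(tab.label) <= {"P", "D", "N"}
    assert len(tab) == res.graph.n_spines
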