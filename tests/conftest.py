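"""Shared fixtures: the expensive simulation runs are session-scoped so the
whole suite pays for each preset once."""

import pytest

from dendroplast import protocols as pr


@pytest.fixture(scope="session")
def fig2_epsp():
    """Subthreshold attenuation run: 5 synapses at 100 um."""
    return pr.run_experiment(pr.preset_fig2(n=5))


@pytest.fixture(scope="session")
def fig2_spike():
    """NMDA-spike attenuation run: 18 synapses at 100 um."""
    return pr.run_experiment(pr.preset_fig2(n=18))


@pytest.fixture(scope="session")
def fig3_result():
    """Asymmetric heterosynaptic plasticity run (27 synapses, spines every
    10 um) together with its experiment spec."""
    spec = pr.preset_fig3()
    return spec, pr.run_experiment(spec)


@pytest.fixture(scope="session")
def quiet_result():
    """No stimulus at all: two nonactivated spines, 300 ms at rest."""
    return pr.run_experiment(pr.preset_fig2(n=0))


def activated_indices(result):
    return [i for i, sp in enumerate(result.graph.morph.spines)
            if sp.onset is not None]


def nonactivated_indices(result):
    return [i for i, sp in enumerate(result.graph.morph.spines)
            if sp.onset is None]
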