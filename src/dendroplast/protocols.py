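"""Experiment configurations.

Every experiment in the study is a deterministic, programmatically built
configuration: a morphology preset, a layout of background (nonactivated)
spines, one or more simultaneously activated spine clusters, plasticity
thresholds, and the integration window. Presets:

* ``fig2``  — ball-and-stick, cluster of 5 (subthreshold EPSP) or 18 (NMDA
  spike) synapses at 100 um, nonactivated probe spines at 60 and 200 um.
* ``fig3``  — ball-and-stick, spines every 10 um, 27 synapses at 100 um;
  the asymmetric heterosynaptic plasticity experiment.
* ``fig4``  — order-3 tree, spines every 10 um tree-wide, cluster of
  20/30/40/50 at the midpoint of a branch of given order.
* ``fig5``  — ball-and-stick sandwich: clusters at 60 and 200 um, inactive
  spine at 130 um.
* ``fig6``  — branched sandwiches, vertical (first-order + third-order
  clusters, probe on the intervening second-order branch) or horizontal
  (two sister third-order clusters, probe on their parent), with the
  lowered thresholds (0.2, 0.4).

Activation is a single simultaneous presynaptic event per synapse
(deterministic release) at onset 50 ms; tstop defaults to 300 ms. A
"cluster at the center of a branch" means n spines attached to the midpoint
segment, each with its own neck and head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import channels as ch
from .morphology import (
    Morphology,
    PassiveParams,
    SpineGeometry,
    SpineSite,
    attach_spine,
    build_ball_and_stick,
    build_symmetric_tree,
)
from .plasticity import PlasticityParams
from .solver import SimulationResult, discretize, simulate

__all__ = [
    "ClusterStim",
    "ExperimentSpec",
    "spine_layout_every",
    "preset_fig2",
    "preset_fig3",
    "preset_fig4",
    "preset_fig5",
    "preset_fig6",
    "preset_by_name",
    "run_experiment",
    "nmda_spike_detect",
    "minimal_cluster_for_spike",
    "NO_SPIKE",
]

#: Default stimulus onset (ms): after the passive model has settled.
DEFAULT_ONSET = 50.0
DEFAULT_TSTOP = 300.0

#: Sentinel returned by minimal_cluster_for_spike when no size succeeds.
NO_SPIKE = -1


@dataclass(frozen=True)
class ClusterStim:
    """A cluster of synapses activated at one time.

    ``layout='colocated'`` puts all ``n_synapses`` spines on the same
    segment; ``'distributed'`` spreads them uniformly along the section.
    """

    section: str
    position: float  # normalized along the section
    n_synapses: int
    onset: float = DEFAULT_ONSET
    layout: str = "colocated"

    def __post_init__(self):
        if self.n_synapses < 0:
            raise ValueError("n_synapses must be >= 0")
        if self.layout not in ("colocated", "distributed"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclass
class ExperimentSpec:
    """Complete, reproducible description of one simulation experiment."""

    name: str
    morphology: str = "ball_and_stick"  # or "tree"
    stimuli: list[ClusterStim] = field(default_factory=list)
    background_spacing: float | None = None  # um; spines every N um
    extra_spines: list[tuple[str, float]] = field(default_factory=list)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    tstop: float = DEFAULT_TSTOP
    dt: float = 0.0125
    rec_dt: float = 0.1
    ih_density: float = 0.0  # pS/um^2
    spine_geometry: SpineGeometry = field(default_factory=SpineGeometry)
    passive: PassiveParams = field(default_factory=PassiveParams)

    def build_morphology(self) -> Morphology:
        """Morphology with all spines attached, in deterministic order:
        background spines first (by branch name, then distance), then extra
        probe spines, then stimulus-cluster spines."""
        if self.morphology == "ball_and_stick":
            morph = build_ball_and_stick(self.passive)
        elif self.morphology == "tree":
            morph = build_symmetric_tree(self.passive)
        else:
            raise ValueError(f"unknown morphology preset {self.morphology!r}")
        if self.background_spacing is not None:
            for site in spine_layout_every(morph, self.background_spacing,
                                           geometry=self.spine_geometry):
                morph = attach_spine(morph, site)
        for sec_name, pos in self.extra_spines:
            morph = attach_spine(morph, SpineSite(
                section=sec_name, position=pos, geometry=self.spine_geometry,
                has_synapse=True, onset=None))
        for stim in self.stimuli:
            sec = morph.section(stim.section)
            for k in range(stim.n_synapses):
                if stim.layout == "colocated":
                    pos = stim.position
                else:
                    pos = (k + 0.5) / stim.n_synapses
                morph = attach_spine(morph, SpineSite(
                    section=stim.section, position=pos,
                    geometry=self.spine_geometry, has_synapse=True,
                    onset=stim.onset))
        return morph

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stimuli"] = [asdict(s) for s in self.stimuli]
        return d


def spine_layout_every(morph: Morphology, spacing: float,
                       geometry: SpineGeometry | None = None) -> list[SpineSite]:
    """Nonactivated spines at every multiple of ``spacing`` um of path
    distance from the soma, on every branch.

    No spine sits at a branch's 0 um point (branch points are owned by the
    parent's distal spine); a 200 um path with 10 um spacing yields sites at
    10, 20, ..., 200 um. Ordering is (branch name, distance), deterministic.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    geometry = geometry or SpineGeometry()
    sites: list[SpineSite] = []
    for sec in sorted(morph.sections, key=lambda s: s.name):
        start = morph.section_path_distance(sec.name, 0.0)
        end = morph.section_path_distance(sec.name, 1.0)
        k = math.floor(start / spacing) + 1
        while k * spacing <= end + 1e-9:
            dist = k * spacing
            if dist > start + 1e-9:
                pos = min((dist - start) / sec.length, 1.0)
                sites.append(SpineSite(section=sec.name, position=pos,
                                       geometry=geometry, has_synapse=True,
                                       onset=None))
            k += 1
    return sites


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def preset_fig2(n: int = 5, site_um: float = 100.0,
                distributed: bool = False) -> ExperimentSpec:
    """Attenuation experiment: a cluster at ``site_um`` on the ball-and-stick
    dendrite with nonactivated probe spines at 60 and 200 um."""
    spec = ExperimentSpec(
        name=f"fig2_n{n}",
        morphology="ball_and_stick",
        stimuli=[ClusterStim("b0", site_um / 200.0, n,
                             layout="distributed" if distributed else "colocated")],
        extra_spines=[("b0", 60.0 / 200.0), ("b0", 200.0 / 200.0)],
    )
    return spec


def preset_fig3(n: int = 27, site_um: float = 100.0,
                thresholds: tuple[float, float] = (0.5, 1.0)) -> ExperimentSpec:
    """Asymmetric heterosynaptic plasticity: spines every 10 um plus a
    colocated cluster of ``n`` at ``site_um``."""
    thd, thp = thresholds
    return ExperimentSpec(
        name=f"fig3_n{n}",
        morphology="ball_and_stick",
        background_spacing=10.0,
        stimuli=[ClusterStim("b0", site_um / 200.0, n)],
        plasticity=PlasticityParams(theta_D=thd, theta_P=thp),
    )


#: Deterministic representative branch per order in the symmetric tree.
_BRANCH_OF_ORDER = {0: "b0", 1: "b0L", 2: "b0LL", 3: "b0LLL"}


def preset_fig4(branch_order: int, n: int,
                thresholds: tuple[float, float] = (0.5, 1.0)) -> ExperimentSpec:
    """Hierarchical plasticity: cluster of ``n`` at the midpoint of a branch
    of the given order on the order-3 tree, spines every 10 um tree-wide."""
    if branch_order not in _BRANCH_OF_ORDER:
        raise ValueError("branch_order must be in {0, 1, 2, 3}")
    thd, thp = thresholds
    return ExperimentSpec(
        name=f"fig4_o{branch_order}_n{n}",
        morphology="tree",
        background_spacing=10.0,
        stimuli=[ClusterStim(_BRANCH_OF_ORDER[branch_order], 0.5, n)],
        plasticity=PlasticityParams(theta_D=thd, theta_P=thp),
    )


def preset_fig5(n_prox: int, n_dist: int,
                thresholds: tuple[float, float] = (0.5, 1.0)) -> ExperimentSpec:
    """Vertical sandwich on the ball-and-stick model: clusters at 60 and
    200 um, inactive spine at 130 um."""
    thd, thp = thresholds
    return ExperimentSpec(
        name=f"fig5_p{n_prox}_d{n_dist}",
        morphology="ball_and_stick",
        extra_spines=[("b0", 130.0 / 200.0)],
        stimuli=[ClusterStim("b0", 60.0 / 200.0, n_prox),
                 ClusterStim("b0", 200.0 / 200.0, n_dist)],
        plasticity=PlasticityParams(theta_D=thd, theta_P=thp),
    )


def preset_fig6(mode: str, n1: int, n2: int,
                thresholds: tuple[float, float] = (0.2, 0.4)) -> ExperimentSpec:
    """Branched sandwiches.

    ``vertical``: clusters on a first-order branch and a descendant
    third-order branch, inactive probe on the intervening second-order
    branch. ``horizontal``: clusters on two sister third-order branches,
    inactive probe on their second-order parent. Cluster sizes ``n1``/``n2``
    are (proximal, distal) for vertical and (left, right) for horizontal.
    """
    thd, thp = thresholds
    if mode == "vertical":
        stims = [ClusterStim("b0L", 0.5, n1), ClusterStim("b0LLL", 0.5, n2)]
        probe = [("b0LL", 0.5)]
    elif mode == "horizontal":
        stims = [ClusterStim("b0LLL", 0.5, n1), ClusterStim("b0LLR", 0.5, n2)]
        probe = [("b0LL", 0.5)]
    else:
        raise ValueError("mode must be 'vertical' or 'horizontal'")
    return ExperimentSpec(
        name=f"fig6{mode[0]}_{n1}_{n2}",
        morphology="tree",
        extra_spines=probe,
        stimuli=stims,
        plasticity=PlasticityParams(theta_D=thd, theta_P=thp),
    )


def preset_by_name(preset: str, **overrides) -> ExperimentSpec:
    """CLI entry: fig2, fig3, fig4, fig5, fig6v, fig6h with keyword tweaks."""
    table = {
        "fig2": lambda: preset_fig2(**overrides),
        "fig3": lambda: preset_fig3(**overrides),
        "fig4": lambda: preset_fig4(**{"branch_order": 1, "n": 40, **overrides}),
        "fig5": lambda: preset_fig5(**{"n_prox": 20, "n_dist": 20, **overrides}),
        "fig6v": lambda: preset_fig6("vertical",
                                     **{"n1": 20, "n2": 20, **overrides}),
        "fig6h": lambda: preset_fig6("horizontal",
                                     **{"n1": 20, "n2": 20, **overrides}),
    }
    if preset not in table:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(table)}")
    return table[preset]()


def run_experiment(spec: ExperimentSpec, ih: ch.IhParams | None = None,
                   **sim_kwargs) -> SimulationResult:
    """Build, discretize and integrate one experiment. Bitwise deterministic
    for a given spec and dt."""
    morph = spec.build_morphology()
    ih = ih or ch.IhParams(density=spec.ih_density)
    graph = discretize(morph, ih=ih)
    return simulate(graph, spec.tstop, spec.dt, plasticity=spec.plasticity,
                    ih=ih, rec_dt=spec.rec_dt,
                    meta={"preset": spec.name, **spec.to_dict()}, **sim_kwargs)


# ---------------------------------------------------------------------------
# NMDA spike detection
# ---------------------------------------------------------------------------


def nmda_spike_detect(v_trace: np.ndarray, t: np.ndarray,
                      v_plateau: float = -40.0,
                      t_plateau: float = 20.0) -> tuple[bool, float]:
    """Plateau criterion: local voltage >= ``v_plateau`` mV for at least
    ``t_plateau`` contiguous ms.

    Returns (detected, duration of the longest supra-threshold run in ms).
    The criterion itself is a package definition of the plateau
    phenomenology; both parameters are exposed.
    """
    v = np.asarray(v_trace, dtype=float)
    above = v >= v_plateau
    if not above.any():
        return False, 0.0
    dt = float(t[1] - t[0])
    longest = run = 0
    for flag in above:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    duration = longest * dt
    return duration >= t_plateau, duration


def minimal_cluster_for_spike(site_um: float = 100.0, max_n: int = 40,
                              v_plateau: float = -40.0,
                              t_plateau: float = 20.0) -> int:
    """Smallest colocated cluster at ``site_um`` on the ball-and-stick
    dendrite that elicits an NMDA plateau, or ``NO_SPIKE`` if none does.

    Sweeps cluster size 1..max_n in steps of 1; deterministic.
    """
    if max_n < 1:
        return NO_SPIKE
    for n in range(1, max_n + 1):
        spec = ExperimentSpec(
            name=f"spike_search_n{n}",
            morphology="ball_and_stick",
            stimuli=[ClusterStim("b0", site_um / 200.0, n)],
        )
        res = run_experiment(spec)
        head = res.graph.spine_head[0]  # first activated spine
        ok, _ = nmda_spike_detect(res.v[:, head], res.t, v_plateau, t_plateau)
        if ok:
            return n
    return NO_SPIKE
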