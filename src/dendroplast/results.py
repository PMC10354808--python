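"""Headline-result recomputation.

Functions that run the protocol sweeps and reduce them to the categorical
milestones the study reports: the smallest cluster size at each branch
order that produces a given homosynaptic or heterosynaptic outcome, the
location of the uniquely depressed spine in the asymmetric-plasticity
experiment, and the minimal cluster size for an NMDA plateau.

Spine-set conventions (deterministic, used everywhere):

* activated — spines with a presynaptic event (the cluster);
* distal set — nonactivated spines strictly distal to the input site:
  everything on descendant branches plus same-branch spines beyond the
  cluster position;
* sister set — nonactivated spines on the stimulated branch's sister
  subtree (same parent, other child, including its descendants).

A set's outcome is its modal label, ties broken toward the higher label in
the N < D < P ordering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from . import protocols as pr
from .plasticity import Outcome, outcome_map

__all__ = ["Fig4Cell", "sweep_branch_order_grid", "smallest_cluster_with",
           "proximal_depression_distance", "set_outcome"]

DEFAULT_GRID = (20, 30, 40, 50)


def set_outcome(labels: list[Outcome]) -> Outcome | None:
    """Modal label of a spine set; ties break toward the higher rank."""
    if not labels:
        return None
    counts = Counter(labels)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0].rank))
    return best[0]


@dataclass(frozen=True)
class Fig4Cell:
    """One cell of the branch-order x cluster-size grid."""

    branch_order: int
    n_synapses: int
    homo: Outcome
    distal: Outcome | None
    sister: Outcome | None


def _classify_cell(spec, branch: str) -> tuple[Outcome, Outcome | None,
                                               Outcome | None]:
    res = pr.run_experiment(spec)
    labels, _ = outcome_map(res, spec.plasticity)
    morph = res.graph.morph
    site = morph.section_path_distance(branch, spec.stimuli[0].position)
    homo, distal, sister = [], [], []
    parent = branch[:-1] if len(branch) > 2 else None
    for sp, lab in zip(morph.spines, labels):
        if sp.onset is not None:
            homo.append(lab)
            continue
        on_descendant = sp.section.startswith(branch) and sp.section != branch
        beyond_on_branch = (sp.section == branch
                            and sp.path_distance > site + 1e-9)
        if on_descendant or beyond_on_branch:
            distal.append(lab)
        elif (parent and sp.section.startswith(parent)
              and not sp.section.startswith(branch)
              and len(sp.section) >= len(branch)):
            sister.append(lab)
    return set_outcome(homo), set_outcome(distal), set_outcome(sister)


def sweep_branch_order_grid(orders=(0, 1, 2, 3), grid=DEFAULT_GRID,
                            thresholds=(0.5, 1.0)) -> list[Fig4Cell]:
    """Run the full branch-order x cluster-size sweep on the order-3 tree."""
    cells = []
    for order in orders:
        branch = pr._BRANCH_OF_ORDER[order]
        for n in grid:
            spec = pr.preset_fig4(order, n, thresholds=thresholds)
            homo, distal, sister = _classify_cell(spec, branch)
            cells.append(Fig4Cell(order, n, homo, distal, sister))
    return cells


def smallest_cluster_with(cells: list[Fig4Cell], branch_order: int,
                          role: str, label: Outcome) -> int | None:
    """Smallest grid size at the given order whose ``role`` set ('homo',
    'distal', 'sister') carries ``label``; None if no size does."""
    hits = [c.n_synapses for c in cells
            if c.branch_order == branch_order
            and getattr(c, role) is label]
    return min(hits) if hits else None


def proximal_depression_distance(n: int = 27, site_um: float = 100.0,
                                 thresholds=(0.5, 1.0)) -> float:
    """Distance (um) from the activated cluster to the single depressed
    spine on its proximal side in the asymmetric-plasticity experiment.

    Raises if the depressed proximal spine is not unique, or if any spine
    at or distal to the cluster fails to potentiate.
    """
    spec = pr.preset_fig3(n=n, site_um=site_um, thresholds=thresholds)
    res = pr.run_experiment(spec)
    labels, _ = outcome_map(res, spec.plasticity)
    depressed = []
    for sp, lab in zip(res.graph.morph.spines, labels):
        if sp.onset is not None:
            continue
        if sp.path_distance < site_um - 1e-9:
            if lab is Outcome.D:
                depressed.append(sp.path_distance)
        elif lab is not Outcome.P:
            raise RuntimeError(
                f"spine at {sp.path_distance} um distal to the cluster is "
                f"{lab.value}, expected P")
    if len(depressed) != 1:
        raise RuntimeError(
            f"expected a unique proximal depressed spine, got {depressed}")
    return site_um - depressed[0]
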