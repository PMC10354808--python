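"""Metrics, figure-style renderings and trace I/O.

The attenuation profile summarizes a run by the peak depolarization above
rest at each dendritic segment; the asymmetry index compares the peak at a
site Delta um distal to the injection site against the peak Delta um
proximal to it — greater than 1 means depolarization spreads preferentially
toward the distal, sealed end, the signature of the somatic current sink.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plasticity import Outcome, PlasticityParams, outcome_map
from .solver import SimulationResult

__all__ = [
    "AttenuationProfile",
    "attenuation_profile",
    "asymmetry_index",
    "outcome_table",
    "render_spacetime_heatmap",
    "export_traces",
    "import_traces",
    "parameter_hash",
]

_FORMAT_VERSION = 1


@dataclass
class AttenuationProfile:
    """Peak depolarization (mV above rest) along the dendritic shaft."""

    distance_um: np.ndarray
    peak_mv: np.ndarray
    section: np.ndarray  # branch name per sample

    def peak_at(self, dist: float) -> float:
        i = int(np.argmin(np.abs(self.distance_um - dist)))
        return float(self.peak_mv[i])


def attenuation_profile(result: SimulationResult) -> AttenuationProfile:
    """Per-segment peak depolarization over the run, shaft compartments only."""
    graph = result.graph
    morph = graph.morph
    rest = morph.passive.Epas
    dists, peaks, secs = [], [], []
    for sec in morph.sections:
        start = graph._seg_start[sec.name]
        for k in range(sec.nseg):
            dists.append(morph.section_path_distance(
                sec.name, (k + 0.5) / sec.nseg))
            peaks.append(float(result.v[:, start + k].max() - rest))
            secs.append(sec.name)
    if not dists:
        raise ValueError("result has no dendritic compartments to profile")
    return AttenuationProfile(np.array(dists), np.array(peaks),
                              np.array(secs))


def asymmetry_index(profile: AttenuationProfile, site_um: float,
                    delta_um: float, section: str | None = None) -> float:
    """(peak at site + delta) / (peak at site - delta); > 1 means the distal
    side of the injection site is depolarized more than the proximal side."""
    mask = (profile.section == section) if section else np.ones_like(
        profile.distance_um, dtype=bool)
    d = profile.distance_um[mask]
    p = profile.peak_mv[mask]
    up = p[np.argmin(np.abs(d - (site_um + delta_um)))]
    down = p[np.argmin(np.abs(d - (site_um - delta_um)))]
    if down <= 0:
        raise ValueError("no depolarization at the proximal comparison site")
    return float(up / down)


def outcome_table(result: SimulationResult,
                  params: PlasticityParams | None = None,
                  rule: str = "peak") -> pd.DataFrame:
    """Per-spine outcome grid: spine id, location, peak calcium and label."""
    labels, peaks = outcome_map(result, params, rule=rule)
    morph = getattr(result.graph, "morph", None)
    rows = []
    for i in range(result.graph.n_spines):
        sp = morph.spines[i] if morph is not None else None
        rows.append({
            "spine_id": i,
            "branch": sp.section if sp else "",
            "path_distance_um": sp.path_distance if sp else float("nan"),
            "activated": (sp.onset is not None) if sp else None,
            "peak_ca": float(peaks[i]),
            "label": labels[i].value,
        })
    return pd.DataFrame(rows)


def render_spacetime_heatmap(result: SimulationResult, path: str,
                             vmin: float | None = None,
                             vmax: float | None = None) -> str:
    """Time x distance voltage map, one panel per branch; returns the path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    graph = result.graph
    morph = graph.morph
    vmin = morph.passive.Epas if vmin is None else vmin
    vmax = float(result.v.max()) if vmax is None else vmax
    sections = morph.sections
    n = len(sections)
    ncol = min(n, 4)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.2 * nrow),
                             squeeze=False)
    for ax in axes.flat:
        ax.set_axis_off()
    for i, sec in enumerate(sections):
        ax = axes[i // ncol][i % ncol]
        ax.set_axis_on()
        start = graph._seg_start[sec.name]
        block = result.v[:, start:start + sec.nseg].T
        im = ax.imshow(block, aspect="auto", origin="lower",
                       extent=(result.t[0], result.t[-1], 0, sec.length),
                       vmin=vmin, vmax=vmax, cmap="inferno")
        ax.set_title(sec.name, fontsize=8)
        ax.set_xlabel("t (ms)", fontsize=7)
        ax.set_ylabel("um", fontsize=7)
    fig.colorbar(im, ax=axes, shrink=0.8, label="V (mV)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------


def parameter_hash(meta: dict) -> str:
    """Stable content hash of a resolved parameter dictionary."""
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


_QUANTITIES = ("ica_nmda", "ica_vgcc", "cai", "eff_ca", "rho")


def export_traces(result: SimulationResult, path: str,
                  format: str = "hdf5") -> str:
    """Persist traces + metadata; HDF5 (hierarchical) or CSV (long format)."""
    if format == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = _FORMAT_VERSION
            f.attrs["meta"] = json.dumps(result.meta, default=str)
            f.attrs["param_hash"] = parameter_hash(result.meta)
            f.create_dataset("t", data=result.t)
            g = f.create_group("traces")
            g.create_dataset("v", data=result.v)
            for q in _QUANTITIES:
                g.create_dataset(q, data=getattr(result, q))
            f.create_dataset("names", data=np.array(result.graph.names,
                                                    dtype="S"))
    elif format == "csv":
        frames = []
        for ci, name in enumerate(result.graph.names):
            frames.append(pd.DataFrame({
                "t": result.t, "site": name, "quantity": "v",
                "value": result.v[:, ci]}))
        for si in range(result.graph.n_spines):
            for q in _QUANTITIES:
                frames.append(pd.DataFrame({
                    "t": result.t, "site": f"spine{si}", "quantity": q,
                    "value": getattr(result, q)[:, si]}))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def import_traces(path: str, graph=None) -> SimulationResult:
    """Load an HDF5 trace file written by :func:`export_traces`."""
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"incompatible trace file version {f.attrs.get('format_version')!r},"
                f" expected {_FORMAT_VERSION}")
        meta = json.loads(f.attrs["meta"])
        t = f["t"][:]
        v = f["traces/v"][:]
        arrays = {q: f[f"traces/{q}"][:] for q in _QUANTITIES}
        names = [s.decode() for s in f["names"][:]]
    if graph is None:
        graph = _GraphStub(names, arrays["eff_ca"].shape[1])
    return SimulationResult(t=t, v=v, graph=graph, meta=meta, **arrays)


class _GraphStub:
    """Minimal stand-in graph for results loaded without a morphology."""

    def __init__(self, names, n_spines):
        self.names = names
        self._n_spines = n_spines
        self.spine_head = np.array(
            [i for i, n in enumerate(names) if n.endswith("_head")],
            dtype=np.int32)
        self.spine_neck = np.array(
            [i for i, n in enumerate(names) if n.endswith("_neck")],
            dtype=np.int32)

    @property
    def n_comp(self):
        return len(self.names)

    @property
    def n_spines(self):
        return self._n_spines

    def index(self, name):
        return self.names.index(name)
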