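"""Idealized spiny-neuron geometries.

Two presets are used throughout: a ball-and-stick model (isopotential soma
with an enlarged, "compensated" diameter that replicates the current-sink
effect of a full dendritic arbor, plus a single 200 um cylindrical dendrite)
and a symmetric order-3 bifurcating tree whose every root-to-tip path is
200 um. Dendritic spines are explicit two-compartment devices: a thin
cylindrical neck and a spherical head, the head carrying the synapse and the
voltage-gated calcium channels.

Unit conventions: lengths and diameters in um, Ra in Ohm*cm, Rm in KOhm*cm^2,
Cm in uF/cm^2, resistances in MOhm. Membrane area of a cylinder is the
lateral area pi*d*L (no end caps); a spherical head of diameter d is
represented as an equivalent cylinder with L = d so that its lateral area
equals the sphere area pi*d^2.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "SectionSpec",
    "PassiveParams",
    "SpineGeometry",
    "SpineSite",
    "Morphology",
    "InvalidGeometryError",
    "SWCParseError",
    "build_ball_and_stick",
    "build_symmetric_tree",
    "compensated_soma_diameter",
    "soma_input_resistance",
    "spine_neck_resistance",
    "fit_neck_diameter",
    "attach_spine",
    "path_distance",
    "to_swc",
    "from_swc",
]


class InvalidGeometryError(ValueError):
    """Raised for non-positive dimensions or broken tree connectivity."""


class SWCParseError(ValueError):
    """Raised on malformed SWC input; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class SectionSpec:
    """A cylindrical cable section.

    ``parent is None`` marks the tree root (the soma). ``parent_position`` is
    the normalized attachment point on the parent, measured from the parent's
    proximal (0) to distal (1) end.
    """

    name: str
    length: float  # um
    diameter: float  # um
    nseg: int = 1
    parent: str | None = None
    parent_position: float = 1.0

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise InvalidGeometryError(
                f"section {self.name!r}: length and diameter must be positive "
                f"(got L={self.length}, d={self.diameter})"
            )
        if self.nseg < 1:
            raise InvalidGeometryError(f"section {self.name!r}: nseg must be >= 1")
        if not 0.0 <= self.parent_position <= 1.0:
            raise InvalidGeometryError(
                f"section {self.name!r}: parent_position outside [0, 1]"
            )

    @property
    def area(self) -> float:
        """Lateral membrane area in um^2 (no end caps)."""
        return math.pi * self.diameter * self.length


@dataclass(frozen=True)
class PassiveParams:
    """Passive cable parameters.

    ``Rm``/``Cm`` apply to the dendrite; the soma has its own values because
    the spine-compensation factor (halve Rm, double Cm, accounting for the
    membrane area of unmodeled spines while preserving tau_m) applies to the
    dendritic shaft only.
    """

    Ra: float = 150.0  # Ohm*cm
    Cm: float = 1.0  # uF/cm^2 (dendrite, before compensation)
    Rm: float = 44.0  # KOhm*cm^2 (dendrite, before compensation)
    Epas: float = -77.0  # mV
    spine_compensation: bool = True
    soma_Rm: float = 30.0  # KOhm*cm^2
    soma_Cm: float = 1.0  # uF/cm^2

    def __post_init__(self):
        if min(self.Ra, self.Cm, self.Rm, self.soma_Rm, self.soma_Cm) <= 0:
            raise InvalidGeometryError("resistivities and capacitances must be > 0")

    @property
    def Rm_eff(self) -> float:
        """Dendritic Rm after spine compensation (KOhm*cm^2)."""
        return self.Rm / 2.0 if self.spine_compensation else self.Rm

    @property
    def Cm_eff(self) -> float:
        """Dendritic Cm after spine compensation (uF/cm^2)."""
        return self.Cm * 2.0 if self.spine_compensation else self.Cm


def fit_neck_diameter(R_neck_MOhm: float, neck_length: float, Ra: float = 150.0) -> float:
    """Neck diameter (um) whose axial resistance equals ``R_neck_MOhm``.

    Inverse of :func:`spine_neck_resistance`: d = sqrt(4*Ra*L / (pi*R)).
    """
    if R_neck_MOhm <= 0 or neck_length <= 0 or Ra <= 0:
        raise InvalidGeometryError("neck fit requires positive R, L, Ra")
    # R[Ohm] = 4*Ra*L[cm] / (pi * d[cm]^2)
    d_cm = math.sqrt(4.0 * Ra * neck_length * 1e-4 / (math.pi * R_neck_MOhm * 1e6))
    return d_cm * 1e4


#: Neck diameter fitted so the neck resistance is exactly 226.6 MOhm at
#: Ra = 150 Ohm*cm and L = 0.66 um (the printed 0.07 um is this value rounded).
FITTED_NECK_DIAMETER = fit_neck_diameter(226.6, 0.66, 150.0)


@dataclass(frozen=True)
class SpineGeometry:
    """Two-compartment spine: cylindrical neck plus spherical head.

    ``spine_Rm`` is the spine membrane resistivity; it is *not* subject to
    the spine-compensation halving (the compensation stands in for spines
    that are not explicitly modeled, which this one is).
    """

    head_diameter: float = 0.4  # um
    neck_diameter: float = FITTED_NECK_DIAMETER  # um
    neck_length: float = 0.66  # um
    spine_Rm: float = 10.7  # KOhm*cm^2
    spine_Cm: float = 1.0  # uF/cm^2

    def __post_init__(self):
        if min(self.head_diameter, self.neck_diameter, self.neck_length,
               self.spine_Rm, self.spine_Cm) <= 0:
            raise InvalidGeometryError("spine dimensions must be positive")

    @property
    def head_area(self) -> float:
        """Sphere surface area pi*d^2 in um^2."""
        return math.pi * self.head_diameter**2

    @property
    def head_volume(self) -> float:
        """Sphere volume in um^3 (calcium-pool volume)."""
        return math.pi * self.head_diameter**3 / 6.0

    @property
    def neck_area(self) -> float:
        return math.pi * self.neck_diameter * self.neck_length


@dataclass(frozen=True)
class SpineSite:
    """Placement of one spine on the dendritic tree."""

    section: str
    position: float  # normalized [0, 1] along the section
    path_distance: float = 0.0  # um from soma, filled by attach_spine
    geometry: SpineGeometry = field(default_factory=SpineGeometry)
    has_synapse: bool = False
    onset: float | None = None  # ms; None = never activated

    def __post_init__(self):
        if not 0.0 <= self.position <= 1.0:
            raise InvalidGeometryError("spine position outside [0, 1]")


@dataclass
class Morphology:
    """Rooted tree of sections, a soma root, and attached spines."""

    soma: SectionSpec
    sections: list[SectionSpec]
    spines: list[SpineSite] = field(default_factory=list)
    passive: PassiveParams = field(default_factory=PassiveParams)

    def __post_init__(self):
        self._validate_tree()

    def _validate_tree(self):
        names = {self.soma.name}
        for sec in self.sections:
            if sec.name in names:
                raise InvalidGeometryError(f"duplicate section name {sec.name!r}")
            names.add(sec.name)
        for sec in self.sections:
            if sec.parent is None:
                raise InvalidGeometryError(
                    f"non-soma section {sec.name!r} has no parent"
                )
            if sec.parent not in names:
                raise InvalidGeometryError(
                    f"section {sec.name!r} references unknown parent {sec.parent!r}"
                )
        # Rooted tree with |sections| parent links and unique names has no
        # cycles iff every section reaches the soma.
        for sec in self.sections:
            seen = set()
            cur = sec
            while cur.parent is not None:
                if cur.name in seen:
                    raise InvalidGeometryError(f"cycle through section {cur.name!r}")
                seen.add(cur.name)
                cur = self.section(cur.parent)

    def section(self, name: str) -> SectionSpec:
        if name == self.soma.name:
            return self.soma
        for sec in self.sections:
            if sec.name == name:
                return sec
        raise KeyError(f"no section named {name!r}")

    @property
    def all_sections(self) -> list[SectionSpec]:
        return [self.soma, *self.sections]

    def total_area(self) -> float:
        """Summed membrane area of soma + dendrite (um^2), spines excluded."""
        return sum(s.area for s in self.all_sections)

    def section_path_distance(self, name: str, position: float = 1.0) -> float:
        """Path distance (um) from the soma center to a point on a section."""
        sec = self.section(name)
        if sec.parent is None:
            return 0.0
        dist = position * sec.length
        while sec.parent is not None:
            parent = self.section(sec.parent)
            if parent.parent is None:  # soma: treated as a point at its center
                break
            dist += sec.parent_position * parent.length
            sec = parent
        return dist


def soma_input_resistance(diameter: float, length: float, Rm: float) -> float:
    """Input resistance (MOhm) of an isolated isopotential cylinder soma.

    RN = Rm / A with the lateral-area convention A = pi*d*L.
    """
    if min(diameter, length, Rm) <= 0:
        raise InvalidGeometryError("soma dimensions and Rm must be positive")
    area_cm2 = math.pi * diameter * length * 1e-8
    return Rm * 1e3 / area_cm2 / 1e6


def compensated_soma_diameter(target_RN: float, Rm: float, soma_len: float) -> float:
    """Soma diameter (um) such that RN = Rm/(pi*d*L) equals ``target_RN`` (MOhm).

    Used to give a reduced model the somatic input resistance of a full
    pyramidal-cell morphology, so the soma acts as an equivalent current sink.
    """
    if target_RN <= 0:
        raise InvalidGeometryError("target input resistance must be positive")
    if min(Rm, soma_len) <= 0:
        raise InvalidGeometryError("Rm and soma length must be positive")
    area_cm2 = Rm * 1e3 / (target_RN * 1e6)
    return area_cm2 / (math.pi * soma_len * 1e-8)


def spine_neck_resistance(geom: SpineGeometry, Ra: float = 150.0) -> float:
    """Axial resistance of the spine neck in MOhm: 4*Ra*L / (pi*d^2)."""
    if geom.neck_diameter <= 0:
        raise InvalidGeometryError("neck diameter must be positive")
    if geom.neck_length < 0:
        raise InvalidGeometryError("neck length must be non-negative")
    r_ohm = (4.0 * Ra * geom.neck_length * 1e-4
             / (math.pi * (geom.neck_diameter * 1e-4) ** 2))
    return r_ohm / 1e6


def build_ball_and_stick(
    passive: PassiveParams | None = None,
    soma_diam: float = 718.0,
    soma_len: float = 23.0,
    dend_len: float = 200.0,
    dend_diam: float = 0.75,
    nseg: int = 50,
) -> Morphology:
    """Isopotential soma plus a single uniform dendrite.

    Defaults reproduce the reference configuration: a 200 um, 0.75 um
    dendrite in 50 electrical segments and a 718 um x 23 um soma whose
    diameter was enlarged to match the somatic input resistance of a full
    layer-5 pyramidal-cell model.
    """
    passive = passive or PassiveParams()
    soma = SectionSpec("soma", length=soma_len, diameter=soma_diam, nseg=1)
    dend = SectionSpec("b0", length=dend_len, diameter=dend_diam, nseg=nseg,
                       parent="soma", parent_position=1.0)
    return Morphology(soma=soma, sections=[dend], passive=passive)


def build_symmetric_tree(
    passive: PassiveParams | None = None,
    order: int = 3,
    branch_len: float = 50.0,
    nseg_per_branch: int = 10,
    soma_diam: float = 718.0,
    soma_len: float = 23.0,
    dend_diam: float = 0.75,
) -> Morphology:
    """Zero-order trunk plus a full binary tree of bifurcation depth ``order``.

    Section count is 2**(order+1) - 1 and every root-to-tip path length is
    (order+1)*branch_len. Branch names: trunk "b0", children suffixed
    "L"/"R" recursively, giving a deterministic depth-first ordering.
    """
    if order < 0:
        raise InvalidGeometryError("branching order must be >= 0")
    passive = passive or PassiveParams()
    soma = SectionSpec("soma", length=soma_len, diameter=soma_diam, nseg=1)
    sections: list[SectionSpec] = []

    def add(name: str, parent: str, depth: int):
        sections.append(
            SectionSpec(name, length=branch_len, diameter=dend_diam,
                        nseg=nseg_per_branch, parent=parent, parent_position=1.0)
        )
        if depth < order:
            add(name + "L", name, depth + 1)
            add(name + "R", name, depth + 1)

    add("b0", "soma", 0)
    return Morphology(soma=soma, sections=sections, spines=[], passive=passive)


def branch_order(section_name: str) -> int:
    """Depth of a branch in the symmetric tree: 'b0' -> 0, 'b0LR' -> 2."""
    if not section_name.startswith("b0"):
        raise KeyError(f"not a branch name: {section_name!r}")
    return len(section_name) - 2


def attach_spine(morph: Morphology, site: SpineSite) -> Morphology:
    """Return a new morphology with one more spine attached.

    The spine contributes two extra electrical compartments when the
    morphology is discretized: the neck cylinder and the head (equivalent
    cylinder with L = d). ``path_distance`` is recomputed from the tree.
    """
    sec = morph.section(site.section)  # raises KeyError for unknown section
    if sec is morph.soma and site.position != 0.0:
        site = replace(site, position=0.0)
    dist = morph.section_path_distance(site.section, site.position)
    site = replace(site, path_distance=dist)
    return Morphology(
        soma=morph.soma,
        sections=list(morph.sections),
        spines=[*morph.spines, site],
        passive=morph.passive,
    )


def path_distance(morph: Morphology, site: SpineSite) -> float:
    """Path distance (um) from soma center to the spine's attachment point."""
    return morph.section_path_distance(site.section, site.position)


# ---------------------------------------------------------------------------
# SWC exchange
# ---------------------------------------------------------------------------

_SWC_SOMA, _SWC_DEND = 1, 3


def _layout(morph: Morphology) -> dict[str, tuple[float, float]]:
    """Schematic 2D coordinates of each section's distal endpoint.

    Children fan out around the parent direction; distances along any path
    from the soma are preserved exactly (unit-speed polylines).
    """
    children: dict[str, list[str]] = {}
    for sec in morph.sections:
        children.setdefault(sec.parent, []).append(sec.name)
    coords: dict[str, tuple[float, float]] = {morph.soma.name: (0.0, 0.0)}
    angles: dict[str, float] = {morph.soma.name: math.pi / 2.0}

    def place(name: str, depth: int):
        sec = morph.section(name)
        px, py = coords[sec.parent]
        ang = angles[name]
        coords[name] = (px + sec.length * math.cos(ang),
                        py + sec.length * math.sin(ang))
        kids = sorted(children.get(name, []))
        spread = math.pi / (2.0 ** (depth + 1))
        for i, kid in enumerate(kids):
            off = (i - (len(kids) - 1) / 2.0) * spread
            angles[kid] = ang + off
            place(kid, depth + 1)

    for i, root_child in enumerate(sorted(children.get(morph.soma.name, []))):
        angles[root_child] = math.pi / 2.0 + (i - 0.0) * math.pi / 4.0
        place(root_child, 0)
    return coords


def to_swc(morph: Morphology) -> str:
    """Serialize the section tree to standard 7-column SWC text.

    One sample per section (its distal endpoint) plus one soma sample.
    Spines and per-section discretization are not representable in plain
    SWC; they are flattened to ``# dendroplast:`` comment annotations that
    :func:`from_swc` understands and other SWC readers ignore.
    """
    coords = _layout(morph)
    ids = {morph.soma.name: 1}
    lines = ["# SWC export (dendroplast); schematic 2D layout, z = 0"]
    lines.append(
        f"1 {_SWC_SOMA} 0.0 0.0 0.0 {morph.soma.diameter / 2.0:.6g} -1"
    )
    lines.append(f"# dendroplast: soma_length {morph.soma.length:.9g}")
    for sec in morph.sections:
        ids[sec.name] = len(ids) + 1
    for sec in morph.sections:
        x, y = coords[sec.name]
        lines.append(
            f"{ids[sec.name]} {_SWC_DEND} {x:.6f} {y:.6f} 0.0 "
            f"{sec.diameter / 2.0:.6g} {ids[sec.parent]}"
        )
        lines.append(
            f"# dendroplast: section {ids[sec.name]} name {sec.name} "
            f"nseg {sec.nseg} parent_position {sec.parent_position:.9g}"
        )
    for sp in morph.spines:
        lines.append(
            f"# dendroplast: spine {sp.section} {sp.position:.9g} "
            f"{int(sp.has_synapse)} {sp.onset if sp.onset is not None else 'none'}"
        )
    return "\n".join(lines) + "\n"


def from_swc(text: str, passive: PassiveParams | None = None) -> Morphology:
    """Rebuild a morphology from :func:`to_swc` output (or plain SWC).

    Plain SWC from other tools is accepted: consecutive samples are treated
    as single-segment sections named after their SWC index.
    """
    nodes: dict[int, tuple[int, float, float, float, float, int]] = {}
    meta_sections: dict[int, tuple[str, int, float]] = {}
    spines: list[tuple[str, float, bool, float | None]] = []
    soma_length = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*dendroplast:\s*(.*)", line)
            if m:
                parts = m.group(1).split()
                if parts[0] == "soma_length":
                    soma_length = float(parts[1])
                elif parts[0] == "section":
                    meta_sections[int(parts[1])] = (
                        parts[3], int(parts[5]), float(parts[7]))
                elif parts[0] == "spine":
                    onset = None if parts[4] == "none" else float(parts[4])
                    spines.append((parts[1], float(parts[2]),
                                   bool(int(parts[3])), onset))
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SWCParseError(f"expected 7 columns, got {len(fields)}", lineno)
        try:
            idx = int(fields[0])
            typ = int(fields[1])
            x, y, z, r = (float(v) for v in fields[2:6])
            parent = int(fields[6])
        except ValueError as exc:
            raise SWCParseError(str(exc), lineno) from None
        nodes[idx] = (typ, x, y, z, r, parent)

    soma_nodes = [i for i, n in nodes.items() if n[0] == _SWC_SOMA]
    if not soma_nodes:
        raise SWCParseError("no soma sample (type 1) found", 0)
    soma_idx = min(soma_nodes)
    styp, sx, sy, sz, sr, _ = nodes[soma_idx]
    soma = SectionSpec("soma", length=soma_length or 2 * sr,
                       diameter=2 * sr, nseg=1)
    name_of = {soma_idx: "soma"}
    sections: list[SectionSpec] = []
    for idx in sorted(n for n in nodes if n != soma_idx):
        typ, x, y, z, r, parent = nodes[idx]
        if parent not in name_of:
            raise SWCParseError(f"node {idx} has unknown parent {parent}", 0)
        px, py, pz = ((sx, sy, sz) if parent == soma_idx
                      else nodes[parent][1:4])
        if parent == soma_idx:
            length = math.hypot(x - px, y - py)
        else:
            length = math.sqrt((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2)
        name, nseg, ppos = meta_sections.get(idx, (f"sec{idx}", 1, 1.0))
        name_of[idx] = name
        sections.append(SectionSpec(name, length=length, diameter=2 * r,
                                    nseg=nseg, parent=name_of[parent],
                                    parent_position=ppos))
    morph = Morphology(soma=soma, sections=sections,
                       passive=passive or PassiveParams())
    for sec_name, pos, has_syn, onset in spines:
        morph = attach_spine(morph, SpineSite(section=sec_name, position=pos,
                                              has_synapse=has_syn, onset=onset))
    return morph
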