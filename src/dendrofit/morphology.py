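"""Neuronal morphologies: SWC I/O, a synthetic reduced L5b cell, and
discretization into electrical compartments.

A :class:`Morphology` is a tree of unbranched sections, each an ordered
run of 3-D points with diameters and a region label (soma, axon_initial,
basal, apical).  Reconstructed cells are read from standard 7-column SWC;
because the spike-initiation zone is collapsed into a perisomatic
compartment, everything distal to the initial axon segment is discarded
on load.

:func:`compartmentalize` splits every section into equal-length pieces no
longer than ``max_len`` (20 um by default, giving on the order of 200
compartments for a full reconstruction), computes membrane areas as
frustum lateral surfaces, and assembles symmetric axial conductances in
parent-before-child (Hines) order for the cable solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Region",
    "Section",
    "Morphology",
    "CompartmentalCell",
    "SyntheticCellSpec",
    "SWCParseError",
    "load_swc",
    "write_swc",
    "build_synthetic_l5b",
    "compartmentalize",
    "path_distance",
    "REGIONS",
]

REGIONS = ("soma", "axon_initial", "basal", "apical")
_SWC_TYPE_TO_REGION = {1: "soma", 2: "axon_initial", 3: "basal", 4: "apical"}
_REGION_TO_SWC_TYPE = {v: k for k, v in _SWC_TYPE_TO_REGION.items()}

Region = str


class SWCParseError(ValueError):
    """Raised for malformed or structurally invalid SWC input."""


@dataclass
class Section:
    """An unbranched neurite piece: ordered 3-D points and diameters."""

    region: Region
    points: np.ndarray  # (n, 3) um
    diams: np.ndarray  # (n,) um
    parent: int | None  # index of parent section, None for the root soma

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.diams = np.asarray(self.diams, dtype=float).ravel()
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if len(self.points) != len(self.diams):
            raise ValueError("points and diameters length mismatch")
        if np.any(self.diams <= 0):
            raise ValueError("diameters must be positive")

    @property
    def seg_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length(self) -> float:
        return float(self.seg_lengths.sum())

    @property
    def frustum_area(self) -> float:
        """Lateral surface of the stack of frusta defined by the points."""
        r = self.diams / 2.0
        ds = self.seg_lengths
        slant = np.sqrt(ds**2 + np.diff(r) ** 2)
        return float(np.sum(math.pi * (r[:-1] + r[1:]) * slant))


@dataclass
class Morphology:
    """A labeled section tree rooted at the soma."""

    sections: list[Section]
    identifier: str = ""

    def __post_init__(self):
        roots = [i for i, s in enumerate(self.sections) if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"morphology must have exactly one root, found {len(roots)}")
        if self.sections[roots[0]].region != "soma":
            raise ValueError("root section must be the soma")
        for i, s in enumerate(self.sections):
            if s.parent is not None and not (0 <= s.parent < i):
                raise ValueError("sections must be ordered parent-before-child (acyclic)")

    @property
    def root(self) -> int:
        return next(i for i, s in enumerate(self.sections) if s.parent is None)

    @property
    def soma_center(self) -> np.ndarray:
        s = self.sections[self.root]
        return s.points.mean(axis=0)

    def children(self, idx: int) -> list[int]:
        return [i for i, s in enumerate(self.sections) if s.parent == idx]

    def section_start_distance(self, idx: int) -> float:
        """Arc length from the soma center to the start of a section.

        The soma itself contributes zero extent: neurites attached to the
        soma start at path distance 0.
        """
        d = 0.0
        while True:
            sec = self.sections[idx]
            if sec.parent is None:
                return d
            if self.sections[sec.parent].region == "soma":
                return d
            idx = sec.parent
            d += self.sections[idx].length

    def region_area(self, region: Region) -> float:
        if region == "soma":
            return soma_area(self.sections[self.root])
        return sum(s.frustum_area for s in self.sections if s.region == region)

    def total_length(self, region: Region | None = None) -> float:
        return sum(s.length for s in self.sections
                   if s.parent is not None and (region is None or s.region == region))

    def locate(self, region: Region, distance: float) -> tuple[int, float]:
        """Find ``(section index, arc fraction)`` at a path distance (um).

        When several branches reach the requested distance the first one
        in section order is returned (for the synthetic cell this is the
        first tuft branch).
        """
        if distance == 0.0:
            return self.root, 0.5
        for i, s in enumerate(self.sections):
            if s.region != region or s.parent is None:
                continue
            d0 = self.section_start_distance(i)
            if d0 - 1e-9 <= distance <= d0 + s.length + 1e-9:
                frac = min(max((distance - d0) / s.length, 0.0), 1.0)
                return i, frac
        raise LookupError(f"no {region} point at path distance {distance} um")


def soma_area(sec: Section) -> float:
    """Membrane area of the soma from its point set.

    A single-point soma follows the SWC sphere convention (area pi*d^2);
    a multi-point outline is treated as a cylinder-equivalent stack of
    frusta plus the two end caps' mean-radius disks are ignored, matching
    the frustum rule used for neurites.
    """
    if len(sec.points) == 1:
        return math.pi * sec.diams[0] ** 2
    return sec.frustum_area


def path_distance(m: Morphology, point: tuple[int, float]) -> float:
    """Arc length (um) from the soma center to ``(section, fraction)``."""
    idx, frac = point
    if not (0 <= idx < len(m.sections)):
        raise LookupError("section index off the morphology")
    if not (0.0 <= frac <= 1.0):
        raise LookupError("arc fraction must lie in [0, 1]")
    sec = m.sections[idx]
    if sec.region == "soma":
        return 0.0
    return m.section_start_distance(idx) + frac * sec.length


# --------------------------------------------------------------------------
# SWC reader / writer
# --------------------------------------------------------------------------

def load_swc(path: str | Path, axon_initial_max_len: float = 60.0) -> Morphology:
    """Read a 7-column SWC reconstruction.

    SWC type codes map 1 -> soma, 2 -> axon_initial, 3 -> basal,
    4 -> apical.  The axon is reduced to its initial segment: only the
    first unbranched axonal piece is kept, truncated to
    ``axon_initial_max_len`` um.
    """
    path = Path(path)
    nodes: dict[int, tuple[int, float, float, float, float, int]] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(f"{path.name}:{ln}: expected 7 columns, got {len(parts)}")
        try:
            nid, ntype = int(parts[0]), int(parts[1])
            x, y, z, r = map(float, parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCParseError(f"{path.name}:{ln}: malformed record: {exc}") from None
        if ntype not in _SWC_TYPE_TO_REGION:
            raise SWCParseError(f"{path.name}:{ln}: unknown SWC type code {ntype}")
        if r <= 0:
            raise SWCParseError(f"{path.name}:{ln}: non-positive radius")
        if nid in nodes:
            raise SWCParseError(f"{path.name}:{ln}: duplicate node id {nid}")
        nodes[nid] = (ntype, x, y, z, r, parent)
    if not nodes:
        raise SWCParseError(f"{path.name}: empty SWC file")

    roots = [nid for nid, n in nodes.items() if n[5] == -1]
    if len(roots) != 1:
        raise SWCParseError(f"{path.name}: expected one root node, found {len(roots)}")
    root = roots[0]
    if nodes[root][0] != 1:
        raise SWCParseError(f"{path.name}: root node must be soma (type 1)")
    for nid, n in nodes.items():
        if n[5] != -1 and n[5] not in nodes:
            raise SWCParseError(f"{path.name}: node {nid} references missing parent {n[5]}")

    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    for nid, n in nodes.items():
        if n[5] != -1:
            children[n[5]].append(nid)

    # soma = the connected run of type-1 nodes containing the root
    soma_ids = [root]
    stack = [root]
    while stack:
        cur = stack.pop()
        for c in children[cur]:
            if nodes[c][0] == 1:
                soma_ids.append(c)
                stack.append(c)
    soma_pts = np.array([[nodes[i][1], nodes[i][2], nodes[i][3]] for i in soma_ids])
    soma_diams = np.array([2 * nodes[i][4] for i in soma_ids])
    sections = [Section("soma", soma_pts, soma_diams, None)]

    # walk neurites: a section ends at a branch point, a type change, or a tip
    def neurite_starts():
        for sid in soma_ids:
            for c in children[sid]:
                if nodes[c][0] != 1:
                    yield c, 0  # attached to soma -> parent section 0

    section_of_node: dict[int, int] = {}
    queue = list(neurite_starts())
    while queue:
        start, parent_sec = queue.pop(0)
        ntype = nodes[start][0]
        run = [start]
        cur = start
        while True:
            kids = children[cur]
            same = [k for k in kids if nodes[k][0] == ntype]
            if len(kids) == 1 and len(same) == 1:
                cur = same[0]
                run.append(cur)
            else:
                break
        # prepend the attachment point so the section is geometrically anchored
        pnode = nodes[start][5]
        if nodes[pnode][0] == 1:
            anchor_xyz = [nodes[pnode][1], nodes[pnode][2], nodes[pnode][3]]
            anchor_diam = 2 * nodes[start][4]  # do not taper from the fat soma
        else:
            anchor_xyz = [nodes[pnode][1], nodes[pnode][2], nodes[pnode][3]]
            anchor_diam = 2 * nodes[pnode][4]
        pts = np.array([anchor_xyz] + [[nodes[i][1], nodes[i][2], nodes[i][3]] for i in run])
        diams = np.array([anchor_diam] + [2 * nodes[i][4] for i in run])
        region = _SWC_TYPE_TO_REGION[ntype]
        sections.append(Section(region, pts, diams, parent_sec))
        sec_idx = len(sections) - 1
        for i in run:
            section_of_node[i] = sec_idx
        for k in children[run[-1]]:
            if nodes[k][0] != 1:
                queue.append((k, sec_idx))

    morph = Morphology(sections, identifier=path.stem)
    return _reduce_axon(morph, axon_initial_max_len)


def _reduce_axon(m: Morphology, max_len: float) -> Morphology:
    """Keep only the initial axon segment, deleting the rest of the axon."""
    keep: list[int] = []
    first_axon_done = False
    remap: dict[int, int] = {}
    sections: list[Section] = []
    for i, s in enumerate(m.sections):
        if s.region == "axon_initial":
            parent_is_soma = s.parent is not None and m.sections[s.parent].region == "soma"
            if first_axon_done or not parent_is_soma:
                continue
            first_axon_done = True
            s = _truncate_section(s, max_len)
        if s.parent is not None and s.parent not in remap:
            continue  # parent was an excised axonal piece
        remap[i] = len(sections)
        sections.append(Section(s.region, s.points.copy(), s.diams.copy(),
                                None if s.parent is None else remap[s.parent]))
    return Morphology(sections, identifier=m.identifier)


def _truncate_section(s: Section, max_len: float) -> Section:
    if s.length <= max_len:
        return s
    ds = s.seg_lengths
    cum = np.concatenate([[0.0], np.cumsum(ds)])
    last = int(np.searchsorted(cum, max_len))
    frac = (max_len - cum[last - 1]) / ds[last - 1]
    cut_pt = s.points[last - 1] + frac * (s.points[last] - s.points[last - 1])
    cut_d = s.diams[last - 1] + frac * (s.diams[last] - s.diams[last - 1])
    pts = np.vstack([s.points[:last], cut_pt])
    diams = np.concatenate([s.diams[:last], [cut_d]])
    return Section(s.region, pts, diams, s.parent)


def write_swc(m: Morphology, path: str | Path) -> None:
    """Write a morphology back to 7-column SWC."""
    path = Path(path)
    lines = ["# generated by dendrofit"]
    next_id = 1
    last_node_of_section: dict[int, int] = {}
    root = m.root
    soma = m.sections[root]
    soma_node_ids = []
    for j in range(len(soma.points)):
        parent = -1 if j == 0 else soma_node_ids[j - 1]
        x, y, z = soma.points[j]
        lines.append(f"{next_id} 1 {x:.6f} {y:.6f} {z:.6f} {soma.diams[j] / 2:.6f} {parent}")
        soma_node_ids.append(next_id)
        next_id += 1
    last_node_of_section[root] = soma_node_ids[0]
    soma_coords = soma.points
    for i, s in enumerate(m.sections):
        if i == root:
            continue
        t = _REGION_TO_SWC_TYPE[s.region]
        if s.parent == root:
            # attach to the soma node nearest the neurite's origin so the
            # anchor geometry survives a round trip
            d2 = np.sum((soma_coords - s.points[0]) ** 2, axis=1)
            parent_node = soma_node_ids[int(np.argmin(d2))]
        else:
            parent_node = last_node_of_section[s.parent]
        # skip the anchor point (duplicated from the parent) on output
        for j in range(1, len(s.points)):
            x, y, z = s.points[j]
            lines.append(f"{next_id} {t} {x:.6f} {y:.6f} {z:.6f} {s.diams[j] / 2:.6f} {parent_node}")
            parent_node = next_id
            next_id += 1
        last_node_of_section[i] = parent_node
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# synthetic reduced L5b morphology
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCellSpec:
    """Geometry of the reduced thick-tufted L5b cell.

    Defaults follow the reference cell used throughout: the main apical
    bifurcation sits 650 um from the soma and the primary tuft ends near
    950 um, so the distal Ca2+ "hot" zone [685, 885] um spans the region
    just distal to the bifurcation.
    """

    bifurcation_distance: float = 650.0  # um, soma to main apical bifurcation
    trunk_length: float | None = None  # alias; must equal bifurcation_distance if set
    tuft_length: float = 300.0  # um per tuft branch
    n_basal: int = 8
    basal_length: float = 250.0  # um
    n_oblique: int = 8  # apical oblique side branches along the trunk
    oblique_length: float = 300.0  # um
    oblique_span: tuple[float, float] = (150.0, 600.0)  # attachment range, um
    soma_length: float = 25.0  # um
    soma_diam: float = 20.0  # um
    axon_length: float = 60.0  # um initial-segment stub
    trunk_diam: tuple[float, float] = (5.5, 2.0)  # proximal, distal taper
    tuft_diam: tuple[float, float] = (2.5, 1.0)
    basal_diam: tuple[float, float] = (2.0, 0.8)
    oblique_diam: tuple[float, float] = (2.0, 0.8)
    axon_diam: tuple[float, float] = (1.75, 1.0)
    point_spacing: float = 10.0  # um between consecutive points

    def validate(self) -> None:
        if self.bifurcation_distance <= 0 or self.tuft_length <= 0:
            raise ValueError("apical lengths must be positive")
        if self.trunk_length is not None and self.trunk_length != self.bifurcation_distance:
            raise ValueError("trunk_length, when given, must equal bifurcation_distance "
                             "(the trunk runs from the soma to the main bifurcation)")
        if self.n_basal < 0 or (self.n_basal > 0 and self.basal_length <= 0):
            raise ValueError("invalid basal specification")
        if self.n_oblique < 0 or (self.n_oblique > 0 and self.oblique_length <= 0):
            raise ValueError("invalid oblique specification")
        if self.n_oblique > 0 and not (0 < self.oblique_span[0] < self.oblique_span[1]
                                       < self.bifurcation_distance):
            raise ValueError("oblique attachment span must lie within the trunk")
        if self.soma_length <= 0 or self.soma_diam <= 0 or self.axon_length <= 0:
            raise ValueError("soma/axon geometry must be positive")
        for lo_hi in (self.trunk_diam, self.tuft_diam, self.basal_diam, self.axon_diam):
            if min(lo_hi) <= 0:
                raise ValueError("diameters must be positive")
        if self.point_spacing <= 0:
            raise ValueError("point spacing must be positive")


def _straight_run(origin, direction, length, diams, spacing):
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    n = max(int(math.ceil(length / spacing)), 1)
    s = np.linspace(0.0, length, n + 1)
    pts = origin[None, :] + s[:, None] * direction[None, :]
    d = diams[0] + (diams[1] - diams[0]) * s / length
    return pts, d


def build_synthetic_l5b(spec: SyntheticCellSpec | None = None, seed: int = 0,
                        **overrides) -> Morphology:
    """Build the synthetic reduced L5b morphology.

    Deterministic for a given spec and seed; the seed only randomizes the
    azimuthal directions of the basal dendrites, never any path length.
    """
    if spec is None:
        spec = SyntheticCellSpec(**overrides)
    elif overrides:
        raise ValueError("pass either a spec or keyword overrides, not both")
    spec.validate()
    rng = np.random.default_rng(seed)

    half = spec.soma_length / 2.0
    soma_pts = np.array([[0.0, -half, 0.0], [0.0, 0.0, 0.0], [0.0, half, 0.0]])
    soma_diams = np.array([spec.soma_diam] * 3)
    sections = [Section("soma", soma_pts, soma_diams, None)]
    top = np.array([0.0, half, 0.0])
    bottom = np.array([0.0, -half, 0.0])

    # axon initial-segment stub, pointing down
    pts, d = _straight_run(bottom, [0.0, -1.0, 0.0], spec.axon_length,
                           spec.axon_diam, spec.point_spacing)
    sections.append(Section("axon_initial", pts, d, 0))

    # apical trunk up to the main bifurcation, split at oblique attachments
    if spec.n_oblique > 0:
        attach = list(np.linspace(spec.oblique_span[0], spec.oblique_span[1],
                                  spec.n_oblique))
    else:
        attach = []
    breakpoints = [0.0] + attach + [spec.bifurcation_distance]
    d0, d1 = spec.trunk_diam
    parent_idx = 0
    oblique_parents = []
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        origin = top + np.array([0.0, a, 0.0])
        diams = (d0 + (d1 - d0) * a / spec.bifurcation_distance,
                 d0 + (d1 - d0) * b / spec.bifurcation_distance)
        pts, d = _straight_run(origin, [0.0, 1.0, 0.0], b - a, diams,
                               spec.point_spacing)
        sections.append(Section("apical", pts, d, parent_idx))
        parent_idx = len(sections) - 1
        if b in attach:
            oblique_parents.append((parent_idx, pts[-1]))
    trunk_idx = parent_idx
    trunk_end = top + np.array([0.0, spec.bifurcation_distance, 0.0])

    # two tuft branches
    for sign in (+1.0, -1.0):
        ang = math.radians(25.0)
        direction = [sign * math.sin(ang), math.cos(ang), 0.0]
        pts, d = _straight_run(trunk_end, direction, spec.tuft_length,
                               spec.tuft_diam, spec.point_spacing)
        sections.append(Section("apical", pts, d, trunk_idx))

    # oblique side branches, alternating laterally off the trunk
    for k, (pidx, origin) in enumerate(oblique_parents):
        phi = 2.0 * math.pi * (k + rng.uniform(0.0, 1.0)) / max(len(oblique_parents), 1)
        direction = [math.cos(phi), 0.35, math.sin(phi)]
        pts, d = _straight_run(origin, direction, spec.oblique_length,
                               spec.oblique_diam, spec.point_spacing)
        sections.append(Section("apical", pts, d, pidx))

    # basal dendrites fanning into the lower hemisphere
    for k in range(spec.n_basal):
        phi = 2.0 * math.pi * (k + rng.uniform(0.0, 1.0)) / max(spec.n_basal, 1)
        tilt = math.radians(35.0 + 20.0 * rng.uniform(0.0, 1.0))
        direction = [math.cos(phi) * math.sin(tilt), -math.cos(tilt),
                     math.sin(phi) * math.sin(tilt)]
        pts, d = _straight_run(bottom, direction, spec.basal_length,
                               spec.basal_diam, spec.point_spacing)
        sections.append(Section("basal", pts, d, 0))

    return Morphology(sections, identifier=f"synthetic_l5b_seed{seed}")


# --------------------------------------------------------------------------
# compartmentalization
# --------------------------------------------------------------------------

@dataclass
class CompartmentalCell:
    """Discretized cable in Hines (parent-before-child) order.

    Index 0 is the isopotential soma.  ``g_axial[i]`` couples compartment
    ``i`` to ``parent[i]`` (uS, symmetric by construction).
    """

    region: np.ndarray  # (n,) int codes indexing REGIONS
    parent: np.ndarray  # (n,) int, -1 for the soma
    length: np.ndarray  # (n,) um
    area: np.ndarray  # (n,) um^2
    path_dist: np.ndarray  # (n,) um at the compartment center
    g_axial: np.ndarray  # (n,) uS to parent; 0 for the soma
    section_of: np.ndarray  # (n,) originating section index
    morphology: Morphology = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.region)

    def region_mask(self, region: Region) -> np.ndarray:
        return self.region == REGIONS.index(region)

    def total_area(self, region: Region | None = None) -> float:
        if region is None:
            return float(self.area.sum())
        return float(self.area[self.region_mask(region)].sum())

    def index_at(self, region: Region, distance: float) -> int:
        """Compartment whose center is nearest a path distance in a region.

        Sites are resolved through the section tree first, so that on
        the main apical path (trunk, then first tuft branch) a distance
        never lands on an oblique side branch.
        """
        mask = self.region_mask(region)
        if not mask.any():
            raise LookupError(f"no {region} compartments")
        try:
            sec_idx, _ = self.morphology.locate(region, distance)
            idx = np.flatnonzero(self.section_of == sec_idx)
        except LookupError:
            idx = np.flatnonzero(mask)
        return int(idx[np.argmin(np.abs(self.path_dist[idx] - distance))])


def _section_profile(sec: Section):
    """Cumulative arc length and radius at each stored point."""
    cum = np.concatenate([[0.0], np.cumsum(sec.seg_lengths)])
    return cum, sec.diams / 2.0


def _integrate_area(cum, radii, a, b) -> float:
    """Frustum lateral area of the piecewise-linear profile over [a, b]."""
    total = 0.0
    for i in range(len(cum) - 1):
        lo, hi = max(a, cum[i]), min(b, cum[i + 1])
        if hi <= lo:
            continue
        seg = cum[i + 1] - cum[i]
        slope = (radii[i + 1] - radii[i]) / seg
        r_lo = radii[i] + slope * (lo - cum[i])
        r_hi = radii[i] + slope * (hi - cum[i])
        ds = hi - lo
        total += math.pi * (r_lo + r_hi) * math.sqrt(ds * ds + (r_hi - r_lo) ** 2)
    return total


def _integrate_axial_resistance(cum, radii, a, b, ra_ohm_cm) -> float:
    """Axial resistance (MOhm) of the profile over [a, b]; exact for a
    linear taper (R = Ra * L / (pi * r0 * r1))."""
    total = 0.0
    for i in range(len(cum) - 1):
        lo, hi = max(a, cum[i]), min(b, cum[i + 1])
        if hi <= lo:
            continue
        seg = cum[i + 1] - cum[i]
        slope = (radii[i + 1] - radii[i]) / seg
        r_lo = radii[i] + slope * (lo - cum[i])
        r_hi = radii[i] + slope * (hi - cum[i])
        ds = hi - lo
        # Ra in Ohm*cm, lengths in um: Ohm*cm*um/um^2 = 1e4 Ohm -> 1e-2 MOhm
        total += 1e-2 * ra_ohm_cm * ds / (math.pi * r_lo * r_hi)
    return total


def compartmentalize(m: Morphology, max_len: float = 20.0,
                     ra_ohm_cm: float = 100.0) -> CompartmentalCell:
    """Split every section into ceil(L/max_len) equal compartments.

    The soma becomes a single isopotential compartment; its own axial
    resistance is neglected (it is electrically fat compared to any
    neurite), so a neurite's coupling to the soma uses only the neurite's
    proximal half-compartment resistance.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    root = m.root
    regions = [REGIONS.index("soma")]
    parents = [-1]
    lengths = [m.sections[root].length]
    areas = [soma_area(m.sections[root])]
    dists = [0.0]
    g_ax = [0.0]
    section_of = [root]
    half_r_distal: dict[int, float] = {}  # section -> MOhm of its last half-compartment
    last_comp_of_section: dict[int, int] = {root: 0}

    for i, sec in enumerate(m.sections):
        if i == root:
            continue
        cum, radii = _section_profile(sec)
        L = sec.length
        ncomp = max(int(math.ceil(L / max_len)), 1)
        dx = L / ncomp
        d0 = m.section_start_distance(i)
        parent_sec = sec.parent
        prev_comp = last_comp_of_section[parent_sec]
        prev_half_r = 0.0 if m.sections[parent_sec].region == "soma" \
            else half_r_distal[parent_sec]
        for j in range(ncomp):
            a, b = j * dx, (j + 1) * dx
            mid = 0.5 * (a + b)
            area = _integrate_area(cum, radii, a, b)
            r_prox = _integrate_axial_resistance(cum, radii, a, mid, ra_ohm_cm)
            r_dist = _integrate_axial_resistance(cum, radii, mid, b, ra_ohm_cm)
            regions.append(REGIONS.index(sec.region))
            parents.append(prev_comp)
            lengths.append(dx)
            areas.append(area)
            dists.append(d0 + mid)
            g_ax.append(1.0 / (r_prox + prev_half_r))  # MOhm^-1 == uS
            section_of.append(i)
            prev_comp = len(regions) - 1
            prev_half_r = r_dist
        half_r_distal[i] = prev_half_r
        last_comp_of_section[i] = prev_comp

    return CompartmentalCell(
        region=np.array(regions, dtype=np.int64),
        parent=np.array(parents, dtype=np.int64),
        length=np.array(lengths, dtype=float),
        area=np.array(areas, dtype=float),
        path_dist=np.array(dists, dtype=float),
        g_axial=np.array(g_ax, dtype=float),
        section_of=np.array(section_of, dtype=np.int64),
        morphology=m,
    )
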