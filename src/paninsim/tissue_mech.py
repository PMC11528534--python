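"""Voronoi tessellation of the acinar-ductal domain and elastic relaxation.

The tissue is a set of generator points inside a planar domain.  Cell
shapes are the Voronoi regions clipped to the domain; boundedness is
obtained by mirroring all generators across the four sides of the domain's
bounding box, so every original region is finite before clipping.

The elastic energy is the standard two-term vertex-model polynomial

    E = sum_i [ 1/2 Kv (A_i - A0_i)^2 + 1/2 Kc (P_i - P0_i)^2 ]

with the preferred perimeter ``P0`` tied to the preferred area through the
regular-hexagon isoperimetric ratio.  Forces are the negative energy
gradient, computed either by central finite differences through the
tessellation (exact but O(N) tessellations per evaluation) or by a fast
pairwise-spring approximation used in large scenario runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal as TLiteral

import numpy as np
import shapely
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import LineString, Point, Polygon, box

__all__ = [
    "TissueDomain",
    "MechanicsParams",
    "CellBody",
    "Tessellation",
    "TissueState",
    "build_voronoi",
    "elastic_energy",
    "forces",
    "relax",
    "hexagon_perimeter",
    "RelaxResult",
]

_SQRT3 = math.sqrt(3.0)


def hexagon_perimeter(area: float) -> float:
    """Perimeter of the regular hexagon with the given area."""
    side = math.sqrt(2.0 * area / (3.0 * _SQRT3))
    return 6.0 * side


# ---------------------------------------------------------------------------
# Domain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueDomain:
    """Planar simulation domain with a duct axis.

    Two parametric kinds are built in.  ``rectangle`` spans
    ``[x0, x0 + duct_length] x [0, width]`` with the duct mouth on the left
    edge.  ``u_shape`` is a duct channel of width ``channel_width`` opening
    into a circular acinar bulb of radius ``bulb_radius`` at the far end.
    Duct elongation extends the mouth end leftwards, leaving cells in place.
    """

    kind: TLiteral["rectangle", "u_shape"] = "rectangle"
    duct_length: float = 1.0
    width: float = 1.0
    channel_width: float = 0.5
    bulb_radius: float = 0.75
    x0: float = 0.0

    def __post_init__(self):
        if self.duct_length <= 0 or self.width <= 0:
            raise ValueError("domain dimensions must be positive")

    @property
    def polygon(self) -> Polygon:
        if self.kind == "rectangle":
            return box(self.x0, 0.0, self.x0 + self.duct_length, self.width)
        if self.kind == "u_shape":
            yc = self.width / 2.0
            hw = self.channel_width / 2.0
            channel = box(self.x0, yc - hw, self.x0 + self.duct_length, yc + hw)
            bulb = Point(self.x0 + self.duct_length, yc).buffer(self.bulb_radius, quad_segs=24)
            poly = channel.union(bulb)
            if not poly.is_valid:
                raise ValueError("invalid u-shape outline")
            return poly
        raise ValueError(f"unknown domain kind {self.kind!r}")

    @property
    def duct_axis(self) -> tuple[tuple[float, float], tuple[float, float]]:
        yc = self.width / 2.0
        return ((self.x0, yc), (self.x0 + self.duct_length, yc))

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def is_convex(self) -> bool:
        return self.kind == "rectangle"

    def elongate(self, delta: float) -> "TissueDomain":
        """Extend the duct mouth leftwards by ``delta``."""
        if delta < 0:
            raise ValueError("elongation must be non-negative")
        new = replace(self, x0=self.x0 - delta, duct_length=self.duct_length + delta)
        if not new.polygon.is_valid:
            raise ValueError("elongation produced a self-intersecting boundary")
        return new

    def duct_mouth_x(self) -> float:
        return self.x0


@dataclass(frozen=True)
class MechanicsParams:
    """Elastic constants and relaxation controls (defaults as published)."""

    Kc: float = 0.3  # perimeter stiffness
    Kv: float = 0.06  # area stiffness
    k_friction: float = 0.001
    force_tolerance: float = 1e-4
    max_relax_time: float = 12.0  # one basal cycle in model-time units
    fd_step: float = 1e-6  # finite-difference step, relative to domain diameter
    spring_stiffness: float = 1.0
    method: TLiteral["fd", "spring"] = "fd"

    def __post_init__(self):
        for f in ("Kc", "Kv", "k_friction", "force_tolerance", "max_relax_time", "fd_step", "spring_stiffness"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# Tessellation
# ---------------------------------------------------------------------------


@dataclass
class Tessellation:
    """Clipped Voronoi diagram of the tissue generators."""

    vertices: list[np.ndarray]  # per cell, (k, 2) polygon vertices (ccw)
    areas: np.ndarray
    perimeters: np.ndarray
    centroids: np.ndarray
    edges: np.ndarray  # (E, 2) adjacent cell index pairs
    edge_lengths: np.ndarray  # shared-edge length per pair
    edge_distances: np.ndarray  # centroid distance per pair

    @property
    def n_cells(self) -> int:
        return len(self.vertices)

    def polygons(self) -> list[Polygon]:
        return [Polygon(v) for v in self.vertices]

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_cells)]
        for i, j in self.edges:
            adj[i].append(int(j))
            adj[j].append(int(i))
        return adj


def _shoelace(verts: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Area, perimeter and centroid of a simple polygon."""
    rolled = np.empty_like(verts)
    rolled[:-1] = verts[1:]
    rolled[-1] = verts[0]
    x, y = verts[:, 0], verts[:, 1]
    xr, yr = rolled[:, 0], rolled[:, 1]
    cross = x * yr - xr * y
    a2 = cross.sum()
    area = 0.5 * a2
    d = rolled - verts
    per = float(np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2).sum())
    if abs(a2) < 1e-300:
        return 0.0, per, verts.mean(axis=0)
    cx = ((x + xr) * cross).sum() / (3.0 * a2)
    cy = ((y + yr) * cross).sum() / (3.0 * a2)
    return float(area), per, np.array([cx, cy])


def build_voronoi(points: np.ndarray, domain: TissueDomain) -> Tessellation:
    """Clipped Voronoi tessellation with adjacency.

    Points must lie strictly inside the domain and be pairwise distinct;
    duplicates are separated by a tiny deterministic jitter.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    n = len(pts)
    if n < 1:
        raise ValueError("need at least one point")
    poly = domain.polygon
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    if not inside.all():
        bad = np.where(~inside)[0]
        raise ValueError(f"points outside domain: indices {bad.tolist()}")

    if n > 1:
        tree = cKDTree(pts)
        close = tree.query_pairs(1e-12, output_type="ndarray")
        if len(close):
            rng = np.random.default_rng(12345)
            for _, j in close:
                pts[j] += rng.normal(0.0, 1e-9, size=2)

    minx, miny, maxx, maxy = poly.bounds
    if n == 1:
        # single generator owns the whole domain
        verts = np.asarray(poly.exterior.coords)[:-1]
        area, per, cen = _shoelace(verts)
        return Tessellation(
            [verts], np.array([abs(area)]), np.array([per]), cen[None, :],
            np.empty((0, 2), dtype=int), np.empty(0), np.empty(0),
        )

    need_clip = not domain.is_convex
    if not need_clip:
        # rectangle: mirroring across the four sides bounds every original
        # region exactly at the domain edge, so no clipping is needed
        mirrors = []
        for refl in (
            lambda p: np.column_stack([2 * minx - p[:, 0], p[:, 1]]),
            lambda p: np.column_stack([2 * maxx - p[:, 0], p[:, 1]]),
            lambda p: np.column_stack([p[:, 0], 2 * miny - p[:, 1]]),
            lambda p: np.column_stack([p[:, 0], 2 * maxy - p[:, 1]]),
        ):
            mirrors.append(refl(pts))
        allpts = np.vstack([pts] + mirrors)
    else:
        # general polygon: distant ghost generators bound the regions; the
        # original regions partition the plane, so clipping to the domain
        # yields an exact partition even for concave outlines
        cx, cy = 0.5 * (minx + maxx), 0.5 * (miny + maxy)
        radius = 50.0 * math.hypot(maxx - minx, maxy - miny)
        ang = np.linspace(0.0, 2.0 * math.pi, 8, endpoint=False)
        ghosts = np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])
        allpts = np.vstack([pts, ghosts])
    vor = Voronoi(allpts)
    verts_list: list[np.ndarray] = []
    polys: list[Polygon | None] = [None] * n
    orphans: list[Polygon] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:  # should not happen with bounding generators
            raise RuntimeError("unbounded region despite bounding construction")
        verts = vor.vertices[region]
        # ensure counter-clockwise ordering
        c = verts.mean(axis=0)
        ang = np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0])
        verts = verts[np.argsort(ang)]
        if need_clip:
            clipped = Polygon(verts).intersection(poly)
            if clipped.geom_type == "MultiPolygon":
                # a convex region meeting a concave outline can fragment;
                # the cell is the piece holding its generator, the rest is
                # reassigned to neighbours below
                gen = Point(pts[i])
                pieces = sorted(clipped.geoms, key=lambda g: g.distance(gen))
                clipped = pieces[0]
                orphans.extend(pieces[1:])
            elif clipped.is_empty or clipped.geom_type != "Polygon":
                raise RuntimeError(f"cell {i} clipped away entirely")
            polys[i] = clipped
        verts_list.append(verts)

    if need_clip and orphans:
        for orphan in orphans:
            shared = [orphan.intersection(polys[j].exterior).length for j in range(n)]
            k = int(np.argmax(shared))
            merged = polys[k].union(orphan)
            if merged.geom_type == "MultiPolygon":
                merged = max(merged.geoms, key=lambda g: g.area)
            polys[k] = merged

    areas = np.empty(n)
    pers = np.empty(n)
    cents = np.empty((n, 2))
    for i in range(n):
        verts = verts_list[i]
        if need_clip:
            verts = np.asarray(polys[i].exterior.coords)[:-1]
        area, per, cen = _shoelace(verts)
        if area < 0:
            verts = verts[::-1]
            area = -area
        verts_list[i] = verts
        areas[i] = area
        pers[i] = per
        cents[i] = cen

    # adjacency between original generators from Voronoi ridges
    pairs = []
    lengths = []
    for (p1, p2), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if p1 >= n or p2 >= n or -1 in rv:
            continue
        v1, v2 = vor.vertices[rv[0]], vor.vertices[rv[1]]
        if need_clip:
            seg = LineString([v1, v2]).intersection(poly)
            length = seg.length
        else:
            length = float(np.hypot(*(v2 - v1)))
        if length > 1e-12:
            pairs.append((min(p1, p2), max(p1, p2)))
            lengths.append(length)
    edges = np.array(pairs, dtype=int) if pairs else np.empty((0, 2), dtype=int)
    edge_lengths = np.array(lengths)
    if len(edges):
        dvec = cents[edges[:, 0]] - cents[edges[:, 1]]
        edge_dist = np.hypot(dvec[:, 0], dvec[:, 1])
    else:
        edge_dist = np.empty(0)
    return Tessellation(verts_list, areas, pers, cents, edges, edge_lengths, edge_dist)


# ---------------------------------------------------------------------------
# Tissue state
# ---------------------------------------------------------------------------

LINEAGE_HEALTHY = 0
LINEAGE_CANCER = 1
_LINEAGE_NAMES = {LINEAGE_HEALTHY: "healthy", LINEAGE_CANCER: "cancer"}


@dataclass
class CellBody:
    """Read-only view of one biological cell."""

    id: int
    position: np.ndarray
    velocity: np.ndarray
    mass: float
    preferred_area: float
    area: float
    perimeter: float
    polygon: np.ndarray
    glucose: float
    clock: float
    age: float
    lineage: str


class TissueState:
    """Domain plus per-cell arrays; the tessellation is cached."""

    def __init__(
        self,
        domain: TissueDomain,
        positions: np.ndarray,
        velocities: np.ndarray | None = None,
        masses: np.ndarray | None = None,
        preferred_areas: np.ndarray | None = None,
        glucose: np.ndarray | None = None,
        clocks: np.ndarray | None = None,
        ages: np.ndarray | None = None,
        lineages: np.ndarray | None = None,
        ids: np.ndarray | None = None,
        next_id: int | None = None,
        birth_areas: np.ndarray | None = None,
        mature: np.ndarray | None = None,
        basal_areas: np.ndarray | None = None,
    ):
        self.domain = domain
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float)).copy()
        n = len(self.positions)
        self.velocities = np.zeros((n, 2)) if velocities is None else np.asarray(velocities, float).copy()
        self.masses = np.ones(n) if masses is None else np.asarray(masses, float).copy()
        if preferred_areas is None:
            self.preferred_areas = np.full(n, domain.area / n)
        else:
            self.preferred_areas = np.asarray(preferred_areas, float).copy()
        self.glucose = np.zeros(n) if glucose is None else np.asarray(glucose, float).copy()
        self.clocks = np.zeros(n) if clocks is None else np.asarray(clocks, float).copy()
        self.ages = np.zeros(n) if ages is None else np.asarray(ages, float).copy()
        self.lineages = (
            np.zeros(n, dtype=np.int8) if lineages is None else np.asarray(lineages, np.int8).copy()
        )
        self.ids = np.arange(n) if ids is None else np.asarray(ids, int).copy()
        self.next_id = int(self.ids.max()) + 1 if next_id is None and n else (next_id or n)
        # preferred area at birth and maturity flag (mature cells do not regrow)
        self.birth_areas = (
            self.preferred_areas.copy() if birth_areas is None else np.asarray(birth_areas, float).copy()
        )
        self.mature = np.ones(n, dtype=np.int8) if mature is None else np.asarray(mature, np.int8).copy()
        # characteristic mature size of the lineage; inherited unchanged at division
        self.basal_areas = (
            self.preferred_areas.copy() if basal_areas is None else np.asarray(basal_areas, float).copy()
        )
        self._tess: Tessellation | None = None
        self._tess_pos: np.ndarray | None = None
        self._tess_domain: TissueDomain | None = None

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    def invalidate(self):
        self._tess = None

    def tessellation(self) -> Tessellation:
        if (
            self._tess is None
            or self._tess_domain is not self.domain
            or self._tess_pos is None
            or self._tess_pos.shape != self.positions.shape
            or not np.array_equal(self._tess_pos, self.positions)
        ):
            self._tess = build_voronoi(self.positions, self.domain)
            self._tess_pos = self.positions.copy()
            self._tess_domain = self.domain
        return self._tess

    @property
    def cells(self) -> list[CellBody]:
        tess = self.tessellation()
        return [
            CellBody(
                id=int(self.ids[i]),
                position=self.positions[i].copy(),
                velocity=self.velocities[i].copy(),
                mass=float(self.masses[i]),
                preferred_area=float(self.preferred_areas[i]),
                area=float(tess.areas[i]),
                perimeter=float(tess.perimeters[i]),
                polygon=tess.vertices[i].copy(),
                glucose=float(self.glucose[i]),
                clock=float(self.clocks[i]),
                age=float(self.ages[i]),
                lineage=_LINEAGE_NAMES[int(self.lineages[i])],
            )
            for i in range(self.n_cells)
        ]

    def copy(self) -> "TissueState":
        t = TissueState(
            self.domain,
            self.positions,
            self.velocities,
            self.masses,
            self.preferred_areas,
            self.glucose,
            self.clocks,
            self.ages,
            self.lineages,
            self.ids,
            self.next_id,
            self.birth_areas,
            self.mature,
            self.basal_areas,
        )
        return t

    def drop(self, index: int):
        """Remove one cell in place (arrays shrink; tessellation invalidated)."""
        keep = np.ones(self.n_cells, dtype=bool)
        keep[index] = False
        self.positions = self.positions[keep]
        self.velocities = self.velocities[keep]
        self.masses = self.masses[keep]
        self.preferred_areas = self.preferred_areas[keep]
        self.glucose = self.glucose[keep]
        self.clocks = self.clocks[keep]
        self.ages = self.ages[keep]
        self.lineages = self.lineages[keep]
        self.ids = self.ids[keep]
        self.birth_areas = self.birth_areas[keep]
        self.mature = self.mature[keep]
        self.basal_areas = self.basal_areas[keep]
        self.invalidate()

    def append(
        self, position, velocity, mass, preferred_area, glucose, clock, age, lineage,
        birth_area: float | None = None, mature: int = 1, basal_area: float | None = None,
    ) -> int:
        cid = self.next_id
        self.next_id += 1
        self.positions = np.vstack([self.positions, [position]])
        self.velocities = np.vstack([self.velocities, [velocity]])
        self.masses = np.append(self.masses, mass)
        self.preferred_areas = np.append(self.preferred_areas, preferred_area)
        self.glucose = np.append(self.glucose, glucose)
        self.clocks = np.append(self.clocks, clock)
        self.ages = np.append(self.ages, age)
        self.lineages = np.append(self.lineages, np.int8(lineage))
        self.ids = np.append(self.ids, cid)
        self.birth_areas = np.append(
            self.birth_areas, preferred_area if birth_area is None else birth_area
        )
        self.mature = np.append(self.mature, np.int8(mature))
        self.basal_areas = np.append(
            self.basal_areas, preferred_area if basal_area is None else basal_area
        )
        self.invalidate()
        return cid


# ---------------------------------------------------------------------------
# Energy and forces
# ---------------------------------------------------------------------------


def elastic_energy(tissue: TissueState, p: MechanicsParams) -> float:
    """Two-term vertex-model energy of the current tessellation."""
    tess = tissue.tessellation()
    a0 = tissue.preferred_areas
    p0 = np.array([hexagon_perimeter(a) for a in a0])
    da = tess.areas - a0
    dp = tess.perimeters - p0
    return float(0.5 * p.Kv * (da**2).sum() + 0.5 * p.Kc * (dp**2).sum())


def _energy_of_positions(positions, tissue: TissueState, p: MechanicsParams) -> float:
    tess = build_voronoi(positions, tissue.domain)
    a0 = tissue.preferred_areas
    p0 = np.array([hexagon_perimeter(a) for a in a0])
    da = tess.areas - a0
    dp = tess.perimeters - p0
    return float(0.5 * p.Kv * (da**2).sum() + 0.5 * p.Kc * (dp**2).sum())


def _forces_fd(tissue: TissueState, p: MechanicsParams) -> np.ndarray:
    poly = tissue.domain.polygon
    minx, miny, maxx, maxy = poly.bounds
    diam = math.hypot(maxx - minx, maxy - miny)
    h = p.fd_step * diam
    n = tissue.n_cells
    F = np.zeros((n, 2))
    base = tissue.positions
    for i in range(n):
        for axis in range(2):
            pp = base.copy()
            pp[i, axis] += h
            pm = base.copy()
            pm[i, axis] -= h
            # keep probes inside the domain
            if not shapely.contains_xy(poly, pp[i, 0], pp[i, 1]):
                pp[i, axis] = base[i, axis]
            if not shapely.contains_xy(poly, pm[i, 0], pm[i, 1]):
                pm[i, axis] = base[i, axis]
            span = pp[i, axis] - pm[i, axis]
            if span == 0:
                continue
            ep = _energy_of_positions(pp, tissue, p)
            em = _energy_of_positions(pm, tissue, p)
            F[i, axis] = -(ep - em) / span
    return F


def spring_rest_length(a0_i: float, a0_j: float) -> float:
    """Neighbour spacing of two cells at their preferred hexagonal packing."""
    d_i = math.sqrt(2.0 * a0_i / _SQRT3)
    d_j = math.sqrt(2.0 * a0_j / _SQRT3)
    return 0.5 * (d_i + d_j)


def _forces_spring(tissue: TissueState, p: MechanicsParams) -> np.ndarray:
    tess = tissue.tessellation()
    n = tissue.n_cells
    F = np.zeros((n, 2))
    if len(tess.edges) == 0:
        return F
    i, j = tess.edges[:, 0], tess.edges[:, 1]
    d = tissue.positions[j] - tissue.positions[i]
    dist = np.hypot(d[:, 0], d[:, 1])
    dist = np.maximum(dist, 1e-12)
    unit = d / dist[:, None]
    d0 = np.sqrt(2.0 * tissue.preferred_areas / _SQRT3)
    r0 = 0.5 * (d0[i] + d0[j])
    mag = p.spring_stiffness * (dist - r0)  # positive = attraction
    fvec = mag[:, None] * unit
    np.add.at(F, i, fvec)
    np.add.at(F, j, -fvec)
    return F


def forces(tissue: TissueState, p: MechanicsParams, method: str | None = None) -> np.ndarray:
    """Per-cell force vectors, -dE/dr by the configured method."""
    method = method or p.method
    if method == "fd":
        return _forces_fd(tissue, p)
    if method == "spring":
        return _forces_spring(tissue, p)
    raise ValueError(f"unknown force method {method!r}")


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------


@dataclass
class RelaxResult:
    tissue: TissueState
    n_steps: int
    converged: bool
    max_force: float
    energy_trace: list[float] = field(default_factory=list)
    clamped: int = 0


def _clamp_inside(positions: np.ndarray, velocities: np.ndarray, domain: TissueDomain) -> int:
    poly = domain.polygon
    inside = shapely.contains_xy(poly, positions[:, 0], positions[:, 1])
    n_clamped = 0
    if inside.all():
        return 0
    shrunk = poly.buffer(-1e-6 * math.sqrt(poly.area))
    if shrunk.is_empty:
        shrunk = poly
    for k in np.where(~inside)[0]:
        target = shapely.ops.nearest_points(shrunk, Point(positions[k]))[0]
        positions[k] = [target.x, target.y]
        velocities[k] = 0.0
        n_clamped += 1
    return n_clamped


def relax(
    tissue: TissueState,
    p: MechanicsParams,
    duration: float,
    dt: float = 0.05,
    method: str | None = None,
    track_energy: bool = False,
) -> RelaxResult:
    """Damped-Newtonian relaxation ``m r'' = F - k r'`` (semi-implicit Euler).

    Runs for ``duration`` or until the largest force drops below the
    tolerance.  Mutates and returns the tissue.  Escaped points are clamped
    back to the domain (velocity reset) and counted.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    method = method or p.method
    n_steps = max(1, int(round(duration / dt)))
    converged = False
    maxf = math.inf
    trace: list[float] = []
    clamped = 0
    for step in range(n_steps):
        F = forces(tissue, p, method)
        maxf = float(np.hypot(F[:, 0], F[:, 1]).max()) if len(F) else 0.0
        if track_energy:
            ek = float(0.5 * (tissue.masses * (tissue.velocities**2).sum(axis=1)).sum())
            trace.append(elastic_energy(tissue, p) + ek)
        if maxf < p.force_tolerance:
            converged = True
            break
        m = tissue.masses[:, None]
        v = (tissue.velocities + dt * F / m) / (1.0 + dt * p.k_friction / m)
        tissue.positions = tissue.positions + dt * v
        tissue.velocities = v
        clamped += _clamp_inside(tissue.positions, tissue.velocities, tissue.domain)
        tissue.invalidate()
    if track_energy:
        ek = float(0.5 * (tissue.masses * (tissue.velocities**2).sum(axis=1)).sum())
        trace.append(elastic_energy(tissue, p) + ek)
    return RelaxResult(tissue, n_steps, converged, maxf, trace, clamped)


import shapely.ops  # noqa: E402  (used in _clamp_inside)
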