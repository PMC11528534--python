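"""Deterministic tissue fixtures for tests and demonstrations."""

from __future__ import annotations

import math

import numpy as np
import shapely

from ..tissue_mech import TissueDomain, TissueState

__all__ = ["make_fixture", "random_points_in_domain", "hex_lattice_points"]


def hex_lattice_points(rings: int, spacing: float, center: tuple[float, float]) -> np.ndarray:
    """Hexagonal patch of ``1 + 3 rings (rings+1)`` points."""
    pts = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if abs(q + r) <= rings:
                x = spacing * (q + r / 2.0)
                y = spacing * (math.sqrt(3.0) / 2.0) * r
                pts.append([x + center[0], y + center[1]])
    return np.array(pts)


def random_points_in_domain(
    domain: TissueDomain, n: int, rng: np.random.Generator, min_spacing: float | None = None
) -> np.ndarray:
    """Seeded uniform rejection sampling with a minimum spacing."""
    poly = domain.polygon
    minx, miny, maxx, maxy = poly.bounds
    if min_spacing is None:
        min_spacing = 0.3 * math.sqrt(poly.area / n)
    pts: list[np.ndarray] = []
    attempts = 0
    margin = 1e-3 * math.sqrt(poly.area)
    while len(pts) < n:
        attempts += 1
        if attempts > 20000 * n:
            raise RuntimeError(
                f"could not place {n} points with spacing {min_spacing:.3g}; domain too small"
            )
        cand = rng.uniform([minx + margin, miny + margin], [maxx - margin, maxy - margin])
        if not shapely.contains_xy(poly, cand[0], cand[1]):
            continue
        if shapely.dwithin(poly.exterior, shapely.Point(cand), margin):
            continue
        if pts and np.min(np.hypot(*(np.array(pts) - cand).T)) < min_spacing:
            continue
        pts.append(cand)
    return np.array(pts)


def make_fixture(kind: str, seed: int = 0) -> TissueState:
    """Build one of the canonical test tissues.

    ``lattice``       hexagonal 19-cell patch at mechanical rest
    ``random``        100 seeded random cells in the unit square
    ``two_cell``      two mirror-symmetric cells of area 1/2 each
    ``perturbed_hex`` the lattice with seeded positional noise
    """
    if kind == "two_cell":
        dom = TissueDomain(kind="rectangle", duct_length=1.0, width=1.0)
        pts = np.array([[0.25, 0.5], [0.75, 0.5]])
        return TissueState(dom, pts, preferred_areas=np.array([0.5, 0.5]))

    if kind in ("lattice", "perturbed_hex"):
        dom = TissueDomain(kind="rectangle", duct_length=1.0, width=1.0)
        a0 = 1.0 / 19.0
        spacing = math.sqrt(2.0 * a0 / math.sqrt(3.0))
        pts = hex_lattice_points(2, spacing, (0.5, 0.5))
        if kind == "perturbed_hex":
            rng = np.random.default_rng(seed)
            pts = pts + rng.normal(0.0, 0.08 * spacing, size=pts.shape)
            pts = np.clip(pts, 0.02, 0.98)
        return TissueState(dom, pts, preferred_areas=np.full(len(pts), a0))

    if kind == "random":
        dom = TissueDomain(kind="rectangle", duct_length=1.0, width=1.0)
        rng = np.random.default_rng(seed)
        pts = random_points_in_domain(dom, 100, rng)
        return TissueState(dom, pts)

    raise ValueError(f"unknown fixture kind {kind!r}")
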