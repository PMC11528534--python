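"""Diffusive glucose transport on the Voronoi adjacency graph.

Finite-volume discretisation on the dual mesh: the flux between adjacent
cells is proportional to the concentration difference weighted by
``shared edge length / centroid distance``.  Duct-boundary cells act as
Dirichlet sources held at concentration 1; the outer boundary is no-flux.

An optional uptake term (consumption proportional to concentration times
cell area) produces the interior gradients that pace the cell-cycle clocks;
with ``uptake = 0`` the scheme conserves total glucose exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .tissue_mech import TissueState

__all__ = [
    "GlucoseField",
    "duct_source_mask",
    "transport_weights",
    "stability_limit",
    "diffuse_step",
    "steady_state",
    "solve_steady_direct",
    "mean_concentration",
    "calibrate_uptake",
]


@dataclass
class GlucoseField:
    """Per-cell normalized concentrations plus transport parameters."""

    concentrations: np.ndarray
    source_mask: np.ndarray  # bool, Dirichlet cells held at 1
    diffusivity: float = 1.0
    uptake: float = 0.0  # consumption coefficient q per unit area (amount/time per unit c)
    #: optional per-cell uptake multiplier (e.g. elevated tumour consumption)
    uptake_scale: np.ndarray | None = None
    #: optional Dirichlet cells held at 0 (used by tests/boundary scenarios)
    sink_mask: np.ndarray | None = None
    #: optional stiffness coupling strength (off by default)
    stiffness_lambda: float = 0.0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.source_mask = np.asarray(self.source_mask, dtype=bool)
        if self.sink_mask is not None:
            self.sink_mask = np.asarray(self.sink_mask, dtype=bool)
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if self.uptake < 0:
            raise ValueError("uptake must be non-negative")

    @property
    def fixed_mask(self) -> np.ndarray:
        if self.sink_mask is None:
            return self.source_mask
        return self.source_mask | self.sink_mask

    def cell_uptake(self, n: int) -> np.ndarray:
        """Per-cell uptake coefficients (scalar q times the optional scale)."""
        if self.uptake_scale is None:
            return np.full(n, self.uptake)
        return self.uptake * np.asarray(self.uptake_scale, dtype=float)

    def copy(self) -> "GlucoseField":
        return replace(
            self,
            concentrations=self.concentrations.copy(),
            source_mask=self.source_mask.copy(),
            uptake_scale=None if self.uptake_scale is None else np.asarray(self.uptake_scale).copy(),
            sink_mask=None if self.sink_mask is None else self.sink_mask.copy(),
        )


def duct_source_mask(tissue: TissueState, tol: float = 1e-9) -> np.ndarray:
    """Cells whose polygon touches the duct mouth (supply) edge."""
    x_mouth = tissue.domain.duct_mouth_x()
    tess = tissue.tessellation()
    mask = np.zeros(tissue.n_cells, dtype=bool)
    for i, verts in enumerate(tess.vertices):
        if np.any(verts[:, 0] <= x_mouth + tol):
            mask[i] = True
    return mask


def transport_weights(tissue: TissueState) -> tuple[np.ndarray, np.ndarray]:
    """Edge list and weights w_ij = shared-edge length / centroid distance."""
    tess = tissue.tessellation()
    if len(tess.edges) == 0:
        return tess.edges, np.empty(0)
    w = tess.edge_lengths / np.maximum(tess.edge_distances, 1e-12)
    return tess.edges, w


def _laplacian(tissue: TissueState, field: GlucoseField) -> sp.csr_matrix:
    """Weighted graph Laplacian L with L @ c = sum_j w_ij (c_j - c_i)."""
    n = tissue.n_cells
    edges, w = transport_weights(tissue)
    if len(edges) == 0:
        return sp.csr_matrix((n, n))
    i, j = edges[:, 0], edges[:, 1]
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    vals = np.concatenate([w, w, -w, -w])
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def stability_limit(tissue: TissueState, field: GlucoseField) -> float:
    """Largest stable explicit step: min_i A_i / (D * sum_j w_ij + q A_i)."""
    tess = tissue.tessellation()
    n = tissue.n_cells
    edges, w = transport_weights(tissue)
    wsum = np.zeros(n)
    if len(edges):
        np.add.at(wsum, edges[:, 0], w)
        np.add.at(wsum, edges[:, 1], w)
    denom = field.diffusivity * wsum + field.cell_uptake(n) * tess.areas
    with np.errstate(divide="ignore"):
        limits = np.where(denom > 0, tess.areas / denom, np.inf)
    return float(limits.min())


def diffuse_step(tissue: TissueState, field: GlucoseField, dt: float) -> GlucoseField:
    """One explicit finite-volume step; sources re-pinned to 1 afterwards."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = tissue.n_cells
    if n == 1 or len(tissue.tessellation().edges) == 0:
        out = field.copy()
        out.concentrations[out.source_mask] = 1.0
        if out.sink_mask is not None:
            out.concentrations[out.sink_mask] = 0.0
        return out
    limit = stability_limit(tissue, field)
    if dt >= limit:
        raise ValueError(f"dt={dt} violates the stability bound {limit}")
    tess = tissue.tessellation()
    L = _laplacian(tissue, field)
    c = field.concentrations
    q = field.cell_uptake(n)
    dc = (field.diffusivity * (L @ c) - q * tess.areas * c) * (dt / tess.areas)
    out = field.copy()
    out.concentrations = c + dc
    out.concentrations[out.source_mask] = 1.0
    if out.sink_mask is not None:
        out.concentrations[out.sink_mask] = 0.0
    return out


def steady_state(
    tissue: TissueState,
    field: GlucoseField,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> GlucoseField:
    """Iterate :func:`diffuse_step` to the stationary field.

    Requires at least one source cell; raises on non-convergence.
    """
    if not field.source_mask.any():
        raise ValueError("steady state needs at least one source cell")
    dt = 0.9 * stability_limit(tissue, field)
    cur = field.copy()
    cur.concentrations[cur.source_mask] = 1.0
    if cur.sink_mask is not None:
        cur.concentrations[cur.sink_mask] = 0.0
    for _ in range(max_iter):
        nxt = diffuse_step(tissue, cur, dt)
        delta = float(np.max(np.abs(nxt.concentrations - cur.concentrations)))
        cur = nxt
        if delta < tol:
            return cur
    raise RuntimeError(f"glucose steady state not reached in {max_iter} iterations")


def solve_steady_direct(tissue: TissueState, field: GlucoseField) -> GlucoseField:
    """Stationary field by direct sparse solve of the Dirichlet problem."""
    if not field.source_mask.any():
        raise ValueError("steady state needs at least one source cell")
    n = tissue.n_cells
    L = _laplacian(tissue, field)
    areas = tissue.tessellation().areas
    A = -field.diffusivity * L + sp.diags(field.cell_uptake(n) * areas)
    A = A.tolil()
    b = np.zeros(n)
    for i in np.where(field.fixed_mask)[0]:
        A.rows[i] = [i]
        A.data[i] = [1.0]
        b[i] = 1.0 if field.source_mask[i] else 0.0
    c = sp.linalg.spsolve(A.tocsr(), b)
    out = field.copy()
    out.concentrations = np.asarray(c)
    return out


def mean_concentration(tissue: TissueState, field: GlucoseField) -> float:
    """Area-weighted mean concentration."""
    tess = tissue.tessellation()
    if tissue.n_cells == 0:
        raise ValueError("empty tissue")
    return float((field.concentrations * tess.areas).sum() / tess.areas.sum())


def calibrate_uptake(
    tissue: TissueState,
    field: GlucoseField,
    target_mean: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 80,
) -> GlucoseField:
    """Choose the uptake coefficient so the steady mean concentration hits
    ``target_mean`` (bisection on q; the mean is monotone decreasing in q)."""
    if not 0 < target_mean < 1:
        raise ValueError("target mean must lie in (0, 1)")
    lo, hi = 0.0, 1.0
    f = field.copy()
    # grow hi until the mean drops below target
    for _ in range(60):
        f.uptake = hi
        if mean_concentration(tissue, solve_steady_direct(tissue, f)) < target_mean:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the uptake coefficient")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f.uptake = mid
        m = mean_concentration(tissue, solve_steady_direct(tissue, f))
        if abs(m - target_mean) < tol:
            break
        if m > target_mean:
            lo = mid
        else:
            hi = mid
    out = solve_steady_direct(tissue, f)
    out.uptake = f.uptake
    return out


def calibrate_uptake_balanced(
    tissue: TissueState,
    field: GlucoseField,
    lower: float,
    upper: float,
    tol: float = 1e-4,
    max_iter: int = 80,
) -> GlucoseField:
    """Choose the uptake so the non-source cell counts above ``upper`` and
    below ``lower`` balance (division band vs death band of the clock law).

    The imbalance (count above - count below) is monotone decreasing in the
    uptake, so a bisection applies; ties are broken toward the mean sitting
    between the two thresholds.
    """
    free = ~field.source_mask
    if not free.any():
        raise ValueError("all cells are sources; nothing to balance")

    def imbalance(q: float) -> float:
        f = field.copy()
        f.uptake = q
        c = solve_steady_direct(tissue, f).concentrations[free]
        return float((c > upper).mean() - (c < lower).mean())

    lo, hi = 1e-6, 1.0
    for _ in range(60):
        if imbalance(hi) < 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the balanced uptake")
    q = hi
    for _ in range(max_iter):
        q = 0.5 * (lo + hi)
        d = imbalance(q)
        if abs(d) < tol or hi - lo < 1e-9:
            break
        if d > 0:
            lo = q
        else:
            hi = q
    f = field.copy()
    f.uptake = q
    out = solve_steady_direct(tissue, f)
    out.uptake = q
    return out
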