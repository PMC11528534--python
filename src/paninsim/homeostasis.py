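"""Inflammation quantification and the duct-elongation relief mechanism.

The inflammation index is the ratio of demanded to realized cell area,

    index = sum_i A0_i / sum_i A_i ,

which exceeds 1 exactly when cells are on average compressed below their
preferred size (inflamed) and is 1 when every cell realizes its preferred
area.  When the index exceeds the threshold ``A_up`` the duct elongates,
adding realizable area and strictly lowering the index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tissue_mech import TissueState

__all__ = [
    "HomeostasisParams",
    "InflammationMetrics",
    "inflammation_index",
    "per_cell_index",
    "classify",
    "metrics",
    "elongate_duct",
    "inflammation_series",
    "CLASS_LABELS",
]

CLASS_LABELS = ("relaxed", "soft", "moderate", "severe")


@dataclass(frozen=True)
class HomeostasisParams:
    """Elongation threshold, gain and classification bin edges."""

    A_up: float = 1.1
    eta: float = 0.1  # elongation gain
    #: index bin edges for (relaxed | soft | moderate | severe)
    bins: tuple[float, float, float] = (1.0, 1.15, 1.35)

    def __post_init__(self):
        if self.A_up <= 0 or self.eta <= 0:
            raise ValueError("A_up and eta must be positive")
        if not (self.bins[0] < self.bins[1] < self.bins[2]):
            raise ValueError("classification bins must be increasing")


@dataclass
class InflammationMetrics:
    index: float
    classification: str
    A_up: float = 1.1


def inflammation_index(tissue: TissueState) -> float:
    """Demanded over realized area (the realized areas tile the domain)."""
    if tissue.n_cells == 0:
        raise ValueError("empty tissue")
    tess = tissue.tessellation()
    return float(tissue.preferred_areas.sum() / tess.areas.sum())


def per_cell_index(tissue: TissueState) -> np.ndarray:
    """Per-cell demanded/realized ratio (rendering diagnostic)."""
    tess = tissue.tessellation()
    return tissue.preferred_areas / tess.areas


def classify(index: float, p: HomeostasisParams | None = None) -> str:
    """Label the inflammation level; monotone in the index."""
    if index <= 0:
        raise ValueError("index must be positive")
    p = p or HomeostasisParams()
    if index < p.bins[0]:
        return "relaxed"
    if index < p.bins[1]:
        return "soft"
    if index < p.bins[2]:
        return "moderate"
    return "severe"


def metrics(tissue: TissueState, p: HomeostasisParams | None = None) -> InflammationMetrics:
    p = p or HomeostasisParams()
    idx = inflammation_index(tissue)
    return InflammationMetrics(index=idx, classification=classify(idx, p), A_up=p.A_up)


def elongate_duct(
    tissue: TissueState, m: InflammationMetrics, p: HomeostasisParams | None = None
) -> TissueState:
    """Extend the duct when the index exceeds ``A_up``; identity otherwise.

    The boundary grows along the duct axis by ``eta * (index - A_up) * L``;
    cell generators stay in place, so the recomputed index strictly
    decreases.
    """
    p = p or HomeostasisParams()
    if m.index <= p.A_up:
        return tissue
    delta = p.eta * (m.index - p.A_up) * tissue.domain.duct_length
    tissue.domain = tissue.domain.elongate(delta)
    tissue.invalidate()
    return tissue


def inflammation_series(run_log) -> "np.ndarray":
    """Time series of index values from an orchestrator run log.

    Accepts the orchestrator's interval records (sequence of dicts with
    ``time`` and ``index``) and returns a structured array sorted by time.
    """
    records = list(run_log)
    if not records:
        raise ValueError("empty run log")
    records.sort(key=lambda r: r["time"])
    out = np.zeros(len(records), dtype=[("time", float), ("index", float)])
    for k, r in enumerate(records):
        out[k] = (r["time"], r["index"])
    return out
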