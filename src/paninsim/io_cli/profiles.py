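"""Canonical desk-scale scenario profiles.

These are the configurations used by the scenario test-suite and the
acceptance report: a rectangular duct strip (fast convex tessellation),
spring forces with overdamped relaxation, and reduced cell counts.  The
full-size long-run configuration remains the library default.
"""

from __future__ import annotations

from ..cell_fate import ClockParams
from ..tissue_mech import MechanicsParams, TissueDomain
from .config import SimConfig

__all__ = ["healthy_profile", "panin2_profile", "DESK_DOMAIN"]

DESK_DOMAIN = TissueDomain(kind="rectangle", duct_length=3.0, width=1.0)

_DESK_MECH = MechanicsParams(method="spring", k_friction=2.0, force_tolerance=5e-3)


def healthy_profile(seed: int = 1, n_cells: int = 100, cycles: float = 10.0) -> SimConfig:
    """Healthy homeostasis scenario (no cancer cells, duct relief on)."""
    return SimConfig(
        seed=seed,
        n_cells=n_cells,
        n_cancer=0,
        total_cycles=cycles,
        dt_mech=0.3,
        domain=DESK_DOMAIN,
        mech=_DESK_MECH,
    )


def panin2_profile(seed: int, n_cancer: int, n_cells: int = 60, cycles: float = 40.0) -> SimConfig:
    """Scenario starting at the PanIN 2 onset with seeded cancer cells.

    The gene-network time axis is offset to the PanIN 2 onset (tau1), the
    lesions are seeded at spread-out locations, and the inflammation index
    is read without the duct-relief controller so terminal values reflect
    the accumulated tumour pressure.
    """
    cfg = SimConfig(
        seed=seed,
        n_cells=n_cells,
        n_cancer=n_cancer,
        total_cycles=cycles,
        dt_mech=0.6,
        cancer_placement="spread",
        elongation=False,
        cancer_clock_rate=0.08,
        cancer_uptake_factor=1.0,
        domain=DESK_DOMAIN,
        mech=_DESK_MECH,
    )
    offset = cfg.delays.tau1_units / cfg.delays.time_units_per_cycle
    import dataclasses

    return dataclasses.replace(cfg, grn_offset_cycles=offset)
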