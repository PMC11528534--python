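"""Scenario assembly and the coupled half-cycle simulation loop.

Each half basal cycle the loop: (1) mechanically relaxes the tissue,
(2) resolves the glucose field to its stationary state, (3) advances the
shared gene-network trajectories and the per-cell clocks, (4) runs the
division/death fate checks (optionally gated by the proliferation
phenotypes), (5) updates the inflammation index and elongates the duct
when it exceeds the threshold, and (6) relaxes again.

The gene network evolves independently of the tissue, so one healthy and
one cancer trajectory are shared by all cells; scenario configs map tissue
time 0 onto a later point of the network trajectory (e.g. the PanIN 2
onset) via ``grn_offset_cycles``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from . import cell_fate, glucose_transport as gt, homeostasis, tissue_mech as tm
from .grn_boolean import NetworkVariant
from .grn_dde import CytokineDriver, Trajectory, build_rhs, integrate_dde, stage_label
from .io_cli.config import SimConfig
from .io_cli.fixtures import random_points_in_domain

__all__ = [
    "GrnTables",
    "SimState",
    "RunResult",
    "compute_grn_tables",
    "init_simulation",
    "run",
    "stage_of",
]

#: initial continuous state: stellate branch active-ish, cancer branch silent
INITIAL_Z = {"y1": 0.5, "y2": 0.0, "y3": 0.5, "y4": 0.5, "z1": 0.0, "z2": 0.5}
#: in diseased tissue RAS starts overexpressed (oncogenic activation), which
#: lets mutated PIP3 switch on early and, through the delayed literals, drives
#: the cancer-proliferation phenotype up during the PanIN stages
INITIAL_Z_CANCER = {**INITIAL_Z, "y1": 1.0}


def initial_state_for(variant: NetworkVariant) -> dict[str, float]:
    return INITIAL_Z_CANCER if NetworkVariant(variant) is NetworkVariant.CANCER else INITIAL_Z


@dataclass
class GrnTables:
    """Shared phenotype-gate lookup tables for both network variants."""

    times: np.ndarray
    healthy_z2: np.ndarray
    cancer_z4: np.ndarray
    cancer_z3: np.ndarray | None = None  # cancer apoptosis phenotype

    def _crossed(self, series: np.ndarray, t: float, window: float) -> bool:
        """Whether the series exceeded 1/2 during ``[t - window, t]``.

        Fate checks land at a fixed phase of the cytokine cycle, so an
        instantaneous read would alias the phenotype oscillation.
        """
        if window <= 0:
            return bool(np.interp(t, self.times, series) > 0.5)
        lo = np.searchsorted(self.times, t - window, side="left")
        hi = np.searchsorted(self.times, t, side="right")
        if hi > lo:
            return bool(series[lo:hi].max() > 0.5)
        return bool(np.interp(t, self.times, series) > 0.5)

    def gate_open(self, lineage: int, t: float, window: float = 0.0) -> bool:
        """Division gate: proliferation phenotype active around ``t``."""
        series = self.cancer_z4 if lineage == tm.LINEAGE_CANCER else self.healthy_z2
        return self._crossed(series, t, window)

    def death_gate_open(self, lineage: int, t: float, window: float = 0.0) -> bool:
        """Death gate: cancer cells die only while their apoptosis phenotype
        is active (oncogenic deregulation suppresses it); healthy turnover is
        purely clock-driven."""
        if lineage != tm.LINEAGE_CANCER or self.cancer_z3 is None:
            return True
        return self._crossed(self.cancer_z3, t, window)


def compute_grn_tables(cfg: SimConfig, t_end: float | None = None, stride: int = 10) -> GrnTables:
    """Integrate both network variants up to ``t_end`` model-time units."""
    if t_end is None:
        t_end = cfg.grn_offset_cycles * cfg.delays.time_units_per_cycle + cfg.total_time_units
    t_end = max(t_end, cfg.dt_grn * stride * 2)
    driver = CytokineDriver.calibrated(cfg.driver_u0, cfg.driver_v0,
                                      period=cfg.delays.time_units_per_cycle)
    trajs: dict[str, Trajectory] = {}
    for variant in (NetworkVariant.HEALTHY, NetworkVariant.CANCER):
        system = build_rhs(variant, cfg.grn, cfg.delays, driver=driver)
        y0 = system.initial_state(initial_state_for(variant))
        trajs[variant.value] = integrate_dde(system, y0, t_end=t_end, dt=cfg.dt_grn, stride=stride)
    return GrnTables(
        times=trajs["healthy"].times,
        healthy_z2=trajs["healthy"].z("z2"),
        cancer_z4=trajs["cancer"].z("z4"),
        cancer_z3=trajs["cancer"].z("z3"),
    )


@dataclass
class SimState:
    time: float
    tissue: tm.TissueState
    field: gt.GlucoseField
    grn: GrnTables | None
    rng: np.random.Generator
    records: list = dfield(default_factory=list)
    events: list = dfield(default_factory=list)


def init_simulation(cfg: SimConfig, grn_tables: GrnTables | None = None) -> SimState:
    """Seeded initial tissue, calibrated glucose field and GRN tables."""
    rng = np.random.default_rng(cfg.seed)
    points = random_points_in_domain(cfg.domain, cfg.n_cells, rng)
    tissue = tm.TissueState(cfg.domain, points)

    sources = gt.duct_source_mask(tissue)
    lineages = np.zeros(cfg.n_cells, dtype=np.int8)
    if cfg.n_cancer:
        candidates = np.where(~sources)[0]
        if cfg.cancer_placement == "nearest_duct":
            mouth = np.array(cfg.domain.duct_axis[0])
            d = np.hypot(*(points[candidates] - mouth).T)
            chosen = candidates[np.argsort(d)[: cfg.n_cancer]]
        elif cfg.cancer_placement == "spread":
            # greedy farthest-point spread: lesions seed at separate places
            pool = list(candidates)
            first = pool[int(rng.integers(len(pool)))]
            sel = [first]
            while len(sel) < cfg.n_cancer and pool:
                dist = np.min(
                    np.hypot(*(points[pool][:, None, :] - points[sel][None, :, :]).transpose(2, 0, 1)),
                    axis=1,
                )
                sel.append(pool[int(np.argmax(dist))])
            chosen = np.array(sel[: cfg.n_cancer])
        else:
            chosen = rng.choice(candidates, size=cfg.n_cancer, replace=False)
        if len(chosen) < cfg.n_cancer:
            raise ValueError("not enough non-source cells to place cancer cells")
        lineages[chosen] = tm.LINEAGE_CANCER
    tissue.lineages = lineages

    field = gt.GlucoseField(np.full(cfg.n_cells, 0.5), sources,
                            diffusivity=cfg.glucose_diffusivity)
    if cfg.glucose_calibration == "balanced":
        lo, hi = cfg.glucose_balance_band
        field = gt.calibrate_uptake_balanced(tissue, field, lo, hi)
    elif cfg.glucose_calibration == "mean":
        field = gt.calibrate_uptake(tissue, field, cfg.glucose_target_mean)
    else:
        field = gt.solve_steady_direct(tissue, field)
    # apply the tumour consumption factor on top of the healthy calibration
    if cfg.n_cancer and cfg.cancer_uptake_factor != 1.0:
        field.uptake_scale = _uptake_scale(tissue, cfg)
        field = gt.solve_steady_direct(tissue, field)
    tissue.glucose = np.clip(field.concentrations, 0.0, 1.0)

    if grn_tables is None and cfg.gating and cfg.total_cycles > 0:
        grn_tables = compute_grn_tables(cfg)
    return SimState(time=0.0, tissue=tissue, field=field, grn=grn_tables, rng=rng)


def _uptake_scale(tissue: tm.TissueState, cfg: SimConfig) -> np.ndarray:
    """Healthy consumption is per unit area; tumour cells consume a fixed
    multiple of a basal-sized cell's demand each, however compressed, so a
    growing tumour drains its neighbourhood in proportion to its cell count."""
    scale = np.ones(tissue.n_cells)
    ca = tissue.lineages == tm.LINEAGE_CANCER
    if ca.any():
        areas = tissue.tessellation().areas
        scale[ca] = cfg.cancer_uptake_factor * tissue.basal_areas[ca] / np.maximum(
            areas[ca], 1e-12
        )
    return scale


def _apply_hypertrophy(tissue: tm.TissueState, cfg: SimConfig) -> None:
    """Dysplastic enlargement: cancer cells' demanded area creeps upward
    (the rising cell area/volume ratio that drives inflammation), capped at
    a multiple of the initial cell size."""
    if cfg.cancer_hypertrophy <= 0:
        return
    ca = tissue.lineages == tm.LINEAGE_CANCER
    if not ca.any():
        return
    cap = cfg.cancer_hypertrophy_max * cfg.domain.area / cfg.n_cells
    tissue.basal_areas[ca] = np.minimum(
        tissue.basal_areas[ca] * (1.0 + cfg.cancer_hypertrophy), cap
    )
    grown = ca & (tissue.mature == 1)
    tissue.preferred_areas[grown] = tissue.basal_areas[grown]


def _resolve_glucose(state: SimState, cfg: SimConfig) -> None:
    tissue = state.tissue
    sources = gt.duct_source_mask(tissue)
    f = gt.GlucoseField(tissue.glucose, sources, diffusivity=cfg.glucose_diffusivity,
                        uptake=state.field.uptake, uptake_scale=_uptake_scale(tissue, cfg))
    f = gt.solve_steady_direct(tissue, f)
    state.field = f
    tissue.glucose = np.clip(f.concentrations, 0.0, 1.0)


def _event_rng(cfg: SimConfig, cell_id: int, check: int) -> np.random.Generator:
    """Per-event generator keyed by (seed, cell, check): common random
    numbers across scenarios that share a seed, so paired comparisons are
    not polluted by stream divergence."""
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, cell_id, check]))


def _fate_sweep(state: SimState, cfg: SimConfig, t_grn: float, check: int = 0) -> tuple[int, int]:
    """Division/death checks on every non-source cell; returns counts."""
    tissue = state.tissue
    clock = cfg.clock
    sources = gt.duct_source_mask(tissue)
    tess = tissue.tessellation()
    decisions: list[tuple[int, cell_fate.FateDecision]] = []
    for i in range(tissue.n_cells):
        if sources[i]:
            continue
        fate = cell_fate.decide_fate(tissue.clocks[i], clock, age=tissue.ages[i])
        if fate is cell_fate.FateDecision.DIE and cfg.gating and state.grn is not None:
            if not state.grn.death_gate_open(int(tissue.lineages[i]), t_grn,
                                             window=clock.interval):
                fate = cell_fate.FateDecision.NONE
        if fate is cell_fate.FateDecision.DIVIDE:
            # size checkpoint / contact inhibition: a cell divides only once
            # its realized footprint approaches the lineage basal size
            # (cancer cells largely escape the inhibition)
            rho = (
                clock.cancer_crowding_threshold
                if tissue.lineages[i] == tm.LINEAGE_CANCER
                else clock.crowding_threshold
            )
            if rho > 0 and tess.areas[i] < rho * tissue.basal_areas[i]:
                fate = cell_fate.FateDecision.NONE
            elif cfg.gating and state.grn is not None and not state.grn.gate_open(
                int(tissue.lineages[i]), t_grn, window=clock.interval
            ):
                fate = cell_fate.FateDecision.NONE
        if fate is not cell_fate.FateDecision.NONE:
            decisions.append((int(tissue.ids[i]), fate))

    n_div = n_die = 0
    for cid, fate in decisions:
        idx_arr = np.where(tissue.ids == cid)[0]
        if len(idx_arr) == 0:
            continue
        idx = int(idx_arr[0])
        pos = tissue.positions[idx].copy()
        lineage = int(tissue.lineages[idx])
        if fate is cell_fate.FateDecision.DIVIDE:
            d1, d2 = cell_fate.divide(tissue, idx, _event_rng(cfg, cid, check), clock)
            if lineage == tm.LINEAGE_CANCER and cfg.cancer_hypertrophy > 0:
                # division resets dysplastic enlargement; it re-accumulates
                basal0 = cfg.domain.area / cfg.n_cells
                for child in (d1, d2):
                    ci_arr = np.where(tissue.ids == child)[0]
                    tissue.basal_areas[ci_arr] = basal0
            n_div += 1
            state.events.append({"time": state.time, "event": "divide", "cell": cid,
                                 "children": [d1, d2], "lineage": lineage,
                                 "x": float(pos[0]), "y": float(pos[1])})
        else:
            if tissue.n_cells <= 1:
                continue
            cell_fate.kill(tissue, idx)
            n_die += 1
            state.events.append({"time": state.time, "event": "die", "cell": cid,
                                 "lineage": lineage, "x": float(pos[0]), "y": float(pos[1])})
    return n_div, n_die


@dataclass
class RunResult:
    config: SimConfig
    state: SimState

    @property
    def records(self) -> list:
        return self.state.records

    @property
    def events(self) -> list:
        return self.state.events

    @property
    def tissue(self) -> tm.TissueState:
        return self.state.tissue

    def records_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.state.records)

    def inflammation_series(self):
        return homeostasis.inflammation_series(self.state.records)


def run(
    cfg: SimConfig,
    grn_tables: GrnTables | None = None,
    snapshot_dir=None,
    audit: bool = False,
) -> RunResult:
    """Execute a full scenario; returns logs and the final state.

    ``audit`` asserts the conservation invariants (domain partition, cell
    mass positivity) after every interval.
    """
    state = init_simulation(cfg, grn_tables)
    tissue = state.tissue
    clock = cfg.clock
    half = clock.interval
    t_offset = cfg.grn_offset_cycles * cfg.delays.time_units_per_cycle
    n_checks = int(round(cfg.total_cycles * cfg.delays.time_units_per_cycle / half))

    _record(state, cfg, 0, 0, 0, t_offset)
    if snapshot_dir is not None:
        _snapshot(state, cfg, snapshot_dir, 0)

    for k in range(1, n_checks + 1):
        tm.relax(tissue, cfg.mech, duration=half, dt=cfg.dt_mech)
        _resolve_glucose(state, cfg)
        cell_fate.advance_clocks(
            tissue, half, clock,
            cancer_rate=cfg.cancer_clock_rate if cfg.cancer_clock_rate > 0 else None,
        )
        cell_fate.update_growth(tissue, clock)
        _apply_hypertrophy(tissue, cfg)
        state.time = k * half
        t_grn = t_offset + state.time

        n_div, n_die = _fate_sweep(state, cfg, t_grn, check=k)
        if n_div or n_die:
            _resolve_glucose(state, cfg)

        idx = homeostasis.inflammation_index(tissue)
        if cfg.elongation and idx > cfg.homeo.A_up:
            homeostasis.elongate_duct(tissue, homeostasis.InflammationMetrics(
                idx, homeostasis.classify(idx, cfg.homeo), cfg.homeo.A_up), cfg.homeo)

        tm.relax(tissue, cfg.mech, duration=half, dt=cfg.dt_mech)

        if audit:
            tess = tissue.tessellation()
            assert abs(tess.areas.sum() - tissue.domain.area) < 1e-9 * tissue.domain.area
            assert (tissue.masses > 0).all()

        _record(state, cfg, k, n_div, n_die, t_grn)
        if snapshot_dir is not None and cfg.snapshot_stride and k % cfg.snapshot_stride == 0:
            _snapshot(state, cfg, snapshot_dir, k)

        if not np.isfinite(tissue.positions).all():
            raise FloatingPointError(f"non-finite tissue state at check {k}")
    return RunResult(cfg, state)


def _record(state: SimState, cfg: SimConfig, k: int, n_div: int, n_die: int, t_grn: float):
    tissue = state.tissue
    idx = homeostasis.inflammation_index(tissue)
    state.records.append({
        "check": k,
        "time": state.time,
        "cycle": state.time / cfg.delays.time_units_per_cycle,
        "n_cells": tissue.n_cells,
        "n_cancer": int((tissue.lineages == tm.LINEAGE_CANCER).sum()),
        "divisions": n_div,
        "deaths": n_die,
        "index": idx,
        "label": homeostasis.classify(idx, cfg.homeo),
        "mean_glucose": float(np.mean(tissue.glucose)),
        "stage": stage_of(t_grn, cfg.delays),
        "duct_length": tissue.domain.duct_length,
    })


def _snapshot(state: SimState, cfg: SimConfig, directory, k: int):
    from pathlib import Path

    from .io_cli.snapshots import write_snapshot

    path = Path(directory) / f"snapshot_{k:05d}.json"
    write_snapshot(state.tissue, path, state.field, time=state.time)


def stage_of(t: float, delays) -> str:
    """PanIN stage at model time ``t`` (PanIN 1 on (0, tau1], then PanIN 2)."""
    return stage_label(t, delays)
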