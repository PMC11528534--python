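"""Glucose-paced cell-cycle clocks and the division/death rules.

Each cell carries an internal clock ``Ti`` that advances at a rate set by
its local glucose concentration; the linear law ``rate(c) = (gamma/8) c``
with ``gamma = 16`` makes a cell at the mean concentration 0.5 complete
exactly one basal cycle per ``T0``.  At fate checks (every ``T0/2``) a cell
divides when its clock runs ahead, ``(Ti - T0)/T0 > lambda_h``, and dies
when it lags, ``(T0 - Ti)/T0 > lambda_h`` -- the latter only once the cell
is at least one basal period old, so newborns are not culled before their
clock has had a full cycle to catch up.

Division is geometric: daughters sit at ``R/2`` from the mother's centre
(``R = sqrt(A/pi)``) along a random direction, split mass and preferred
area in half, inherit the mother's concentration (the glucose amount splits
with the realized areas) and restart their clocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import shapely
import shapely.ops

from .tissue_mech import TissueState

__all__ = [
    "ClockParams",
    "FateDecision",
    "clock_rate",
    "advance_clock",
    "advance_clocks",
    "update_growth",
    "decide_fate",
    "divide",
    "kill",
    "division_kick",
]


class FateDecision(str, Enum):
    DIVIDE = "divide"
    DIE = "die"
    NONE = "none"


@dataclass(frozen=True)
class ClockParams:
    """Clock law constants and fate thresholds (paper defaults)."""

    T0: float = 12.0  # basal cycle, model-time units (36 days)
    gamma: float = 16.0
    beta0: float = 0.5  # half-saturation of the optional saturating law
    lambda_h: float = 0.15
    check_interval: float | None = None  # default T0/2
    law: str = "linear"  # or "hill"
    #: minimum age before the death rule applies (one basal period)
    death_eligible_age: float | None = None
    #: daughters regrow their preferred area to the mother's over this time
    growth_time: float | None = None
    division_offset: str = "half_radius"  # or "sqrt_half" (R/sqrt(2))
    #: contact inhibition -- a cell divides only if its realized area is at
    #: least this fraction of its preferred area (0 disables the gate)
    crowding_threshold: float = 0.92
    #: cancer cells largely escape contact inhibition
    cancer_crowding_threshold: float = 0.5

    def __post_init__(self):
        if self.T0 <= 0 or self.gamma <= 0 or self.beta0 <= 0:
            raise ValueError("T0, gamma, beta0 must be positive")
        if not 0 < self.lambda_h < 1:
            raise ValueError("lambda_h must lie in (0, 1)")
        if self.law not in ("linear", "hill"):
            raise ValueError("clock law must be 'linear' or 'hill'")
        if self.division_offset not in ("half_radius", "sqrt_half"):
            raise ValueError("division offset must be 'half_radius' or 'sqrt_half'")

    @property
    def interval(self) -> float:
        return self.check_interval if self.check_interval is not None else self.T0 / 2.0

    @property
    def death_age(self) -> float:
        return self.death_eligible_age if self.death_eligible_age is not None else self.T0

    @property
    def regrow_time(self) -> float:
        return self.growth_time if self.growth_time is not None else self.T0


def clock_rate(ci, p: ClockParams):
    """Clock speed as a function of glucose; calibrated so rate(0.5) = 1."""
    ci = np.asarray(ci, dtype=float)
    if np.any((ci < 0) | (ci > 1)):
        raise ValueError("glucose concentration must lie in [0, 1]")
    if p.law == "linear":
        out = (p.gamma / 8.0) * ci
    else:  # saturating alternative with half-saturation beta0
        k = (p.beta0**2 + 0.25) / 0.25
        out = k * ci**2 / (p.beta0**2 + ci**2)
    return float(out) if out.ndim == 0 else out


def advance_clock(clock: float, dt: float, ci: float, p: ClockParams) -> float:
    """New clock value after ``dt`` at constant concentration ``ci``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return clock + dt * clock_rate(ci, p)


def advance_clocks(tissue: TissueState, dt: float, p: ClockParams,
                   cancer_rate: float | None = None):
    """Vectorised in-place clock and age advance for the whole tissue.

    ``cancer_rate`` overrides the glucose-paced law for cancer cells:
    oncogenic signalling makes their cycle autonomous, ticking at a fixed
    (slow) pace regardless of the local nutrient level.
    """
    rates = clock_rate(tissue.glucose, p)
    if cancer_rate is not None:
        rates = np.where(tissue.lineages == 1, cancer_rate, rates)
    tissue.clocks = tissue.clocks + dt * rates
    tissue.ages = tissue.ages + dt


def update_growth(tissue: TissueState, p: ClockParams):
    """Regrow daughters' preferred areas toward the lineage basal size.

    A non-mature cell's preferred area interpolates linearly from its value
    at birth to the basal (characteristic mature) size over ``T_grow``.
    """
    growing = tissue.mature == 0
    if not growing.any():
        return
    frac = np.minimum(tissue.ages[growing] / p.regrow_time, 1.0)
    birth = tissue.birth_areas[growing]
    basal = tissue.basal_areas[growing]
    tissue.preferred_areas[growing] = birth + (basal - birth) * frac
    done = growing & (tissue.ages >= p.regrow_time)
    tissue.mature[done] = 1


def decide_fate(clock: float, p: ClockParams, age: float | None = None) -> FateDecision:
    """Fate of a cell with clock ``Ti`` at a check (strict inequalities).

    ``age`` gates the death rule: cells younger than one basal period are
    never culled.  ``age=None`` means unconditionally eligible.
    """
    if clock < 0:
        raise ValueError("negative clock")
    eps = 1e-12  # keep the strict inequality strict under float rounding
    if (clock - p.T0) / p.T0 > p.lambda_h + eps:
        return FateDecision.DIVIDE
    if (p.T0 - clock) / p.T0 > p.lambda_h + eps and (age is None or age >= p.death_age):
        return FateDecision.DIE
    return FateDecision.NONE


def division_kick(velocity: np.ndarray, mass: float, direction: np.ndarray) -> np.ndarray:
    """Default opposite-kick magnitude at division.

    The printed daughter-speed expression is dimensionally damaged and
    incompatible with simultaneous momentum and energy conservation for
    equal-mass daughters; the default rule targets each daughter's speed at
    ``sqrt(3 Ec / 2)`` where reachable under momentum conservation, which
    for a perpendicular kick means ``w^2 = max(0, 3 Ec / 2 - |v|^2)``.
    """
    ec = 0.5 * mass * float(velocity @ velocity)
    w2 = max(0.0, 1.5 * ec - float(velocity @ velocity))
    return math.sqrt(w2) * direction


def divide(
    tissue: TissueState,
    index: int,
    rng: np.random.Generator,
    p: ClockParams | None = None,
) -> tuple[int, int]:
    """Split cell ``index`` into two daughters; returns the daughter ids.

    The mother is removed.  Mass, momentum and glucose amount are conserved
    at the event; preferred areas halve and the clocks restart.
    """
    p = p or ClockParams()
    tess = tissue.tessellation()
    area = float(tess.areas[index])
    radius = math.sqrt(area / math.pi)
    offset = radius / 2.0 if p.division_offset == "half_radius" else radius / math.sqrt(2.0)
    pos = tissue.positions[index].copy()
    vel = tissue.velocities[index].copy()
    mass = float(tissue.masses[index])
    a0 = float(tissue.preferred_areas[index])
    ci = float(tissue.glucose[index])
    lineage = int(tissue.lineages[index])

    poly = tissue.domain.polygon
    placed = False
    for trial_offset in (offset, offset / 2.0, offset / 4.0, offset / 8.0):
        for _ in range(100):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            u = np.array([math.cos(theta), math.sin(theta)])
            p1 = pos + trial_offset * u
            p2 = pos - trial_offset * u
            if shapely.contains_xy(poly, p1[0], p1[1]) and shapely.contains_xy(poly, p2[0], p2[1]):
                placed = True
                break
        if placed:
            break
    if not placed:
        # degenerate geometry (e.g. mother pinned in a corner): project the
        # daughter centres back into a slightly shrunk domain
        theta = rng.uniform(0.0, 2.0 * math.pi)
        u = np.array([math.cos(theta), math.sin(theta)])
        shrunk = poly.buffer(-min(offset / 4.0, 1e-3 * math.sqrt(poly.area)))
        if shrunk.is_empty:
            shrunk = poly
        proj = []
        for cand in (pos + offset * u, pos - offset * u):
            pt = shapely.ops.nearest_points(shrunk, shapely.Point(cand))[0]
            proj.append(np.array([pt.x, pt.y]))
        p1, p2 = proj
        if np.allclose(p1, p2):
            p2 = p2 + 1e-6 * np.array([-u[1], u[0]])

    kick = division_kick(vel, mass, u)
    v1 = vel + kick
    v2 = vel - kick

    basal = float(tissue.basal_areas[index])
    tissue.drop(index)
    id1 = tissue.append(p1, v1, mass / 2.0, a0 / 2.0, ci, 0.0, 0.0, lineage,
                        birth_area=a0 / 2.0, mature=0, basal_area=basal)
    id2 = tissue.append(p2, v2, mass / 2.0, a0 / 2.0, ci, 0.0, 0.0, lineage,
                        birth_area=a0 / 2.0, mature=0, basal_area=basal)
    return id1, id2


def kill(tissue: TissueState, index: int) -> None:
    """Remove a cell; neighbours absorb the freed area on re-tessellation."""
    if tissue.n_cells <= 1:
        raise ValueError("cannot remove the last cell of the tissue")
    tissue.drop(index)
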