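"""Delayed Hill-logic dynamics of the regulatory network.

Each regulated agent ``z`` is modelled by a two-stage system

    dR_z/dt = eps_z * B_z(literals) - R_z
    dz/dt   = 1 / (1 + (R_z / rho)^m) - z

where the bracket ``B_z`` translates the agent's Boolean rule: an AND of
OR-groups becomes a product over groups of the mean of per-literal Hill
terms.  Activating literals use the negative exponent ``n``, negated
literals the positive exponent ``-n``.  The two delayed literals (past RAS
and past mutated PIP3) are read from an interpolated history buffer at
``t - tau1`` and ``t - tau2``.

The cytokine inputs are a dimensionless Lotka-Volterra oscillator

    du/dt = alpha * u * (1 - v),   dv/dt = beta * v * (u - 1)

whose rate constants are calibrated so the orbit through the configured
initial condition has the basal period ``T0``.

Literal arguments are scaled by a midpoint before entering the Hill term:
gene concentrations live in [0, 1] with Boolean threshold 0.5, cytokines
oscillate around 1.  Midpoints of 1.0 everywhere recover the plain
unscaled form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .grn_boolean import REGULATED_AGENTS, NetworkVariant, rule_groups

__all__ = [
    "GrnParameters",
    "DelayConfig",
    "CytokineDriver",
    "HistoryBuffer",
    "DdeSystem",
    "Trajectory",
    "hill",
    "build_rhs",
    "step_cytokines",
    "lv_invariant",
    "integrate_dde",
    "phenotype_profile",
    "DEFAULT_EPSILON",
]

#: Regulation strengths, one per regulated agent (table row order).
DEFAULT_EPSILON: dict[str, float] = {
    "y1": 1 / 0.3,
    "y2": 1 / 2.2,
    "y3": 1.0,
    "y4": 1 / 0.3,
    "c1": 1 / 1.25,
    "c2": 1 / 1.4,
    "c3": 1.0,
    "c4": 1 / 0.2,
    "z1": 1.0,
    "z2": 1.0,
    "z3": 1 / 0.68,
    "z4": 1 / 1.14,
}


def hill(x, n: float):
    """Hill response ``1 / (1 + x**n)``.

    Negative ``n`` is an activator (0 at x=0), positive ``n`` a repressor
    (1 at x=0), ``n = 0`` constitutive (0.5 everywhere).  Accepts scalars
    or arrays; ``x`` must be non-negative.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill argument must be non-negative")
    if n == 0:
        out = np.full_like(x, 0.5)
        return float(out) if out.ndim == 0 else out
    with np.errstate(divide="ignore", over="ignore"):
        p = np.where(x > 0, x, 1.0) ** n
        out = np.where(x > 0, 1.0 / (1.0 + p), 0.0 if n < 0 else 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GrnParameters:
    """Regulation strengths, Hill exponents and midpoint scalings."""

    epsilon: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EPSILON))
    n: int = -6
    m: int = -10
    #: Boolean threshold of gene concentrations inside Hill arguments.
    regulation_midpoint: float = 0.5
    #: Threshold of the regulation response R inside the output stage.
    response_midpoint: float = 0.5
    #: Cytokines oscillate around 1; their Hill midpoint.
    cytokine_midpoint: float = 1.0

    def __post_init__(self):
        missing = set(REGULATED_AGENTS) - set(self.epsilon)
        if missing:
            raise ValueError(f"epsilon missing agents: {sorted(missing)}")
        if any(e <= 0 for e in self.epsilon.values()):
            raise ValueError("all epsilon must be positive")
        if self.n >= 0 or self.m >= 0:
            raise ValueError("activation exponents n and m must be negative")


@dataclass(frozen=True)
class DelayConfig:
    """Delay durations and the calendar <-> model-time mapping.

    One basal cytokine cycle lasts ``days_per_cycle`` (36) days and spans
    ``time_units_per_cycle`` dimensionless model-time units.  The default of
    12 units per cycle is the reading of the printed step accounting under
    which 48e6 steps of 1e-4 equal 400 basal cycles; it also lets the
    network track the cytokine oscillation.  Months are 30 days, years 360
    days throughout.
    """

    tau1_years: float = 17.13
    tau2_years: float = 13.82
    days_per_cycle: float = 36.0
    days_per_month: float = 30.0
    days_per_year: float = 360.0
    time_units_per_cycle: float = 12.0

    def __post_init__(self):
        # zero is allowed for delay-ablation studies
        if self.tau1_years < 0 or self.tau2_years < 0:
            raise ValueError("delays must be non-negative")
        for f in ("days_per_cycle", "days_per_month", "days_per_year", "time_units_per_cycle"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def years_per_time_unit(self) -> float:
        return self.days_per_cycle / (self.days_per_year * self.time_units_per_cycle)

    @property
    def cycles(self) -> float:
        """Model-time units of one basal cycle (alias for readability)."""
        return self.time_units_per_cycle

    def years_to_units(self, years: float) -> float:
        return years / self.years_per_time_unit

    @property
    def tau1_units(self) -> float:
        return self.years_to_units(self.tau1_years)

    @property
    def tau2_units(self) -> float:
        return self.years_to_units(self.tau2_years)


# ---------------------------------------------------------------------------
# Cytokine driver
# ---------------------------------------------------------------------------


def _lv_rhs(t, y, alpha, beta):
    u, v = y
    return [alpha * u * (1.0 - v), beta * v * (u - 1.0)]


@lru_cache(maxsize=16)
def _lv_base_period(u0: float, v0: float) -> float:
    """Orbit period of the unit-rate system through (u0, v0)."""
    events_t = []

    def section(t, y, *args):
        return y[1] - 1.0

    section.direction = 1.0
    sol = solve_ivp(
        _lv_rhs,
        (0.0, 200.0),
        [u0, v0],
        args=(1.0, 1.0),
        events=section,
        rtol=1e-11,
        atol=1e-12,
        dense_output=False,
        max_step=0.05,
    )
    events_t = sol.t_events[0]
    if len(events_t) < 2:
        raise RuntimeError("failed to detect Lotka-Volterra period")
    return float(events_t[1] - events_t[0])


@dataclass
class CytokineDriver:
    """Lotka-Volterra cytokine pair (u = TNFa = x1, v = TGFb1 = x2)."""

    u: float = 1.5
    v: float = 0.7
    alpha: float = 1.0
    beta: float = 1.0
    period: float = 12.0  # model-time units of one basal cycle

    def __post_init__(self):
        if self.u <= 0 or self.v <= 0:
            raise ValueError("cytokine concentrations must stay positive")

    @classmethod
    def calibrated(cls, u0: float = 1.5, v0: float = 0.7, period: float = 12.0) -> "CytokineDriver":
        """Driver whose orbit through (u0, v0) has the requested period."""
        base = _lv_base_period(round(u0, 12), round(v0, 12))
        rate = base / period
        return cls(u=u0, v=v0, alpha=rate, beta=rate, period=period)

    @property
    def state(self) -> tuple[float, float]:
        return (self.u, self.v)


def lv_invariant(u: float, v: float) -> float:
    """First integral ``log u - u + log v - v`` (conserved for alpha = beta)."""
    return math.log(u) - u + math.log(v) - v


def step_cytokines(driver: CytokineDriver, dt: float) -> CytokineDriver:
    """Advance the oscillator one classical RK4 step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if driver.u <= 0 or driver.v <= 0:
        raise ValueError("non-positive cytokine state")
    y = np.array([driver.u, driver.v])

    def f(y):
        u, v = y
        return np.array([driver.alpha * u * (1.0 - v), driver.beta * v * (u - 1.0)])

    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return replace(driver, u=float(y[0]), v=float(y[1]))


# ---------------------------------------------------------------------------
# History buffer (uniform-step, Hermite interpolation)
# ---------------------------------------------------------------------------


class HistoryBuffer:
    """Stores (t, y, dy/dt) at uniform steps; interpolates delayed queries.

    Queries before ``t0`` return the initial history value (constant
    pre-history convention).  Interpolation is cubic Hermite by default,
    or piecewise linear.
    """

    def __init__(self, t0: float, dt: float, y0: np.ndarray, capacity: int, order: str = "cubic"):
        if order not in ("linear", "cubic"):
            raise ValueError("interpolation order must be 'linear' or 'cubic'")
        self.t0 = float(t0)
        self.dt = float(dt)
        self.order = order
        dim = len(y0)
        self._y = np.empty((capacity + 1, dim))
        self._f = np.zeros((capacity + 1, dim))
        self._y[0] = y0
        self.n = 0  # index of last filled node

    def append(self, y: np.ndarray, f: np.ndarray, f_prev: np.ndarray | None = None):
        """Record the state at node ``n+1`` with its derivative."""
        self.n += 1
        if self.n >= self._y.shape[0]:
            grow = max(self._y.shape[0] // 2, 1024)
            self._y = np.vstack([self._y, np.empty((grow, self._y.shape[1]))])
            self._f = np.vstack([self._f, np.empty((grow, self._f.shape[1]))])
        self._y[self.n] = y
        self._f[self.n] = f
        if f_prev is not None and self.n == 1:
            self._f[0] = f_prev

    def set_initial_derivative(self, f0: np.ndarray):
        self._f[0] = f0

    @property
    def t_end(self) -> float:
        return self.t0 + self.n * self.dt

    def value(self, t: float, component: int) -> float:
        if t <= self.t0:
            return float(self._y[0, component])
        s = (t - self.t0) / self.dt
        k = int(s)
        if k >= self.n:
            if s - self.n < 1e-9:  # query at the live node
                return float(self._y[self.n, component])
            raise ValueError(f"history queried at t={t} beyond recorded end {self.t_end}")
        frac = s - k
        y0 = self._y[k, component]
        y1 = self._y[k + 1, component]
        if self.order == "linear":
            return float(y0 + frac * (y1 - y0))
        f0 = self._f[k, component] * self.dt
        f1 = self._f[k + 1, component] * self.dt
        h00 = (1 + 2 * frac) * (1 - frac) ** 2
        h10 = frac * (1 - frac) ** 2
        h01 = frac**2 * (3 - 2 * frac)
        h11 = frac**2 * (frac - 1)
        return float(h00 * y0 + h10 * f0 + h01 * y1 + h11 * f1)


# ---------------------------------------------------------------------------
# Vectorised right-hand side
# ---------------------------------------------------------------------------

_N_AGENTS = len(REGULATED_AGENTS)
# State layout: R (12) | z (12) | u | v
IDX_R = {a: i for i, a in enumerate(REGULATED_AGENTS)}
IDX_Z = {a: _N_AGENTS + i for i, a in enumerate(REGULATED_AGENTS)}
IDX_U = 2 * _N_AGENTS
IDX_V = 2 * _N_AGENTS + 1
DIM = 2 * _N_AGENTS + 2
# Extended literal-value vector: z (12) | u | v | y1_delayed | c3_delayed
_EXT_U = _N_AGENTS
_EXT_V = _N_AGENTS + 1
_EXT_D1 = _N_AGENTS + 2
_EXT_D2 = _N_AGENTS + 3


class DdeSystem:
    """Compiled vector field for one network variant.

    ``frozen_inputs`` replaces the Lotka-Volterra cytokines by constants;
    ``frozen_delays`` replaces the history lookups of the two delayed
    literals by constants (used for steep-limit / attractor comparisons).
    """

    def __init__(
        self,
        variant: NetworkVariant,
        params: GrnParameters,
        delays: DelayConfig,
        driver: CytokineDriver | None = None,
        frozen_inputs: tuple[float, float] | None = None,
        frozen_delays: tuple[float, float] | None = None,
    ):
        self.variant = NetworkVariant(variant)
        self.params = params
        self.delays = delays
        self.driver = driver
        self.frozen_inputs = frozen_inputs
        self.frozen_delays = frozen_delays
        if driver is None and frozen_inputs is None:
            raise ValueError("need either a cytokine driver or frozen inputs")

        lit_src: list[int] = []
        lit_exp: list[float] = []
        lit_mid: list[float] = []
        g_start: list[int] = []
        g_size: list[int] = []
        a_start: list[int] = []
        pos = 0
        gpos = 0
        # z-values occupy the first 12 extended-vector slots
        ext_index = {a: i for i, a in enumerate(REGULATED_AGENTS)}
        ext_index.update(x1=_EXT_U, x2=_EXT_V, y1_delayed=_EXT_D1, c3_delayed=_EXT_D2)
        for agent in REGULATED_AGENTS:
            a_start.append(gpos)
            for group in rule_groups(agent, self.variant):
                g_start.append(pos)
                g_size.append(len(group))
                for lit in group:
                    lit_src.append(ext_index[lit.name])
                    lit_exp.append(float(-params.n) if lit.negated else float(params.n))
                    if lit.name in ("x1", "x2"):
                        lit_mid.append(params.cytokine_midpoint)
                    else:
                        lit_mid.append(params.regulation_midpoint)
                    pos += 1
                gpos += 1
        self._lit_src = np.array(lit_src)
        self._lit_exp = np.array(lit_exp)
        self._lit_invmid = 1.0 / np.array(lit_mid)
        self._g_start = np.array(g_start)
        self._g_size = np.array(g_size, dtype=float)
        self._a_start = np.array(a_start)
        self._eps = np.array([params.epsilon[a] for a in REGULATED_AGENTS])
        self._m = float(params.m)
        self._inv_rho = 1.0 / params.response_midpoint

    @property
    def dim(self) -> int:
        return DIM

    def delay_spec(self) -> list[tuple[float, int]]:
        """(delay in model units, state component) pairs for history lookups."""
        if self.frozen_delays is not None:
            return []
        return [
            (self.delays.tau1_units, IDX_Z["y1"]),
            (self.delays.tau2_units, IDX_Z["c3"]),
        ]

    def initial_state(self, z0: dict[str, float] | None = None) -> np.ndarray:
        """State vector with given per-agent concentrations (default 0)."""
        y = np.zeros(DIM)
        if z0:
            for a, v in z0.items():
                y[IDX_Z[a]] = v
        if self.frozen_inputs is not None:
            y[IDX_U], y[IDX_V] = self.frozen_inputs
        else:
            y[IDX_U], y[IDX_V] = self.driver.u, self.driver.v
        return y

    def rhs(self, t: float, y: np.ndarray, delayed: Sequence[float]) -> np.ndarray:
        """Vector field; ``delayed`` holds the values at t-tau1 and t-tau2."""
        R = np.maximum(y[:_N_AGENTS], 0.0)
        z = y[_N_AGENTS : 2 * _N_AGENTS]
        if self.frozen_inputs is not None:
            u, v = self.frozen_inputs
        else:
            u, v = y[IDX_U], y[IDX_V]
        if self.frozen_delays is not None:
            d1, d2 = self.frozen_delays
        else:
            d1, d2 = delayed

        ext = np.empty(_N_AGENTS + 4)
        ext[:_N_AGENTS] = np.maximum(z, 0.0)
        ext[_EXT_U], ext[_EXT_V] = u, v
        ext[_EXT_D1], ext[_EXT_D2] = max(d1, 0.0), max(d2, 0.0)

        x = ext[self._lit_src] * self._lit_invmid
        with np.errstate(divide="ignore", over="ignore"):
            p = np.where(x > 0, x, 1.0) ** self._lit_exp
            terms = np.where(x > 0, 1.0 / (1.0 + p), np.where(self._lit_exp < 0, 0.0, 1.0))
        gsum = np.add.reduceat(terms, self._g_start) / self._g_size
        bracket = np.multiply.reduceat(gsum, self._a_start)

        out = np.empty(DIM)
        out[:_N_AGENTS] = self._eps * bracket - R
        with np.errstate(divide="ignore", over="ignore"):
            rp = np.where(R > 0, R * self._inv_rho, 1.0) ** self._m
            resp = np.where(R > 0, 1.0 / (1.0 + rp), 0.0)
        out[_N_AGENTS : 2 * _N_AGENTS] = resp - z
        if self.frozen_inputs is not None:
            out[IDX_U] = 0.0
            out[IDX_V] = 0.0
        else:
            out[IDX_U] = self.driver.alpha * u * (1.0 - v)
            out[IDX_V] = self.driver.beta * v * (u - 1.0)
        return out


def build_rhs(
    variant: NetworkVariant,
    params: GrnParameters | None = None,
    delays: DelayConfig | None = None,
    driver: CytokineDriver | None = None,
    frozen_inputs: tuple[float, float] | None = None,
    frozen_delays: tuple[float, float] | None = None,
) -> DdeSystem:
    """Construct the delayed vector field for a network variant."""
    params = params or GrnParameters()
    delays = delays or DelayConfig()
    if driver is None and frozen_inputs is None:
        driver = CytokineDriver.calibrated(period=delays.time_units_per_cycle)
    return DdeSystem(variant, params, delays, driver, frozen_inputs, frozen_delays)


# ---------------------------------------------------------------------------
# RK4 integrator with method-of-steps history
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Sampled solution of the (delayed) system."""

    times: np.ndarray
    states: np.ndarray  # (n_samples, DIM)
    system: DdeSystem | None = None

    def z(self, agent: str) -> np.ndarray:
        return self.states[:, IDX_Z[agent]]

    def r(self, agent: str) -> np.ndarray:
        return self.states[:, IDX_R[agent]]

    @property
    def cytokines(self) -> np.ndarray:
        return self.states[:, [IDX_U, IDX_V]]

    def to_dataframe(self, delays: DelayConfig | None = None):
        import pandas as pd

        data = {"time": self.times}
        if delays is not None:
            data["stage"] = [stage_label(t, delays) for t in self.times]
        for a in REGULATED_AGENTS:
            data[f"R_{a}"] = self.states[:, IDX_R[a]]
        for a in REGULATED_AGENTS:
            data[f"z_{a}"] = self.states[:, IDX_Z[a]]
        data["x1"] = self.states[:, IDX_U]
        data["x2"] = self.states[:, IDX_V]
        return pd.DataFrame(data)

    def to_csv(self, path, delays: DelayConfig | None = None):
        self.to_dataframe(delays).to_csv(path, index=False)

    def at(self, t: float) -> np.ndarray:
        """State at time t by linear interpolation of the samples."""
        out = np.empty(self.states.shape[1])
        for j in range(self.states.shape[1]):
            out[j] = np.interp(t, self.times, self.states[:, j])
        return out


def integrate_dde(
    system,
    y0: np.ndarray,
    t_end: float,
    dt: float,
    t0: float = 0.0,
    history_init: Callable[[float], np.ndarray] | np.ndarray | None = None,
    stride: int = 1,
    history_order: str = "cubic",
) -> Trajectory:
    """Classical RK4 with delayed arguments read from the history buffer.

    ``system`` is a :class:`DdeSystem` or any object exposing ``rhs(t, y,
    delayed)`` and ``delay_spec()``.  Delayed values for the RK4 stages are
    looked up at ``t - tau``, ``t + dt/2 - tau`` and ``t + dt - tau``.  The
    initial history is the constant ``y0`` unless ``history_init`` is given
    (an array, or a callable of ``t`` for t <= t0).
    """
    if dt <= 0 or t_end <= t0:
        raise ValueError("need dt > 0 and t_end > t0")
    spec = system.delay_spec()
    for tau, _ in spec:
        if 0 < tau < dt:
            raise ValueError(f"delay {tau} smaller than step {dt}; reduce dt")
    # zero delays degenerate to the current stage value (ablation limit)
    zero_delay = [j for j, (tau, _) in enumerate(spec) if tau == 0]

    n_steps = int(round((t_end - t0) / dt))
    y0 = np.asarray(y0, dtype=float)

    if history_init is None:
        h0 = y0
        hist_fn = None
    elif callable(history_init):
        hist_fn = history_init
        h0 = np.asarray(history_init(t0), dtype=float)
    else:
        h0 = np.asarray(history_init, dtype=float)
        hist_fn = None

    hist = HistoryBuffer(t0, dt, h0, n_steps, order=history_order)

    def delayed_at(t_query: float) -> list[float]:
        vals = []
        for tau, comp in spec:
            if tau == 0:
                vals.append(0.0)  # placeholder, replaced per stage
                continue
            tq = t_query - tau
            if tq <= t0 and hist_fn is not None:
                vals.append(float(hist_fn(tq)[comp]))
            else:
                vals.append(hist.value(tq, comp))
        return vals

    n_samples = n_steps // stride + 1
    times = np.empty(n_samples)
    states = np.empty((n_samples, len(y0)))
    times[0] = t0
    states[0] = y0

    def stage_delayed(template: list[float], y_stage: np.ndarray) -> list[float]:
        if not zero_delay:
            return template
        vals = list(template)
        for j in zero_delay:
            vals[j] = float(y_stage[spec[j][1]])
        return vals

    y = y0.copy()
    t = t0
    si = 1
    k1 = system.rhs(t, y, stage_delayed(delayed_at(t), y))
    hist.set_initial_derivative(k1)
    for k in range(n_steps):
        dh = delayed_at(t + 0.5 * dt)
        d1 = delayed_at(t + dt)
        y2 = y + 0.5 * dt * k1
        k2 = system.rhs(t + 0.5 * dt, y2, stage_delayed(dh, y2))
        y3 = y + 0.5 * dt * k2
        k3 = system.rhs(t + 0.5 * dt, y3, stage_delayed(dh, y3))
        y4 = y + dt * k3
        k4 = system.rhs(t + dt, y4, stage_delayed(d1, y4))
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t0 + (k + 1) * dt
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite state at t={t}")
        # the node derivative doubles as k1 of the next step
        k1 = system.rhs(t, y, stage_delayed(delayed_at(t), y))
        hist.append(y, k1)
        if (k + 1) % stride == 0:
            times[si] = t
            states[si] = y
            si += 1
    return Trajectory(times[:si], states[:si], system if isinstance(system, DdeSystem) else None)


# ---------------------------------------------------------------------------
# Stage annotation
# ---------------------------------------------------------------------------

STAGES = ("PanIN1", "PanIN2", "post")


def stage_label(t: float, delays: DelayConfig) -> str:
    """Disease stage at model time ``t`` (closed right boundaries)."""
    if t < 0:
        raise ValueError("negative time")
    if t <= delays.tau1_units:
        return "PanIN1"
    if t <= delays.tau1_units + delays.tau2_units:
        return "PanIN2"
    return "post"


def phenotype_profile(traj: Trajectory, delays: DelayConfig) -> dict:
    """Stage labels per sample plus per-stage means of the phenotype agents.

    Requires the trajectory to cover at least ``tau1 + tau2`` of model time.
    """
    span = traj.times[-1] - traj.times[0]
    if span < delays.tau1_units + delays.tau2_units:
        raise ValueError("trajectory shorter than tau1 + tau2")
    labels = np.array([stage_label(t, delays) for t in traj.times])
    means: dict[str, dict[str, float]] = {}
    for stage in STAGES:
        mask = labels == stage
        if not mask.any():
            continue
        means[stage] = {a: float(traj.z(a)[mask].mean()) for a in ("z1", "z2", "z3", "z4")}
    return {"labels": labels, "stage_means": means}
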