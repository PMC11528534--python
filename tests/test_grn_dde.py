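import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paninsim.grn_boolean import REGULATED_AGENTS, NetworkVariant
from paninsim.grn_dde import (
    DEFAULT_EPSILON,
    IDX_R,
    IDX_Z,
    CytokineDriver,
    DelayConfig,
    GrnParameters,
    HistoryBuffer,
    Trajectory,
    build_rhs,
    hill,
    integrate_dde,
    lv_invariant,
    phenotype_profile,
    stage_label,
    step_cytokines,
)


class TestHill:
    @pytest.mark.parametrize("n", [-10, -6, -1, 1, 6, 10])
    def test_midpoint(self, n):
        assert hill(1.0, n) == pytest.approx(0.5)

    def test_constitutive(self):
        for x in (0.0, 0.3, 1.0, 7.0):
            assert hill(x, 0) == 0.5

    def test_activator_value(self):
        assert hill(2.0, -6) == pytest.approx(64.0 / 65.0)

    def test_limits_at_zero(self):
        assert hill(0.0, -6) == 0.0
        assert hill(0.0, 6) == 1.0

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            hill(-0.1, -6)

    def test_vectorized(self):
        out = hill(np.array([0.0, 1.0, 2.0]), -6)
        assert out == pytest.approx([0.0, 0.5, 64 / 65])


class TestParameters:
    def test_default_epsilon_values(self):
        p = GrnParameters()
        assert p.epsilon["y1"] == pytest.approx(1 / 0.3)
        assert p.epsilon["y2"] == pytest.approx(1 / 2.2)
        assert p.epsilon["c1"] == pytest.approx(1 / 1.25)
        assert p.epsilon["c4"] == pytest.approx(1 / 0.2)
        assert p.epsilon["z3"] == pytest.approx(1 / 0.68)
        assert p.epsilon["z4"] == pytest.approx(1 / 1.14)
        assert (p.n, p.m) == (-6, -10)

    def test_rejects_nonpositive_epsilon(self):
        eps = dict(DEFAULT_EPSILON)
        eps["y1"] = 0.0
        with pytest.raises(ValueError):
            GrnParameters(epsilon=eps)

    def test_rejects_repressor_global_exponents(self):
        with pytest.raises(ValueError):
            GrnParameters(n=6)


class TestDelayConfig:
    def test_ratio_rounds_to_published_value(self):
        d = DelayConfig()
        assert round(d.tau2_years / d.tau1_years, 1) == 0.8

    def test_unit_conversion(self):
        d = DelayConfig()
        # one model-time unit is 1/120 of a 360-day year
        assert d.years_per_time_unit == pytest.approx(36.0 / (360.0 * 12.0))
        assert d.tau1_units == pytest.approx(17.13 * 120.0)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            DelayConfig(tau1_years=-1.0)


class TestCytokines:
    def test_equilibrium_is_stationary(self):
        d = CytokineDriver(u=1.0, v=1.0, alpha=0.5, beta=0.5)
        out = step_cytokines(d, 0.1)
        assert (out.u, out.v) == pytest.approx((1.0, 1.0), abs=1e-14)

    def test_invariant_drift_small(self):
        d = CytokineDriver.calibrated(period=12.0)
        inv0 = lv_invariant(d.u, d.v)
        x = d
        steps = 1200
        for _ in range(steps):
            x = step_cytokines(x, 12.0 / steps)
        assert abs(lv_invariant(x.u, x.v) - inv0) < 1e-6

    def test_calibrated_period(self):
        d = CytokineDriver.calibrated(period=12.0)
        # integrate finely; measure the return time to the start point
        x = d
        dt = 1e-3
        t, crossed = 0.0, []
        prev_v = d.v
        while t < 30.0 and len(crossed) < 2:
            x = step_cytokines(x, dt)
            t += dt
            if prev_v < 1.0 <= x.v:  # rising crossing of v = 1
                crossed.append(t)
            prev_v = x.v
        period = crossed[1] - crossed[0]
        assert period == pytest.approx(12.0, rel=0.01)

    def test_positive_state_required(self):
        with pytest.raises(ValueError):
            CytokineDriver(u=-1.0, v=1.0)


class _ScalarRelaxation:
    """dy/dt = a - y, no delays (closed form a + (y0-a) e^-t)."""

    def __init__(self, a):
        self.a = a

    def delay_spec(self):
        return []

    def rhs(self, t, y, delayed):
        return np.array([self.a - y[0]])


class _PureDelay:
    """dy/dt = -y(t - tau), constant history."""

    def __init__(self, tau):
        self.tau = tau

    def delay_spec(self):
        return [(self.tau, 0)]

    def rhs(self, t, y, delayed):
        return np.array([-delayed[0]])


class TestIntegrator:
    def test_scalar_linear_ode(self):
        sys_ = _ScalarRelaxation(2.0)
        traj = integrate_dde(sys_, np.array([0.5]), t_end=3.0, dt=1e-3)
        exact = 2.0 + (0.5 - 2.0) * math.exp(-3.0)
        assert traj.states[-1, 0] == pytest.approx(exact, abs=1e-8)

    def test_method_of_steps_closed_form(self):
        # y' = -y(t - 1), y == 1 on [-1, 0]:
        # y(t) = 1 - t on [0, 1]; y(t) = 1 - t + (t-1)^2/2 on [1, 2]
        sys_ = _PureDelay(1.0)
        traj = integrate_dde(sys_, np.array([1.0]), t_end=2.0, dt=0.01)
        for t, y in zip(traj.times, traj.states[:, 0]):
            if t <= 1.0:
                exact = 1.0 - t
            else:
                exact = 1.0 - t + 0.5 * (t - 1.0) ** 2
            assert y == pytest.approx(exact, abs=1e-9), t

    def test_nan_detection(self):
        class Blowup:
            def delay_spec(self):
                return []

            def rhs(self, t, y, d):
                with np.errstate(over="ignore"):
                    return y**2

        with pytest.raises(FloatingPointError):
            integrate_dde(Blowup(), np.array([5.0]), t_end=10.0, dt=0.1)

    def test_richardson_order(self):
        system = build_rhs(NetworkVariant.CANCER)
        y0 = system.initial_state({"y1": 0.5, "y3": 0.5, "y4": 0.5, "z2": 0.5})
        ends = []
        for dt in (0.08, 0.04, 0.02):
            traj = integrate_dde(system, y0, t_end=12.0, dt=dt)
            ends.append(traj.states[-1])
        e1 = np.linalg.norm(ends[0] - ends[1])
        e2 = np.linalg.norm(ends[1] - ends[2])
        order = math.log2(e1 / e2)
        assert order >= 3.5

    def test_delay_ablation_matches_no_delay(self):
        delays0 = DelayConfig(tau1_years=0.0, tau2_years=0.0)
        driver = CytokineDriver.calibrated(period=12.0)
        sys_delayed = build_rhs(NetworkVariant.CANCER, delays=delays0, driver=driver)
        y0 = sys_delayed.initial_state({"y1": 0.6, "y3": 0.4})

        class NoDelay:
            def delay_spec(self):
                return []

            def rhs(self, t, y, d):
                inner = [y[comp] for _, comp in sys_delayed_spec]
                return sys_delayed.rhs(t, y, inner)

        sys_delayed_spec = [
            (sys_delayed.delays.tau1_units, IDX_Z["y1"]),
            (sys_delayed.delays.tau2_units, IDX_Z["c3"]),
        ]
        t_a = integrate_dde(sys_delayed, y0, t_end=6.0, dt=0.01)
        t_b = integrate_dde(NoDelay(), y0, t_end=6.0, dt=0.01)
        assert np.max(np.abs(t_a.states - t_b.states)) < 1e-10

    def test_boundedness(self):
        system = build_rhs(NetworkVariant.CANCER)
        y0 = system.initial_state({"y1": 1.0, "y3": 1.0})
        traj = integrate_dde(system, y0, t_end=60.0, dt=0.02, stride=10)
        for a in REGULATED_AGENTS:
            z = traj.z(a)
            r = traj.r(a)
            assert np.all(z >= -1e-12) and np.all(z <= 1.0 + 1e-9)
            assert np.all(r >= -1e-12)
            assert np.all(r <= system.params.epsilon[a] + 1e-9)


class TestBuildRhs:
    def test_single_activator_fixed_point_unscaled(self):
        # with unit midpoints, a single always-on activator at x = 1 gives
        # R* = eps/2 and z* = 1/(1 + (eps/2)^m)
        p = GrnParameters(regulation_midpoint=1.0, response_midpoint=1.0)
        system = build_rhs(NetworkVariant.CANCER, p, frozen_inputs=(1.0, 1.0),
                           frozen_delays=(0.0, 0.0))
        eps = p.epsilon["z2"]
        y = system.initial_state()
        y[IDX_Z["y3"]] = 1.0  # z2's only regulator pinned on
        y[IDX_R["z2"]] = eps * 0.5
        zstar = 1.0 / (1.0 + (eps / 2.0) ** p.m)
        y[IDX_Z["z2"]] = zstar
        out = system.rhs(0.0, y, [0.0, 0.0])
        assert out[IDX_R["z2"]] == pytest.approx(0.0, abs=1e-12)
        assert out[IDX_Z["z2"]] == pytest.approx(0.0, abs=1e-12)

    def test_steep_limit_matches_boolean_fixed_point(self):
        fp = {"y1": 1, "y2": 0, "y3": 1, "y4": 1, "c1": 1, "c2": 0,
              "c3": 1, "c4": 1, "z1": 0, "z2": 1, "z3": 0, "z4": 0}
        eps = {a: (5.0 if fp[a] else 0.2) for a in REGULATED_AGENTS}
        p = GrnParameters(epsilon=eps, n=-40, m=-40)
        system = build_rhs(NetworkVariant.CANCER, p, frozen_inputs=(1.0, 1.0),
                           frozen_delays=(1.0, 1.0))
        y0 = system.initial_state({a: float(v) for a, v in fp.items()})
        traj = integrate_dde(system, y0, t_end=60.0, dt=0.02, stride=1000)
        got = {a: int(traj.z(a)[-1] > 0.5) for a in REGULATED_AGENTS}
        assert got == fp

    def test_frozen_inputs_override_driver(self):
        system = build_rhs(NetworkVariant.HEALTHY, frozen_inputs=(1.2, 0.8))
        y = system.initial_state()
        out = system.rhs(0.0, y, [0.0, 0.0])
        assert out[-2:] == pytest.approx([0.0, 0.0])


class TestHistoryBuffer:
    def test_constant_prehistory(self):
        h = HistoryBuffer(0.0, 0.1, np.array([3.0]), capacity=10)
        assert h.value(-5.0, 0) == 3.0

    def test_cubic_reproduces_cubic(self):
        f = lambda t: t**3 - 2 * t  # noqa: E731
        df = lambda t: 3 * t**2 - 2  # noqa: E731
        h = HistoryBuffer(0.0, 0.25, np.array([f(0.0)]), capacity=8)
        h.set_initial_derivative(np.array([df(0.0)]))
        for k in range(1, 9):
            t = 0.25 * k
            h.append(np.array([f(t)]), np.array([df(t)]))
        for t in np.linspace(0.0, 2.0, 29):
            assert h.value(t, 0) == pytest.approx(f(t), abs=1e-12)

    def test_linear_interpolation(self):
        h = HistoryBuffer(0.0, 1.0, np.array([0.0]), capacity=2, order="linear")
        h.append(np.array([2.0]), np.array([0.0]))
        assert h.value(0.5, 0) == pytest.approx(1.0)

    def test_query_beyond_end_raises(self):
        h = HistoryBuffer(0.0, 1.0, np.array([0.0]), capacity=2)
        with pytest.raises(ValueError):
            h.value(1.5, 0)

    def test_bad_order(self):
        with pytest.raises(ValueError):
            HistoryBuffer(0.0, 1.0, np.array([0.0]), 2, order="quintic")


class TestPhenotypeProfile:
    @pytest.fixture
    def short_delays(self):
        # small delays so the profile test stays cheap
        return DelayConfig(tau1_years=0.1, tau2_years=0.08)

    def test_stage_boundaries(self, short_delays):
        d = short_delays
        assert stage_label(0.0, d) == "PanIN1"
        assert stage_label(d.tau1_units, d) == "PanIN1"
        assert stage_label(d.tau1_units + d.tau2_units / 2, d) == "PanIN2"
        assert stage_label(d.tau1_units + d.tau2_units + 1.0, d) == "post"
        with pytest.raises(ValueError):
            stage_label(-1.0, d)

    def test_labels_partition_time_axis(self, short_delays):
        d = short_delays
        times = np.linspace(0.0, 30.0, 400)
        labels = [stage_label(t, d) for t in times]
        assert set(labels) == {"PanIN1", "PanIN2", "post"}
        # monotone: once a later stage starts, earlier ones never return
        order = {"PanIN1": 0, "PanIN2": 1, "post": 2}
        ranks = [order[label] for label in labels]
        assert ranks == sorted(ranks)

    def test_profile_means_and_errors(self, short_delays):
        d = short_delays
        system = build_rhs(NetworkVariant.CANCER, delays=d)
        y0 = system.initial_state({"y1": 1.0, "y3": 0.5})
        traj = integrate_dde(system, y0, t_end=30.0, dt=0.01, stride=20)
        prof = phenotype_profile(traj, d)
        assert set(prof["stage_means"]) == {"PanIN1", "PanIN2", "post"}
        for stage in prof["stage_means"].values():
            assert set(stage) == {"z1", "z2", "z3", "z4"}
        short = Trajectory(traj.times[:3], traj.states[:3])
        with pytest.raises(ValueError):
            phenotype_profile(short, d)
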