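"""RK4 dynamics, the balance equations and the steady-state oracle."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from qwasi.core import Volumes, ZValueSet
from qwasi.forcing import ForcingSet, GeneratorConfig, generate_forcings
from qwasi.solver import (
    FugacityState,
    SingularSystemError,
    rhs,
    rk4_step,
    simulate,
    steady_state,
)
from qwasi.transfer import DValueSet


def _unit_z():
    return ZValueSet(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


def _unit_volumes():
    return Volumes(1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0)


def _d(**kw):
    base = {name: 0.0 for name in (
        "d12d", "d12p", "d12w", "d12r", "d21d", "d24d", "d24s", "d42d", "d42r",
        "d10m", "d20m", "d40m", "d10t", "d20t", "d23h",
    )}
    base.update(kw)
    return DValueSet(**base)


class TestRhs:
    def test_pure_input_drives_air_only(self):
        d = _d(t01t=3.0)
        df = rhs(FugacityState(0, 0, 0), d, _unit_z(), _unit_volumes())
        assert df == (3.0, 0.0, 0.0)

    def test_no_processes_no_motion(self):
        df = rhs(FugacityState(1.0, 2.0, 3.0), _d(), _unit_z(), _unit_volumes())
        assert df == (0.0, 0.0, 0.0)

    def test_detailed_balance_of_symmetric_exchange(self):
        d = _d(d12d=2.0, d21d=2.0)
        df = rhs(FugacityState(0.7, 0.7, 0.0), d, _unit_z(), _unit_volumes())
        assert df[0] == pytest.approx(0.0, abs=1e-15)
        assert df[1] == pytest.approx(0.0, abs=1e-15)

    def test_air_advection_out_is_a_loss(self):
        d = _d(d10t=1.0)
        df = rhs(FugacityState(1.0, 0.0, 0.0), d, _unit_z(), _unit_volumes())
        assert df[0] == pytest.approx(-1.0)


class TestRk4Step:
    def test_exponential_decay_to_fifth_order(self):
        k = 0.01
        state = FugacityState(1.0, 1.0, 1.0)
        nxt = rk4_step(state, 1.0, lambda s: (-k * s.f1, -k * s.f2, -k * s.f4))
        assert abs(nxt.f1 - math.exp(-k)) < 1e-10

    def test_zero_derivative_leaves_state(self):
        state = FugacityState(0.3, 0.2, 0.1, t=5)
        nxt = rk4_step(state, 1.0, lambda s: (0.0, 0.0, 0.0))
        assert (nxt.f1, nxt.f2, nxt.f4) == (0.3, 0.2, 0.1)
        assert nxt.t == 6

    def test_fourth_order_convergence(self):
        """Halving the step cuts the global decay error ~16x."""
        k = 0.1

        def integrate(dt):
            f = FugacityState(1.0, 0.0, 0.0)
            for _ in range(round(10.0 / dt)):
                f = rk4_step(f, dt, lambda s: (-k * s.f1, 0.0, 0.0))
            return abs(f.f1 - math.exp(-k * 10.0))

        ratio = integrate(1.0) / integrate(0.5)
        assert 12.0 < ratio < 20.0

    def test_negative_result_clipped_with_warning(self):
        # a constant sink larger than the inventory drives the state negative
        state = FugacityState(1.0, 0.0, 0.0)
        with pytest.warns(RuntimeWarning, match="negative fugacity"):
            nxt = rk4_step(state, 1.0, lambda s: (-2.0, 0.0, 0.0))
        assert nxt.f1 == 0.0


class TestSteadyState:
    def test_zero_inputs_zero_fugacities(self):
        d = _d(d10t=1.0, d20t=1.0, d40m=1.0, d12d=0.5, d21d=0.5, d24d=0.2, d42d=0.2)
        f = steady_state(d, _unit_z(), _unit_volumes())
        assert (f.f1, f.f2, f.f4) == (0.0, 0.0, 0.0)

    def test_single_compartment_scalar_balance(self):
        d = _d(d10t=4.0, t01t=2.0, d20t=1.0, d40m=1.0)
        f = steady_state(d, _unit_z(), _unit_volumes())
        assert f.f1 == pytest.approx(2.0 / 4.0)

    def test_isolated_compartment_is_singular(self):
        with pytest.raises(SingularSystemError):
            steady_state(_d(d10t=1.0, d20t=1.0), _unit_z(), _unit_volumes())

    def test_rhs_vanishes_at_steady_state(self, rng):
        for _ in range(20):
            d = _random_system(rng)
            f = steady_state(d, _unit_z(), _unit_volumes())
            df = rhs(f, d, _unit_z(), _unit_volumes())
            scale = max(abs(f.f1), abs(f.f2), abs(f.f4), 1e-12)
            assert max(abs(x) for x in df) < 1e-9 * scale


def _random_system(rng):
    # rates kept well inside RK4's stability region for the 1-hour step
    u = lambda: float(rng.uniform(0.02, 0.2))
    return _d(
        d12d=u(), d12p=u(), d12w=u(), d12r=u(), d21d=u(), d24d=u(), d24s=u(),
        d42d=u(), d42r=u(), d10m=u(), d20m=u(), d40m=u(), d10t=u(), d20t=u(),
        d23h=u(), t01t=u(), t02t=u(),
    )


class TestOracleEquivalence:
    def test_long_integration_reaches_linear_solve(self, rng):
        """RK4 under frozen coefficients converges to the 3x3 steady solution."""
        z, vol = _unit_z(), _unit_volumes()
        for _ in range(100):
            d = _random_system(rng)
            target = steady_state(d, z, vol)
            state = FugacityState(0.0, 0.0, 0.0)
            for _ in range(600):  # 600 h at dt = 1 h; slowest mode ~< 20 h
                state = rk4_step(state, 1.0, lambda s: rhs(s, d, z, vol))
            for got, want in zip(
                (state.f1, state.f2, state.f4), (target.f1, target.f2, target.f4)
            ):
                assert got == pytest.approx(want, rel=1e-6)


def _constant_forcing(setup, n_days=30):
    """A forcing set in which every series is constant in time."""
    cfg = GeneratorConfig(
        temp_amplitude=0.0, temp_noise_sd=0.0, wind_log_sd=0.0,
        h2_amplitude=0.0, h2_noise_sd=0.0, rain_log_sd=0.0, rain_summer_factor=1.0,
        monthly_gsd={},
    )
    end = pd.Timestamp("2010-05-01") + pd.Timedelta(days=n_days - 1)
    return generate_forcings(
        0, start="2010-05-01", end=end, config=cfg,
        chem=setup.chem, constants=setup.constants,
    )


class TestSimulate:
    def test_full_window_returns_one_state_per_hour(self, full_trajectory):
        assert len(full_trajectory) == 7296
        assert len(full_trajectory.f2) == 7296

    def test_constant_forcing_steady_init_is_fixed_point(self, setup):
        forcing = _constant_forcing(setup)
        traj = simulate(setup.chem, setup.env, forcing, setup.constants, init="steady")
        for arr in (traj.f1, traj.f2, traj.f4):
            assert np.allclose(arr, arr[0], rtol=1e-9)
            assert arr[0] > 0

    def test_zero_inputs_decay_monotonically(self, setup):
        forcing = _constant_forcing(setup)
        monthly = forcing.monthly.copy()
        monthly["c_air_in"] = 0.0
        monthly["c_water_in"] = 0.0
        forcing = dataclasses.replace(forcing, monthly=monthly)
        init = FugacityState(1e-9, 1e-9, 1e-9)
        traj = simulate(setup.chem, setup.env, forcing, setup.constants, init=init)
        # individual compartments may transiently exchange, but the total
        # inventory of a pure-loss system decays monotonically to zero
        inventory = (
            traj.vz["air"] * traj.f1
            + traj.vz["water"] * traj.f2
            + traj.vz["sediment"] * traj.f4
        )
        assert np.all(np.diff(inventory) < 0)
        assert inventory[-1] < 0.9 * inventory[0]
        assert traj.f2[-1] < traj.f2[0]

    def test_first_step_matches_manual_rk4(self, setup, short_forcing):
        """One hand-assembled RK4 step reproduces the solver's first state."""
        from qwasi.solver import _coefficients_for_hour

        snap = short_forcing.snapshot(0)
        z, d, vol = _coefficients_for_hour(setup.chem, setup.env, setup.constants, snap)
        init = steady_state(d, z, vol)
        bumped = FugacityState(init.f1 * 1.1, init.f2 * 0.9, init.f4, t=0)
        manual = rk4_step(bumped, 1.0, lambda s: rhs(s, d, z, vol))
        traj = simulate(setup.chem, setup.env, short_forcing, setup.constants, init=bumped)
        assert traj.f1[0] == pytest.approx(manual.f1, rel=1e-12)
        assert traj.f2[0] == pytest.approx(manual.f2, rel=1e-12)
        assert traj.f4[0] == pytest.approx(manual.f4, rel=1e-12)

    def test_nonnegative_over_seeded_runs(self, setup):
        for seed in range(5):
            forcing = generate_forcings(
                seed, start="2010-05-01", end="2010-05-31",
                chem=setup.chem, constants=setup.constants,
            )
            traj = simulate(setup.chem, setup.env, forcing, setup.constants)
            assert (traj.f1 >= 0).all() and (traj.f2 >= 0).all() and (traj.f4 >= 0).all()

    def test_subhourly_step_agrees_with_hourly(self, setup, short_forcing):
        a = simulate(setup.chem, setup.env, short_forcing, setup.constants)
        b = simulate(setup.chem, setup.env, short_forcing, setup.constants, step_hours=0.5)
        # both are 4th-order accurate; they differ only by truncation error
        assert np.allclose(a.f2, b.f2, rtol=1e-3)
        assert np.allclose(a.f1, b.f1, rtol=1e-3)
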