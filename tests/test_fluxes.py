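"""Concentration conversion, flux budgets and mass-balance closure."""

import numpy as np
import pandas as pd
import pytest

from qwasi.core import ZValueSet, compute_z_values
from qwasi.fluxes import (
    aggregate_fluxes,
    concentrations_from_fugacity,
    instantaneous_fluxes,
    interface_net_flux,
    mol_per_hour_to_tonnes_per_year,
    monthly_mean_concentrations,
)
from qwasi.solver import FLUX_NAMES, FugacityState
from qwasi.transfer import DValueSet


def _d(**kw):
    base = {name: 0.0 for name in (
        "d12d", "d12p", "d12w", "d12r", "d21d", "d24d", "d24s", "d42d", "d42r",
        "d10m", "d20m", "d40m", "d10t", "d20t", "d23h",
    )}
    base.update(kw)
    return DValueSet(**base)


class TestConcentrations:
    def test_zero_fugacity_zero_concentrations(self, chem, env):
        z = compute_z_values(chem, env, 25.0)
        rec = concentrations_from_fugacity(FugacityState(0, 0, 0), z, chem, env)
        assert rec.air_gaseous_pg_m3 == 0
        assert rec.water_dissolved_pg_L == 0
        assert rec.sediment_solid_ng_g == 0

    def test_dissolved_unit_chain(self, chem, env):
        # f2 = 1e-9 Pa with z_water = 1e-3 -> 1e-12 mol/m3 * 290.83 g/mol
        # = 2.9083e-10 g/m3 = 290.83 pg/m3 = 0.29083 pg/L
        z = ZValueSet(1e-4, 1e-3, 1.0, 1.0, 1.0, 1e-4, 1e-3, 1.0)
        rec = concentrations_from_fugacity(FugacityState(0.0, 1e-9, 0.0), z, chem, env)
        assert rec.water_dissolved_pg_L == pytest.approx(0.29083, rel=1e-6)

    def test_linearity_in_fugacity(self, chem, env):
        z = compute_z_values(chem, env, 10.0)
        a = concentrations_from_fugacity(FugacityState(1e-10, 2e-9, 3e-9), z, chem, env)
        b = concentrations_from_fugacity(FugacityState(2e-10, 4e-9, 6e-9), z, chem, env)
        assert b.air_gaseous_pg_m3 == pytest.approx(2 * a.air_gaseous_pg_m3, rel=1e-12)
        assert b.suspended_ng_g == pytest.approx(2 * a.suspended_ng_g, rel=1e-12)
        assert b.sediment_solid_ng_g == pytest.approx(2 * a.sediment_solid_ng_g, rel=1e-12)


class TestInstantaneousFluxes:
    def test_zero_state_keeps_only_advective_inputs(self):
        d = _d(d12d=1.0, d21d=2.0, t01t=0.7)
        fluxes = instantaneous_fluxes(FugacityState(0, 0, 0), d)
        assert fluxes["t01t"] == 0.7
        assert all(
            fluxes[name] == 0.0 for name in fluxes if name not in ("t01t",)
        )

    def test_flux_is_d_times_source_fugacity(self):
        d = _d(d21d=2.0)
        fluxes = instantaneous_fluxes(FugacityState(0.0, 0.5, 0.0), d)
        assert fluxes["t21d"] == pytest.approx(1.0)

    def test_air_losses_sum(self):
        d = _d(d12d=1, d12p=2, d12w=3, d12r=4, d10m=5, d10t=6)
        f1 = 0.3
        fluxes = instantaneous_fluxes(FugacityState(f1, 0, 0), d)
        total = sum(fluxes[n] for n in ("t12d", "t12p", "t12w", "t12r", "t10m", "t10t"))
        assert total == pytest.approx((1 + 2 + 3 + 4 + 5 + 6) * f1, rel=1e-12)


class TestUnitConversion:
    @pytest.mark.parametrize(
        "mol_h, mw, expected",
        [
            (0.0, 100.0, 0.0),
            (1.0, 100.0, 0.876),  # 8760 * 100 / 1e6
            (0.115, 290.83, 0.293),  # the printed-rate cross-check
        ],
    )
    def test_known_values(self, mol_h, mw, expected):
        assert mol_per_hour_to_tonnes_per_year(mol_h, mw) == pytest.approx(
            expected, rel=2e-3
        )

    def test_exact_formula(self, full_trajectory, chem):
        ledger = aggregate_fluxes(full_trajectory, chem.molar_mass)
        ta = ledger.to_tonnes_per_year()
        expected = ledger.table * 8760 * chem.molar_mass / 1e6
        pd.testing.assert_frame_equal(ta, expected)


class TestAggregation:
    def test_monthly_means_are_time_weighted(self, full_trajectory, chem):
        ledger = aggregate_fluxes(full_trajectory, chem.molar_mass)
        may = full_trajectory.month_of_hour == 0
        manual = full_trajectory.fluxes["t21d"][may].mean()
        assert ledger.table.loc["2010-05", "t21d"] == pytest.approx(manual, rel=1e-12)

    def test_annual_row_is_window_mean(self, full_trajectory, chem):
        ledger = aggregate_fluxes(full_trajectory, chem.molar_mass)
        assert ledger.table.loc["annual", "t40m"] == pytest.approx(
            full_trajectory.fluxes["t40m"].mean(), rel=1e-12
        )

    def test_mass_balance_closure(self, full_trajectory, full_forcing, chem):
        """Annual (net input - net output) equals the inventory change."""
        ledger = aggregate_fluxes(full_trajectory, chem.molar_mass)
        net = (ledger.net_input() - ledger.net_output()) * full_forcing.n_hours
        inventory = full_trajectory.inventory_change()
        assert net == pytest.approx(inventory, rel=1e-4)

    def test_all_ledger_fluxes_nonnegative(self, full_trajectory, chem):
        ledger = aggregate_fluxes(full_trajectory, chem.molar_mass)
        assert (ledger.table[list(FLUX_NAMES)] >= 0).all().all()


class TestInterfaceNetFlux:
    def test_sign_convention(self, full_trajectory, chem):
        ledger = aggregate_fluxes(full_trajectory, chem.molar_mass)
        net = interface_net_flux(ledger, "air-water")
        table = ledger.table.drop(index="annual")
        manual = (
            table[["t12d", "t12p", "t12w", "t12r"]].sum(axis=1) - table["t21d"]
        )
        assert np.allclose(net.to_numpy(), manual.to_numpy())

    def test_volatilization_is_negative(self, full_trajectory, chem):
        ledger = aggregate_fluxes(full_trajectory, chem.molar_mass)
        # zero out deposition: net must equal -T21d < 0
        table = ledger.table.copy()
        for name in ("t12d", "t12p", "t12w", "t12r"):
            table[name] = 0.0
        from qwasi.fluxes import FluxLedger

        net = interface_net_flux(FluxLedger(table, chem.molar_mass), "air-water")
        assert (net < 0).all()

    def test_unknown_interface_rejected(self, full_trajectory, chem):
        ledger = aggregate_fluxes(full_trajectory, chem.molar_mass)
        with pytest.raises(ValueError, match="unknown interface"):
            interface_net_flux(ledger, "air-sediment")

    def test_share_percentages_sum_to_100(self, full_trajectory, chem):
        """Process shares of a parent flux partition it exactly."""
        ledger = aggregate_fluxes(full_trajectory, chem.molar_mass)
        row = ledger.table.loc["annual"]
        gas_to_water = sum(row[n] for n in ("t12d", "t12p", "t12w", "t12r"))
        shares = [100 * row[n] / gas_to_water for n in ("t12d", "t12p", "t12w", "t12r")]
        assert sum(shares) == pytest.approx(100.0, abs=1e-2)


class TestMonthlyConcentrations:
    def test_shape_and_positivity(self, full_trajectory, chem, env):
        monthly = monthly_mean_concentrations(full_trajectory, chem, env)
        assert list(monthly.columns) == ["air", "water", "sediment"]
        assert len(monthly) == 10
        assert (monthly > 0).all().all()
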