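"""Truncated parameter sampling, MC ensembles and rate-constant recovery."""

import numpy as np
import pytest

from qwasi.montecarlo import (
    MonteCarloSummary,
    ParameterDistribution,
    apply_draw,
    default_distributions,
    recover_km_sediment,
    run_monte_carlo,
    sample_parameters,
    select_sensitive,
    summarize_semi_iqr,
)
from qwasi.sensitivity import COMPARTMENTS


class TestParameterDistribution:
    def test_lognormal_draws_inside_truncation_band_and_positive(self, rng):
        dist = ParameterDistribution("km4", "lognormal", central=2.9e-4, dispersion=1.8)
        draws = dist.draw(rng, 10_000)
        assert (draws > 0).all()
        assert (draws >= 2.9e-4 / 1.8 - 1e-18).all()
        assert (draws <= 2.9e-4 * 1.8 + 1e-18).all()

    def test_normal_draws_inside_mean_pm_sd(self, rng):
        dist = ParameterDistribution("T", "normal", central=0.0, dispersion=2.0)
        draws = dist.draw(rng, 10_000)
        assert (np.abs(draws) <= 2.0).all()

    def test_zero_dispersion_returns_central(self, rng):
        assert ParameterDistribution("x", "lognormal", 5.0, 1.0).draw(rng, 3).tolist() == [
            5.0, 5.0, 5.0,
        ]
        assert ParameterDistribution("y", "normal", 1.5, 0.0).draw(rng, 1)[0] == 1.5

    def test_same_seed_identical_draws(self):
        dist = ParameterDistribution("km4", "lognormal", 1.0, 1.5)
        a = dist.draw(np.random.default_rng(9), 50)
        b = dist.draw(np.random.default_rng(9), 50)
        assert np.array_equal(a, b)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ParameterDistribution("x", "lognormal", central=-1.0)
        with pytest.raises(ValueError):
            ParameterDistribution("x", "lognormal", central=1.0, dispersion=0.5)
        with pytest.raises(ValueError):
            ParameterDistribution("x", "uniform")


class TestSampling:
    def test_static_scalar_monthly_vector(self, rng):
        dists = [
            ParameterDistribution("km4", "lognormal", 1e-4, 1.5, scope="static"),
            ParameterDistribution("C1", "lognormal", 1.0, 1.2, scope="monthly"),
        ]
        draw = sample_parameters(dists, rng, n_months=10)
        assert draw["km4"].shape == (1,)
        assert draw["C1"].shape == (10,)

    def test_apply_draw_scales_monthly_series(self, setup, short_forcing, rng):
        dists = [ParameterDistribution("C1", "lognormal", 1.0, 1.4, scope="monthly")]
        draw = sample_parameters(dists, rng, n_months=2)
        _, perturbed = apply_draw(setup, short_forcing, draw, dists)
        expected = short_forcing.monthly["c_air_in"].to_numpy() * draw["C1"]
        assert np.allclose(perturbed.monthly["c_air_in"].to_numpy(), expected)

    def test_apply_draw_replaces_static_parameter(self, setup, short_forcing, rng):
        dists = [ParameterDistribution("km4", "lognormal", 2.9e-4, 1.5, scope="static")]
        draw = sample_parameters(dists, rng)
        new_setup, _ = apply_draw(setup, short_forcing, draw, dists)
        assert new_setup.chem.km_sediment == draw["km4"][0]


class TestSemiIqr:
    def test_hand_quartiles(self):
        # {1..5}: Q1 = 2, Q3 = 4 under linear interpolation -> semi-IQR = 1
        ensemble = np.array([1.0, 2.0, 3.0, 4.0, 5.0]).reshape(5, 1, 1)
        summary = summarize_semi_iqr(ensemble, ["m"], ["air"])
        assert summary.semi_iqr.iloc[0, 0] == pytest.approx(1.0)
        assert summary.median.iloc[0, 0] == pytest.approx(3.0)

    def test_constant_ensemble(self):
        ensemble = np.full((8, 2, 3), 7.5)
        summary = summarize_semi_iqr(ensemble, ["a", "b"], COMPARTMENTS)
        assert (summary.semi_iqr.to_numpy() == 0).all()
        assert (summary.median.to_numpy() == 7.5).all()

    def test_translation_and_scale_behaviour(self, rng):
        base = rng.lognormal(0, 0.5, size=(40, 3, 3))
        s1 = summarize_semi_iqr(base, list("abc"), COMPARTMENTS)
        s2 = summarize_semi_iqr(base + 5.0, list("abc"), COMPARTMENTS)
        s3 = summarize_semi_iqr(base * 3.0, list("abc"), COMPARTMENTS)
        assert np.allclose(s2.semi_iqr, s1.semi_iqr)
        assert np.allclose(s3.semi_iqr, 3.0 * s1.semi_iqr)

    def test_quartile_ordering_enforced(self):
        import pandas as pd

        frame = pd.DataFrame({"air": [1.0]})
        with pytest.raises(ValueError, match="ordered"):
            MonteCarloSummary(
                median=frame, q1=frame + 1.0, q3=frame, semi_iqr=frame * 0.0, n_runs=2
            )


class TestRunMonteCarlo:
    def test_zero_dispersion_gives_zero_semi_iqr(self, setup, short_forcing):
        dists = [
            ParameterDistribution("km4", "lognormal", setup.chem.km_sediment, 1.0),
            ParameterDistribution("C1", "lognormal", 1.0, 1.0, scope="monthly"),
        ]
        summary = run_monte_carlo(setup, short_forcing, dists, n_runs=4, seed=3)
        assert (summary.semi_iqr.to_numpy() == 0).all()
        assert summary.n_runs == 4

    def test_seeded_reproducibility(self, setup, short_forcing):
        dists = default_distributions(setup)
        a = run_monte_carlo(setup, short_forcing, dists, n_runs=10, seed=5)
        b = run_monte_carlo(setup, short_forcing, dists, n_runs=10, seed=5)
        assert a.median.equals(b.median)
        assert a.semi_iqr.equals(b.semi_iqr)

    def test_dispersion_widens_bands(self, setup, short_forcing):
        narrow = [ParameterDistribution("C1", "lognormal", 1.0, 1.05, scope="monthly")]
        wide = [ParameterDistribution("C1", "lognormal", 1.0, 1.8, scope="monthly")]
        s_narrow = run_monte_carlo(setup, short_forcing, narrow, n_runs=30, seed=2)
        s_wide = run_monte_carlo(setup, short_forcing, wide, n_runs=30, seed=2)
        assert (
            s_wide.semi_iqr["air"].mean() > s_narrow.semi_iqr["air"].mean()
        )


class TestSensitiveSubset:
    def test_top_quantile_selection(self):
        import pandas as pd

        static = pd.DataFrame(
            {
                "parameter": ["a", "a", "b", "b", "c", "c", "d", "d"],
                "output": ["air", "water"] * 4,
                "Cn": [0.9, 0.8, 0.1, 0.2, 0.05, 0.1, 0.01, 0.02],
            }
        )
        chosen, _ = select_sensitive(static, quantile=0.75)
        assert chosen == ["a"]


class TestRateRecovery:
    def test_km4_recovered_within_ten_percent(self, setup, short_forcing):
        """Grid search over the sediment degradation rate finds the truth."""
        from qwasi.fluxes import monthly_mean_concentrations
        from qwasi.solver import simulate

        truth_factor = 1.35
        truth = setup.with_parameter("km4", setup.chem.km_sediment * truth_factor)
        traj = simulate(truth.chem, truth.env, short_forcing, truth.constants)
        observed = monthly_mean_concentrations(traj, truth.chem, truth.env)[
            "sediment"
        ].to_numpy()
        grid = np.exp(np.linspace(np.log(0.5), np.log(2.5), 25))
        best, table = recover_km_sediment(setup, short_forcing, observed, grid)
        assert best == pytest.approx(truth.chem.km_sediment, rel=0.10)
        assert table["sse"].min() < table["sse"].max()
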