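"""HDI computation, trait differencing, summaries, and predictive intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fvcbayes as fb
from fvcbayes.mcmc import PosteriorDraws


class TestHDI:
    def test_constant_sample_zero_width(self):
        interval = fb.hdi(np.full(500, 3.3), 0.9)
        assert interval.lower == interval.upper == 3.3

    def test_uniform_width(self, rng):
        x = rng.uniform(0, 1, 1_000_000)
        assert fb.hdi(x, 0.5).width == pytest.approx(0.5, abs=0.01)

    def test_normal_95(self, rng):
        x = rng.standard_normal(1_000_000)
        interval = fb.hdi(x, 0.95)
        assert interval.lower == pytest.approx(-1.96, abs=0.02)
        assert interval.upper == pytest.approx(1.96, abs=0.02)

    def test_agrees_with_arviz(self, rng):
        arviz = pytest.importorskip("arviz")
        x = rng.gamma(3.0, 2.0, 200_000)
        ours = fb.hdi(x, 0.9)
        lo, hi = arviz.hdi(x, hdi_prob=0.9)
        assert ours.lower == pytest.approx(lo, abs=0.05)
        assert ours.upper == pytest.approx(hi, abs=0.05)

    def test_width_monotone_in_mass(self, rng):
        x = rng.standard_normal(50_000)
        widths = [fb.hdi(x, m).width for m in (0.5, 0.7, 0.9, 0.95, 0.99)]
        assert widths == sorted(widths)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 100"):
            fb.hdi(np.arange(50), 0.9)


class TestMaxHDILevel:
    def test_symmetric_about_zero_is_none(self, rng):
        diffs = rng.standard_normal(50_000)
        res = fb.max_hdi_level_excluding_zero(diffs)
        assert res.max_hdi_level is None

    def test_clearly_shifted_reaches_99(self, rng):
        diffs = rng.normal(10.0, 1.0, 50_000)
        res = fb.max_hdi_level_excluding_zero(diffs)
        assert res.max_hdi_level == 0.99

    def test_intermediate_level_matches_normal_quantile_oracle(self, rng):
        # For N(0.5, 1) the HDI at mass m is ~ 0.5 +/- z_{(1+m)/2}; it excludes
        # zero iff m < 2*Phi(0.5) - 1 = 0.383.
        levels = (0.2, 0.3, 0.5, 0.7)
        for seed in range(5):
            diffs = np.random.default_rng(seed).normal(0.5, 1.0, 200_000)
            res = fb.max_hdi_level_excluding_zero(diffs, levels=levels)
            assert res.max_hdi_level == pytest.approx(0.3)

    def test_monotone_exclusion_for_unimodal_sample(self, rng):
        diffs = rng.normal(1.2, 1.0, 100_000)
        res = fb.max_hdi_level_excluding_zero(diffs)
        if res.max_hdi_level is not None:
            for lvl in res.levels:
                if lvl < res.max_hdi_level:
                    assert fb.hdi(diffs, lvl).excludes(0.0)


class TestDifferenceDistribution:
    def test_identity_pairing_of_same_run_is_zero(self, fitted_run):
        d = fb.genotype_difference_distribution(fitted_run, fitted_run,
                                                "mu_Vcmax25", permute=False)
        assert np.all(d == 0.0)

    def test_shift_linearity(self, fitted_pair):
        a, b = fitted_pair["g1"], fitted_pair["g2"]
        d0 = fb.genotype_difference_distribution(a, b, "mu_Vcmax25", seed=4)
        shifted = PosteriorDraws(
            parameter_names=b.parameter_names,
            draws=b.draws + 3.0 * (np.array(b.parameter_names) == "mu_Vcmax25"),
            deviance_trace=b.deviance_trace,
            seed=b.seed, schedule=b.schedule, model_code=b.model_code,
            genotype_id=b.genotype_id, individual_ids=b.individual_ids,
        )
        d1 = fb.genotype_difference_distribution(a, shifted, "mu_Vcmax25", seed=4)
        assert d1.mean() == pytest.approx(d0.mean() - 3.0, rel=1e-9)

    def test_variance_of_independent_normals(self, rng):
        def fake(name_seed):
            r = np.random.default_rng(name_seed)
            return PosteriorDraws(
                parameter_names=["mu_x", "sigma"],
                draws=np.stack([r.standard_normal((5000, 2))]),
                deviance_trace=np.zeros((1, 5000)),
                seed=0, schedule=(0, 5000, 1, 1), model_code="CaCc_Jm",
                genotype_id="g", individual_ids=[],
            )
        d = fb.genotype_difference_distribution(fake(1), fake(2), "mu_x", seed=0)
        assert d.var() == pytest.approx(2.0, rel=0.1)

    def test_missing_symbol(self, fitted_pair):
        with pytest.raises(KeyError):
            fb.genotype_difference_distribution(fitted_pair["g1"],
                                                fitted_pair["g2"], "mu_nope")

    def test_model_mismatch(self, fitted_run, small_dataset):
        curves, _ = small_dataset
        g2 = [c for c in curves if c.genotype_id == "g2"]
        other = fb.run_mcmc(g2, fb.ModelSpec.from_code("CaCc_Jf"),
                            fb.RunConfig(chains=2, iterations=200, burn_in=200,
                                         thin=2, seed=8))
        with pytest.raises(ValueError, match="different model"):
            fb.genotype_difference_distribution(fitted_run, other, "mu_Vcmax25")


class TestSummaries:
    def _dummy_draws(self, values):
        x = np.asarray(values, dtype=float)[None, :, None]
        return PosteriorDraws(
            parameter_names=["mu_x"], draws=x,
            deviance_trace=np.zeros((1, x.shape[1])),
            seed=0, schedule=(0, x.shape[1], 1, 1), model_code="CaCc_Jm",
            genotype_id="g", individual_ids=[],
        )

    def test_constant_draws(self):
        stats_ = fb.summarize_posterior(self._dummy_draws(np.full(100, 7.0)))
        row = stats_.loc["mu_x"]
        assert set(row[["median", "q25", "q75", "min", "max"]]) == {7.0}

    def test_known_vector_order_statistics(self):
        stats_ = fb.summarize_posterior(self._dummy_draws(np.arange(1, 101)))
        row = stats_.loc["mu_x"]
        assert row["median"] == pytest.approx(50.5)
        assert row["q25"] == pytest.approx(25.75)
        assert row["q75"] == pytest.approx(75.25)
        assert (row["min"], row["max"]) == (1.0, 100.0)


def _ladder_grid(n=12):
    ca = np.array(fb.DEFAULT_CO2_LADDER) * 1e-6 * 101325.0
    return {
        "Ca": ca, "Ci": 0.7 * ca, "gs": np.full(n, 3.0),
        "Q": np.full(n, 2000.0), "phiPSII": np.full(n, 0.38),
        "T": np.full(n, 22.0), "O": np.full(n, 0.21 * 101325.0),
    }


class TestPredictiveIntervals:
    def test_interval_nesting(self, fitted_run, jm_spec):
        grid = _ladder_grid()
        wide = fb.posterior_predictive_interval(fitted_run, jm_spec, grid, 0.95)
        narrow = fb.posterior_predictive_interval(fitted_run, jm_spec, grid, 0.70)
        assert np.all(wide["lower"] <= narrow["lower"] + 1e-9)
        assert np.all(narrow["upper"] <= wide["upper"] + 1e-9)

    def test_degenerate_posterior_zero_width(self, fitted_run, jm_spec):
        frozen = PosteriorDraws(
            parameter_names=fitted_run.parameter_names,
            draws=np.repeat(fitted_run.draws.mean(axis=(0, 1))[None, None, :],
                            200, axis=1),
            deviance_trace=np.zeros((1, 200)),
            seed=0, schedule=fitted_run.schedule, model_code=fitted_run.model_code,
            genotype_id=fitted_run.genotype_id,
            individual_ids=fitted_run.individual_ids,
        )
        out = fb.posterior_predictive_interval(frozen, jm_spec, _ladder_grid(), 0.95)
        np.testing.assert_allclose(out["lower"], out["upper"], rtol=1e-9)

    def test_calibration_with_observation_noise(self, fitted_run, small_dataset,
                                                jm_spec):
        """Held-out noisy observations mostly fall inside the 95% band."""
        curves, _ = small_dataset
        g1 = [c for c in curves if c.genotype_id == "g1"]
        inside = total = 0
        for curve in g1:
            grid = {k: curve.column(k) for k in ("Ca", "Ci", "gs", "Q",
                                                 "phiPSII", "T", "O")}
            out = fb.posterior_predictive_interval(
                fitted_run, jm_spec, grid, 0.95, scope="individual",
                individual_id=curve.individual_id,
                include_observation_noise=True, seed=1,
            )
            an = curve.column("An")
            inside += int(np.sum((an >= out["lower"]) & (an <= out["upper"])))
            total += an.size
        assert inside / total >= 0.85

    def test_pooling_with_itself_is_identity(self, fitted_run, jm_spec):
        grid = _ladder_grid()
        single = fb.posterior_predictive_interval(fitted_run, jm_spec, grid, 0.95,
                                                  max_draws=10 ** 9)
        pooled = fb.pooled_accession_prediction([fitted_run, fitted_run], jm_spec,
                                                grid, 0.95)
        # duplication leaves the sample distribution unchanged; quantile
        # interpolation differs only at O(1/n)
        np.testing.assert_allclose(pooled["lower"], single["lower"], atol=0.05)
        np.testing.assert_allclose(pooled["upper"], single["upper"], atol=0.05)

    def test_pooling_two_runs_at_least_as_wide(self, fitted_pair, jm_spec):
        grid = _ladder_grid()
        a = fb.posterior_predictive_interval(fitted_pair["g1"], jm_spec, grid,
                                             0.95, max_draws=10 ** 9)
        b = fb.posterior_predictive_interval(fitted_pair["g2"], jm_spec, grid,
                                             0.95, max_draws=10 ** 9)
        pooled = fb.pooled_accession_prediction(list(fitted_pair.values()),
                                                jm_spec, grid, 0.95)
        narrow = np.minimum(a["upper"] - a["lower"], b["upper"] - b["lower"])
        assert np.all(pooled["upper"] - pooled["lower"] >= narrow - 1e-6)

    def test_pooling_spec_mismatch(self, fitted_run):
        with pytest.raises(ValueError):
            fb.pooled_accession_prediction([fitted_run],
                                           fb.ModelSpec.from_code("CiCc_Jf"),
                                           _ladder_grid())

    def test_residual_summary(self, fitted_run, small_dataset, jm_spec):
        curves, _ = small_dataset
        g1 = [c for c in curves if c.genotype_id == "g1"]
        out = fb.residual_summary(fitted_run, g1, jm_spec)
        assert 0 < out["rmse"] < 5.0
        assert out["residual_se"] < out["residual_sd"]
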