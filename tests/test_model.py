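"""Sampler correctness: conjugate oracle, deviance identities, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import beta as beta_dist

from fgmspatial.design import ModelSpec, build_design
from fgmspatial.model import (
    BayesSpatialLogit,
    BayesSpatialLogitResults,
    bernoulli_deviance,
    load_draws,
)
from fgmspatial.scenarios import _reference_frame, two_group_dataset
from fgmspatial.synthetic import true_linear_predictor


def intercept_only_records(n, k, rng):
    df = _reference_frame(n, rng)
    df["fgm_status"] = np.array([1] * k + [0] * (n - k))
    df["age_at_cutting"] = np.where(df["fgm_status"] == 1, 0.0, np.nan)
    return df


INTERCEPT_SPEC = ModelSpec(
    "m1", "individual", smooth_covariates=(), include_weight_covariate=False
)


class TestConjugateOracle:
    def test_intercept_only_posterior_matches_beta(self, rng):
        df = intercept_only_records(1000, 200, rng)
        model = BayesSpatialLogit.from_dataframe(df, INTERCEPT_SPEC)
        res = model.fit(iterations=3000, burn_in=800, seed=3)
        p = expit(res.theta_draws[:, 0])
        lo, hi = np.quantile(p, [0.025, 0.975])
        assert p.mean() == pytest.approx(beta_dist.mean(201, 801), abs=0.02)
        assert lo == pytest.approx(beta_dist.ppf(0.025, 201, 801), abs=0.02)
        assert hi == pytest.approx(beta_dist.ppf(0.975, 201, 801), abs=0.02)


class TestDeviance:
    def test_half_probability_closed_form(self):
        y = np.array([0, 1, 1, 0, 1])
        assert bernoulli_deviance(y, np.full(5, 0.5)) == pytest.approx(10 * np.log(2))

    def test_perfect_prediction_tends_to_zero(self):
        y = np.array([0.0, 1.0])
        assert bernoulli_deviance(y, np.array([1e-13, 1 - 1e-13])) < 1e-9

    def test_stored_deviance_matches_independent_recomputation(self, fitted_m2):
        _, _, model, res = fitted_m2
        for i in np.linspace(0, res.n_draws - 1, 10).astype(int):
            eta = res.linear_predictor(int(i))
            direct = -2 * np.sum(
                np.log(
                    np.where(model.design.y == 1, expit(eta), 1 - expit(eta))
                )
            )
            assert res.deviance_draws[i] == pytest.approx(direct, rel=1e-9)


class TestLinearPredictor:
    def test_zero_draw_gives_half_probability(self, fitted_m2):
        _, _, model, res = fitted_m2
        zero = BayesSpatialLogitResults(
            model, np.zeros((1, model.n_coef)), {}, np.array([0.0]), res.mcmc
        )
        eta = zero.linear_predictor(0)
        assert np.allclose(eta, 0.0)

    def test_model_assembly_matches_generator_assembly(self, fitted_m2):
        records, params, model, res = fitted_m2
        # inject the true parameters into the model's coefficient layout
        theta = np.zeros(model.n_coef)
        d = model.design
        for j, name in enumerate(d.fixed_names):
            if name == "intercept":
                theta[j] = params.beta0
            elif name == "weight":
                theta[j] = params.beta_w
            else:
                cov, lev = name[:-1].split("[")
                theta[j] = params.beta[cov].get(lev, 0.0)
        for sname in d.info.smooth_names:
            theta[model.block_slices[sname]] = params.smooth_fns[sname]
        theta[model.block_slices["u_str"]] = params.u_str
        fake = BayesSpatialLogitResults(
            model, theta[None, :], {}, np.array([0.0]), res.mcmc
        )
        eta_model = fake.linear_predictor(0)
        eta_gen = true_linear_predictor(records, params, model.structure)
        assert np.allclose(eta_model, eta_gen, atol=1e-12)

    def test_out_of_range_draw_rejected(self, fitted_m2):
        *_, res = fitted_m2
        with pytest.raises(IndexError):
            res.linear_predictor(res.n_draws)


class TestSamplerContracts:
    def test_identical_seed_gives_identical_draws(self, rng):
        df, spec, _ = two_group_dataset(n=400, seed=5)
        model = BayesSpatialLogit.from_dataframe(df, spec)
        a = model.fit(iterations=300, burn_in=100, seed=9)
        b = model.fit(iterations=300, burn_in=100, seed=9)
        assert np.array_equal(a.theta_draws, b.theta_draws)
        assert np.array_equal(a.deviance_draws, b.deviance_draws)

    def test_binary_covariate_posterior_covers_true_odds_ratio(self):
        df, spec, _ = two_group_dataset(n=5000, seed=21, odds_ratio=8.0)
        model = BayesSpatialLogit.from_dataframe(df, spec)
        res = model.fit(iterations=1500, burn_in=500, seed=22)
        por = res.odds_ratios().set_index("level").loc["cut"]
        assert por["q2.5"] < 8.0 < por["q97.5"]
        # ML logistic oracle agrees with the posterior centre
        import statsmodels.api as sm

        d = model.design
        ml = sm.GLM(d.y, d.X_fixed, family=sm.families.Binomial()).fit()
        assert np.log(por["POR"]) == pytest.approx(
            ml.params[d.fixed_names.index("mother_fgm[cut]")], abs=0.15
        )

    def test_spatially_null_data_shrinks_structured_effects(self, lattice, rng):
        from fgmspatial.scenarios import recovery_dataset

        records, _, graph, _ = recovery_dataset(seed=31, tau_str=1e8)
        model = BayesSpatialLogit.from_dataframe(
            records, ModelSpec("m2", "individual"), graph=graph
        )
        res = model.fit(iterations=700, burn_in=300, seed=32)
        u = res.block("u_str")
        assert (np.abs(u.mean(axis=0)) < u.std(axis=0)).mean() > 0.8

    def test_structured_draws_satisfy_constraints(self, fitted_m2):
        _, _, model, res = fitted_m2
        u = res.block("u_str")
        for row in model.structure.constraints:
            assert np.abs(u @ row).max() < 1e-8

    def test_missing_structure_rejected(self, rng):
        df, _, _ = two_group_dataset(n=100, seed=1)
        with pytest.raises(ValueError, match="graph"):
            BayesSpatialLogit.from_dataframe(df, ModelSpec("m2", "individual"))

    def test_iterations_must_exceed_burn_in(self, rng):
        df, spec, _ = two_group_dataset(n=100, seed=2)
        model = BayesSpatialLogit.from_dataframe(df, spec)
        with pytest.raises(ValueError, match="exceed"):
            model.fit(iterations=100, burn_in=100, seed=1)


class TestPersistence:
    def test_draw_archive_round_trip(self, tmp_path):
        df, spec, _ = two_group_dataset(n=300, seed=8)
        model = BayesSpatialLogit.from_dataframe(df, spec)
        res = model.fit(iterations=250, burn_in=100, seed=4)
        res.save(tmp_path / "arch")
        draws, meta = load_draws(tmp_path / "arch")
        assert meta["spec"]["complexity"] == "m1"
        assert meta["mcmc"]["seed"] == 4
        assert np.allclose(draws[res.coef_names].to_numpy(), res.theta_draws)
        assert np.allclose(draws["deviance"], res.deviance_draws)

    def test_summary_mentions_dic_and_levels(self, fitted_m2):
        *_, res = fitted_m2
        text = res.summary()
        assert "DIC" in text and "mother_fgm" in text
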