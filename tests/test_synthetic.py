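"""Generator contracts: geography, population, outcomes, two-period design."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from fgmspatial.geo import icar_precision
from fgmspatial.schema import read_records, write_records
from fgmspatial.synthetic import (
    CovariateConfig,
    TrueParams,
    calibrate_intercept,
    default_true_params,
    generate_geography,
    generate_population,
    make_two_period,
    read_params,
    simulate_outcomes,
    write_params,
)


class TestGeography:
    def test_lattice_is_connected(self):
        graph, zones = generate_geography(12, (3, 4), seed=1)
        assert graph.n_nodes == 12 and len(graph.components) == 1
        assert set(zones) == set(graph.node_ids)

    def test_2x2_grid_queen_edge_count(self):
        graph, _ = generate_geography(4, (2, 2), seed=1)
        assert graph.n_edges == 6

    def test_same_seed_reproduces(self):
        a = generate_geography(9, (3, 3), seed=5)
        b = generate_geography(9, (3, 3), seed=5)
        assert a[0] == b[0] and a[1] == b[1]

    def test_too_few_states_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            generate_geography(3, (1, 3), seed=0)

    def test_states_must_fit_grid(self):
        with pytest.raises(ValueError, match="fit"):
            generate_geography(10, (3, 3), seed=0)


class TestPopulation:
    def test_nesting_and_size(self, lattice):
        graph, zones, _ = lattice
        df = generate_population(graph, zones, 5, 50, seed=3)
        assert len(df) == 12 * 5 * 50
        states_per_cluster = df.groupby("cluster_id")["state_id"].nunique()
        assert (states_per_cluster == 1).all()
        assert df["weight"].mean() == pytest.approx(1.0)

    def test_equal_probability_design_gives_unit_weights(self, lattice):
        graph, zones, _ = lattice
        cfg = CovariateConfig(weight_dispersion=0.0)
        df = generate_population(graph, zones, 3, 20, config=cfg, seed=3)
        assert np.allclose(df["weight"], 1.0)

    def test_bad_probabilities_rejected(self, lattice):
        graph, zones, _ = lattice
        cfg = CovariateConfig(support={"no": 0.5, "yes": 0.2, "dk": 0.2})
        with pytest.raises(ValueError, match="sum to 1"):
            generate_population(graph, zones, 2, 10, config=cfg, seed=0)

    def test_religion_mixture_within_binomial_bounds(self, lattice):
        graph, zones, _ = lattice
        df = generate_population(graph, zones, 10, 60, seed=4)
        north = df[df["zone"].str.startswith("north")]
        n = len(north)
        k = (north["religion"] == "islam").sum()
        lo, hi = binom.ppf([0.005, 0.995], n, 0.70)
        assert lo <= k <= hi


class TestOutcomes:
    def test_intercept_only_prevalence_in_exact_binomial_interval(self, lattice):
        graph, zones, structure = lattice
        df = generate_population(graph, zones, 10, 84, seed=6)  # n = 10080
        p0 = 0.2
        params = TrueParams(beta0=float(np.log(p0 / (1 - p0))))
        out = simulate_outcomes(df, params, structure, seed=6)
        k = out["fgm_status"].sum()
        lo, hi = binom.ppf([0.005, 0.995], len(out), p0)
        assert lo <= k <= hi

    def test_mother_cut_odds_ratio_recovered_in_2x2_table(self, lattice):
        graph, zones, structure = lattice
        df = generate_population(graph, zones, 10, 80, seed=7)
        params = TrueParams(
            beta0=float(np.log(0.1 / 0.9)), beta={"mother_fgm": {"cut": float(np.log(8))}}
        )
        out = simulate_outcomes(df, params, structure, seed=7)
        tab = pd.crosstab(out["mother_fgm"], out["fgm_status"])
        orhat = (tab.loc["cut", 1] * tab.loc["uncut", 0]) / (
            tab.loc["cut", 0] * tab.loc["uncut", 1]
        )
        se = np.sqrt((1.0 / tab.to_numpy()).sum())
        assert abs(np.log(orhat) - np.log(8)) < 4 * se

    def test_saturated_intercept_cuts_everyone(self, lattice):
        graph, zones, structure = lattice
        df = generate_population(graph, zones, 2, 20, seed=8)
        out = simulate_outcomes(df, TrueParams(beta0=50.0), structure, seed=8)
        assert (out["fgm_status"] == 1).all()

    def test_age_at_cutting_consistency(self, lattice):
        graph, zones, structure = lattice
        df = generate_population(graph, zones, 5, 40, seed=9)
        params = TrueParams(beta0=0.0)
        out = simulate_outcomes(df, params, structure, seed=9)
        cut = out[out["fgm_status"] == 1]
        uncut = out[out["fgm_status"] == 0]
        assert cut["age_at_cutting"].notna().all()
        assert uncut["age_at_cutting"].isna().all()
        assert (cut["age_at_cutting"] <= cut["girl_age"]).all()

    def test_unknown_level_named_in_error(self, lattice):
        graph, zones, structure = lattice
        df = generate_population(graph, zones, 2, 10, seed=10)
        params = TrueParams(beta0=0.0, beta={"religion": {"animist": 1.0}})
        with pytest.raises(ValueError, match="animist"):
            simulate_outcomes(df, params, structure, seed=10)


class TestCalibration:
    def test_intercept_calibration_hits_target(self, lattice):
        graph, zones, structure = lattice
        df = generate_population(graph, zones, 5, 50, seed=13)
        params = default_true_params(structure, "pre", seed=13, smooths=("girl_age",))
        cal = calibrate_intercept(df, params, 0.192, structure)
        from fgmspatial.synthetic import true_linear_predictor
        from scipy.special import expit

        eta = true_linear_predictor(df, cal, structure)
        w = df["weight"].to_numpy()
        assert (w * expit(eta)).sum() / w.sum() == pytest.approx(0.192, abs=1e-8)

    def test_structured_effects_sum_to_zero(self, lattice):
        _, _, structure = lattice
        params = default_true_params(structure, "post", seed=3)
        for row in structure.constraints:
            assert float(row @ params.u_str) == pytest.approx(0.0, abs=1e-10)


class TestTwoPeriod:
    def test_exchangeable_periods_have_similar_prevalence(self, lattice):
        graph, zones, structure = lattice
        params = default_true_params(structure, "pre", seed=14)
        data = make_two_period(
            graph, zones, params, params, 5, 40, seed=14,
            target_prevalence={"pre": 0.15, "post": 0.15},
        )
        p1 = data["pre"]["fgm_status"].mean()
        p2 = data["post"]["fgm_status"].mean()
        se = np.sqrt(2 * 0.15 * 0.85 / len(data["pre"]))
        assert abs(p1 - p2) < 5 * se

    def test_lower_post_target_lowers_prevalence(self, lattice):
        graph, zones, structure = lattice
        params = default_true_params(structure, "pre", seed=15)
        data = make_two_period(
            graph, zones, params, params, 5, 40, seed=15,
            target_prevalence={"pre": 0.20, "post": 0.10},
        )
        assert data["post"]["fgm_status"].mean() < data["pre"]["fgm_status"].mean()

    def test_periods_are_independent_draws(self, lattice):
        graph, zones, structure = lattice
        params = default_true_params(structure, "pre", seed=16)
        data = make_two_period(graph, zones, params, params, 2, 20, seed=16)
        assert not data["pre"]["fgm_status"].equals(data["post"]["fgm_status"])
        assert (data["pre"]["period"] == "pre").all()
        assert (data["post"]["period"] == "post").all()

    def test_mismatched_geography_rejected(self, lattice):
        graph, zones, structure = lattice
        params = default_true_params(structure, "pre", seed=17)
        bad = TrueParams(beta0=0.0, u_str=np.zeros(5), v_unstr=np.zeros(5))
        with pytest.raises(ValueError, match="geography"):
            make_two_period(graph, zones, params, bad, 2, 10, seed=17)


class TestPersistence:
    def test_csv_round_trip_is_byte_identical(self, lattice, tmp_path):
        graph, zones, structure = lattice
        params = default_true_params(structure, "pre", seed=18)
        df = simulate_outcomes(
            generate_population(graph, zones, 3, 20, seed=18), params, structure, seed=18
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_records(df, p1)
        back = read_records(p1)
        write_records(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_params_sidecar_round_trip(self, lattice, tmp_path):
        _, _, structure = lattice
        params = default_true_params(structure, "post", seed=19)
        path = tmp_path / "params.json"
        write_params(params, path)
        back = read_params(path)
        assert back.beta0 == params.beta0
        assert np.allclose(back.u_str, params.u_str)
        assert back.beta["mother_fgm"]["cut"] == pytest.approx(np.log(10.992))
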