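"""Canonical synthetic validation scenarios.

Shared by the test suite and the acceptance script so the study conditions
are defined once: a 3x4 state lattice with 5 clusters of 50 girls per
state, generating coefficients from the published odds-ratio table
(mother-cut OR 8.145, support-continuation OR 16.4), intercept calibrated
to the observed national prevalence, and a Besag field of configurable
strength.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import ModelSpec
from .geo import AdjacencyGraph, ICARStructure, icar_precision
from .synthetic import (
    TrueParams,
    calibrate_intercept,
    default_true_params,
    generate_geography,
    generate_population,
    simulate_outcomes,
)

__all__ = [
    "lattice_study",
    "recovery_dataset",
    "strong_field_dataset",
    "two_group_dataset",
    "separable_dataset",
]


def lattice_study(
    n_states: int = 12, grid_shape: tuple[int, int] = (3, 4), seed: int = 1
) -> tuple[AdjacencyGraph, dict[str, str], ICARStructure]:
    """The standard 3x4 lattice geography used by the validation runs."""
    graph, zones = generate_geography(n_states, grid_shape, seed=seed)
    return graph, zones, icar_precision(graph)


def recovery_dataset(
    seed: int,
    n_clusters_per_state: int = 5,
    n_girls_per_cluster: int = 50,
    tau_str: float = 2.0,
    target_prevalence: float = 0.192,
) -> tuple[pd.DataFrame, TrueParams, AdjacencyGraph, ICARStructure]:
    """One simulate-replicate under the individual-covariate true model.

    Generating coefficients are the 2018 published ORs (mother-cut 8.145,
    support-yes 16.436, ...); smooths restricted to the two age terms so
    an individual-covariate m2 fit is the true model; intercept calibrated
    to the survey's observed national prevalence (19.2%).
    """
    graph, zones, structure = lattice_study()
    params = default_true_params(
        structure, "pre", seed=seed, tau_str=tau_str, smooths=("girl_age", "mother_age")
    )
    pop = generate_population(
        graph, zones, n_clusters_per_state, n_girls_per_cluster, seed=seed
    )
    params = calibrate_intercept(pop, params, target_prevalence, structure)
    records = simulate_outcomes(pop, params, structure, seed=seed)
    return records, params, graph, structure


def strong_field_dataset(
    seed: int,
    n_clusters_per_state: int = 5,
    n_girls_per_cluster: int = 50,
    tau_str: float = 0.2,
) -> tuple[pd.DataFrame, TrueParams, AdjacencyGraph, ICARStructure]:
    """Replicate with a strong Besag field (tau_str = 0.2).

    The between-state spread this induces (state prevalences ranging over
    tens of points) mirrors the real surveys, where observed state
    prevalence spans roughly 0-63%.
    """
    return recovery_dataset(
        seed,
        n_clusters_per_state=n_clusters_per_state,
        n_girls_per_cluster=n_girls_per_cluster,
        tau_str=tau_str,
    )


def _reference_frame(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cluster = [f"c{i // 25:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "girl_id": [f"g{i}" for i in range(n)],
            "cluster_id": cluster,
            "state_id": "s0",
            "zone": "north_central",
            "residence": "urban",
            "girl_age": rng.integers(0, 15, size=n),
            "fgm_status": 0,
            "age_at_cutting": np.nan,
            "mother_age": rng.integers(15, 50, size=n),
            "mother_education": "none",
            "mother_marital": "current",
            "ethnicity": "fulani",
            "religion": "christian",
            "mother_support": "no",
            "mother_fgm": "uncut",
            "wealth": "poorest",
            "weight": 1.0,
            "period": "pre",
        }
    )


def two_group_dataset(
    n: int = 4000,
    seed: int = 0,
    base_p: float = 0.2,
    odds_ratio: float = 8.0,
    share_exposed: float = 0.3,
) -> tuple[pd.DataFrame, ModelSpec, float]:
    """Two-group scenario with an analytically known Bayes accuracy.

    Only the mother-FGM covariate carries signal: p = base_p for uncut
    mothers and expit(logit(base_p) + log(OR)) for cut mothers.  The Bayes
    classifier predicts the majority class within each group, so its
    accuracy is exactly computable from (base_p, OR, exposure share).
    Returns the records, the matching intercept+mother_fgm model spec, and
    the Bayes accuracy.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 31)))
    df = _reference_frame(n, rng)
    df["mother_fgm"] = np.where(rng.random(n) < share_exposed, "cut", "uncut")
    b0 = float(np.log(base_p / (1 - base_p)))
    params = TrueParams(beta0=b0, beta={"mother_fgm": {"cut": float(np.log(odds_ratio))}})
    df = simulate_outcomes(df, params, seed=seed)
    p1 = float(expit(b0 + np.log(odds_ratio)))
    bayes_acc = (1 - share_exposed) * max(base_p, 1 - base_p) + share_exposed * max(
        p1, 1 - p1
    )
    spec = ModelSpec("m1", "individual", smooth_covariates=(), include_weight_covariate=False)
    return df, spec, bayes_acc


def separable_dataset(n: int = 1000, seed: int = 0) -> tuple[pd.DataFrame, ModelSpec]:
    """Perfectly separable fixture: cut mothers' daughters are always cut."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 37)))
    df = _reference_frame(n, rng)
    df["mother_fgm"] = np.where(rng.random(n) < 0.5, "cut", "uncut")
    params = TrueParams(beta0=-60.0, beta={"mother_fgm": {"cut": 120.0}})
    df = simulate_outcomes(df, params, seed=seed)
    spec = ModelSpec("m1", "individual", smooth_covariates=(), include_weight_covariate=False)
    return df, spec
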