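"""Synthetic two-period cluster-survey generator.

Emulates DHS/MICS-style girl-level data: a lattice of states with queen
contiguity (stand-in geography), two-stage cluster sampling (clusters of
girls within states, inverse-inclusion-probability weights), the
individual- and community-level covariate mix of the risk model, and
binary cut/uncut outcomes drawn from the full hierarchical logistic model
(fixed effects + tabulated smooth functions + structured/unstructured
state effects + weight covariate).

Randomness is split hierarchically: every cluster draws from its own
``SeedSequence((seed, stage, state, cluster))`` stream, so enlarging the
design does not perturb earlier draws and identical seeds reproduce
byte-identical CSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import SMOOTH_GRIDS, smooth_bin_index
from .geo import AdjacencyGraph, ICARStructure, adjacency_from_polygons, icar_precision
from .schema import CATEGORIES

__all__ = [
    "TrueParams",
    "CovariateConfig",
    "generate_geography",
    "generate_population",
    "calibrate_intercept",
    "simulate_outcomes",
    "make_two_period",
    "default_true_params",
    "draw_spatial_effects",
    "write_params",
    "read_params",
]

_P_CLIP = 1e-12


@dataclass
class TrueParams:
    """Generating parameters of the hierarchical logistic model.

    ``beta`` maps covariate -> {level: log-odds}; reference levels are
    implicitly 0.  ``smooth_fns`` holds each smooth's true values tabulated
    on its model grid.  ``u_str`` / ``v_unstr`` are per-state effects in the
    adjacency graph's node order; ``u_str`` sums to zero per component.
    """

    beta0: float
    beta: dict[str, dict[str, float]] = field(default_factory=dict)
    beta_w: float = 0.0
    smooth_fns: dict[str, np.ndarray] = field(default_factory=dict)
    tau_str: float = 2.0
    tau_unstr: float = 25.0
    u_str: np.ndarray = field(default_factory=lambda: np.zeros(0))
    v_unstr: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def validate_levels(self) -> None:
        for cov, levels in self.beta.items():
            declared = CATEGORIES.get(cov)
            if declared is None:
                raise ValueError(f"unknown covariate {cov!r} in beta")
            bad = set(levels) - set(declared)
            if bad:
                raise ValueError(f"unknown level(s) {sorted(bad)} for covariate {cov!r}")


@dataclass
class CovariateConfig:
    """Mixture probabilities of the covariate generator.

    Each categorical distribution must sum to 1.  ``religion_by_region``
    keys are 'north'/'south' (zones starting 'north_' use the former).
    ``dominant_ethnicity_share`` implements the spatial clustering of
    ethnic groups: each state has one dominant group holding that share.
    ``weight_dispersion`` is the log-normal sd of notional cluster
    populations; 0 gives a self-weighting design (all weights 1).
    """

    p_urban: float = 0.35
    education: dict[str, float] = field(
        default_factory=lambda: {"none": 0.35, "primary": 0.20, "secondary": 0.30, "higher": 0.15}
    )
    marital: dict[str, float] = field(
        default_factory=lambda: {"current": 0.85, "former": 0.10, "never": 0.05}
    )
    support: dict[str, float] = field(
        default_factory=lambda: {"no": 0.70, "yes": 0.20, "dk": 0.10}
    )
    mother_fgm: dict[str, float] = field(
        default_factory=lambda: {"uncut": 0.70, "cut": 0.30}
    )
    wealth: dict[str, float] = field(
        default_factory=lambda: {q: 0.2 for q in CATEGORIES["wealth"]}
    )
    religion_by_region: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "north": {"christian": 0.25, "islam": 0.70, "traditional": 0.03, "other": 0.02},
            "south": {"christian": 0.75, "islam": 0.18, "traditional": 0.05, "other": 0.02},
        }
    )
    dominant_ethnicity_share: float = 0.7
    weight_dispersion: float = 0.3
    early_cutting_mass: float = 0.7  # share of cut girls cut at age <= 1

    def validate(self) -> None:
        for name, dist in [
            ("education", self.education),
            ("marital", self.marital),
            ("support", self.support),
            ("mother_fgm", self.mother_fgm),
            ("wealth", self.wealth),
            *[(f"religion[{k}]", v) for k, v in self.religion_by_region.items()],
        ]:
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities do not sum to 1")


def generate_geography(
    n_states: int, grid_shape: tuple[int, int] | None = None, seed: int = 0
) -> tuple[AdjacencyGraph, dict[str, str]]:
    """Lay states out as a rectangular lattice with queen contiguity.

    Returns the adjacency graph and a state -> zone assignment; the six
    zones are contiguous blocks of grid columns.
    """
    if n_states < 4:
        raise ValueError("need at least 4 states")
    if grid_shape is None:
        rows = int(np.floor(np.sqrt(n_states)))
        cols = int(np.ceil(n_states / rows))
        grid_shape = (rows, cols)
    rows, cols = grid_shape
    if rows * cols < n_states:
        raise ValueError(f"{n_states} states do not fit grid {grid_shape}")
    from shapely.geometry import box

    polys = {}
    positions = {}
    k = 0
    for c in range(cols):
        for r in range(rows):
            if k >= n_states:
                break
            lab = f"S{k:02d}"
            polys[lab] = box(c, r, c + 1, r + 1)
            positions[lab] = (r, c)
            k += 1
    graph = adjacency_from_polygons(polys, contiguity="queen")
    zone_names = CATEGORIES["zone"]
    n_zones = min(len(zone_names), n_states)
    # contiguous blocks in column-major order
    order = sorted(polys, key=lambda s: (positions[s][1], positions[s][0]))
    zones = {}
    block = int(np.ceil(n_states / n_zones))
    for i, lab in enumerate(order):
        zones[lab] = zone_names[min(i // block, n_zones - 1)]
    return graph, zones


def draw_spatial_effects(
    structure: ICARStructure, tau_str: float, tau_unstr: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a Besag field (centred per component) and iid state effects."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    Q = structure.Q.toarray()
    lam, V = np.linalg.eigh(Q)
    u = np.zeros(structure.n)
    pos = lam > 1e-8
    z = rng.standard_normal(pos.sum())
    u = V[:, pos] @ (z / np.sqrt(tau_str * lam[pos]))
    for row in structure.constraints:  # exact re-centring per component
        m = row > 0
        u[m] -= u[m].mean()
    v = rng.standard_normal(structure.n) / np.sqrt(tau_unstr)
    return u, v


def _sample_cat(rng: np.random.Generator, dist: dict[str, float], size: int) -> np.ndarray:
    levels = list(dist)
    p = np.array([dist[l] for l in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=size, p=p)


_MOTHER_AGES = np.arange(15, 50)
_MOTHER_AGE_P = 1.0 / (1.0 + np.abs(_MOTHER_AGES - 30) / 8.0)
_MOTHER_AGE_P = _MOTHER_AGE_P / _MOTHER_AGE_P.sum()


def generate_population(
    graph: AdjacencyGraph,
    zones: dict[str, str],
    n_clusters_per_state: int,
    n_girls_per_cluster: int,
    config: CovariateConfig | None = None,
    seed: int = 0,
    period: str = "pre",
) -> pd.DataFrame:
    """Generate girl records (outcomes unset) under two-stage sampling.

    Clusters are nested in states; each state has a dominant ethnic group;
    religion mixtures depend on the zone's region.  Weights are inverse
    inclusion probabilities of the two-stage design (state pool of notional
    clusters, log-normal cluster sizes), normalised to mean 1.
    """
    if n_clusters_per_state <= 0 or n_girls_per_cluster <= 0:
        raise ValueError("cluster and girl counts must be positive")
    config = config or CovariateConfig()
    config.validate()

    state_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    eth_levels = CATEGORIES["ethnicity"]
    dominant = {s: state_rng.choice(eth_levels) for s in graph.node_ids}

    n_pool = max(50, 2 * n_clusters_per_state)  # notional clusters per state
    p1 = n_clusters_per_state / n_pool

    rows = []
    for si, state in enumerate(graph.node_ids):
        zone = zones[state]
        region = "north" if zone.startswith("north") else "south"
        rel_dist = config.religion_by_region[region]
        dom = dominant[state]
        eth_dist = {
            e: (
                config.dominant_ethnicity_share
                if e == dom
                else (1 - config.dominant_ethnicity_share) / (len(eth_levels) - 1)
            )
            for e in eth_levels
        }
        for ci in range(n_clusters_per_state):
            rng = np.random.default_rng(np.random.SeedSequence((seed, 2, si, ci)))
            cluster_id = f"{state}_C{ci:03d}"
            residence = "urban" if rng.random() < config.p_urban else "rural"
            if config.weight_dispersion > 0:
                pop = 200.0 * rng.lognormal(0.0, config.weight_dispersion)
            else:
                pop = 200.0
            p2 = min(1.0, n_girls_per_cluster / pop)
            w = 1.0 / (p1 * p2)
            m = n_girls_per_cluster
            rows.append(
                pd.DataFrame(
                    {
                        "girl_id": [f"{cluster_id}_G{g:03d}" for g in range(m)],
                        "cluster_id": cluster_id,
                        "state_id": state,
                        "zone": zone,
                        "residence": residence,
                        "girl_age": rng.integers(0, 15, size=m),
                        "fgm_status": 0,
                        "age_at_cutting": np.nan,
                        "mother_age": rng.choice(_MOTHER_AGES, size=m, p=_MOTHER_AGE_P),
                        "mother_education": _sample_cat(rng, config.education, m),
                        "mother_marital": _sample_cat(rng, config.marital, m),
                        "ethnicity": _sample_cat(rng, eth_dist, m),
                        "religion": _sample_cat(rng, rel_dist, m),
                        "mother_support": _sample_cat(rng, config.support, m),
                        "mother_fgm": _sample_cat(rng, config.mother_fgm, m),
                        "wealth": _sample_cat(rng, config.wealth, m),
                        "weight": w,
                        "period": period,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    df["weight"] = df["weight"] / df["weight"].mean()
    return df


def true_linear_predictor(
    records: pd.DataFrame, params: TrueParams, structure: ICARStructure | None = None
) -> np.ndarray:
    """Assemble the generating linear predictor for each record."""
    params.validate_levels()
    needed = {"pct_cut", "pct_support"} & set(params.smooth_fns)
    if needed - set(records.columns):
        # community proportions derive from the mothers' covariates, which
        # exist before outcomes are drawn
        from .community import attach_community

        records = attach_community(records)
    eta = np.full(len(records), params.beta0, dtype=float)
    for cov, levels in params.beta.items():
        col = records[cov].astype(str)
        unknown = set(col) - set(CATEGORIES[cov])
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} in column {cov!r}")
        eta += col.map(lambda l, lv=levels: lv.get(l, 0.0)).to_numpy(dtype=float)
    for name, fvals in params.smooth_fns.items():
        fvals = np.asarray(fvals, dtype=float)
        if len(fvals) != len(SMOOTH_GRIDS[name]):
            raise ValueError(f"smooth {name!r} not tabulated on its full grid")
        vals = records[name].to_numpy(dtype=float)
        if name in ("pct_cut", "pct_support"):
            vals = vals / 100.0
        eta += fvals[smooth_bin_index(name, vals)]
    if len(params.u_str) or len(params.v_unstr):
        if structure is None:
            raise ValueError("spatial effects present but no ICAR structure given")
        pos = {s: i for i, s in enumerate(structure.graph.node_ids)}
        sidx = records["state_id"].astype(str).map(pos).to_numpy()
        if len(params.u_str):
            eta += np.asarray(params.u_str)[sidx]
        if len(params.v_unstr):
            eta += np.asarray(params.v_unstr)[sidx]
    eta += params.beta_w * records["weight"].to_numpy(dtype=float)
    return eta


def calibrate_intercept(
    records: pd.DataFrame,
    params: TrueParams,
    target_prevalence: float,
    structure: ICARStructure | None = None,
) -> TrueParams:
    """Shift the intercept so the weighted population prevalence hits a target.

    The published odds ratios and the observed national prevalence are both
    stated survey facts; because the synthetic covariate mixture differs
    from the real population, the intercept is the free term that
    reconciles them.  Solves for the constant ``c`` with
    ``sum_i w_i expit(eta_i + c) / sum_i w_i = target`` (deterministic).
    """
    from scipy.optimize import brentq

    if not 0 < target_prevalence < 1:
        raise ValueError("target_prevalence must be in (0, 1)")
    eta = true_linear_predictor(records, params, structure)
    w = records["weight"].to_numpy(dtype=float)

    def gap(c: float) -> float:
        return float((w * expit(eta + c)).sum() / w.sum()) - target_prevalence

    c = brentq(gap, -20.0, 20.0, xtol=1e-10)
    out = TrueParams(
        beta0=params.beta0 + c,
        beta={k: dict(v) for k, v in params.beta.items()},
        beta_w=params.beta_w,
        smooth_fns={k: np.asarray(v).copy() for k, v in params.smooth_fns.items()},
        tau_str=params.tau_str,
        tau_unstr=params.tau_unstr,
        u_str=np.asarray(params.u_str).copy(),
        v_unstr=np.asarray(params.v_unstr).copy(),
    )
    return out


def simulate_outcomes(
    records: pd.DataFrame,
    params: TrueParams,
    structure: ICARStructure | None = None,
    seed: int = 0,
    early_cutting_mass: float = 0.7,
) -> pd.DataFrame:
    """Draw cut/uncut outcomes (and ages at cutting) from the true model."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    df = records.copy()
    eta = true_linear_predictor(df, params, structure)
    p = np.clip(expit(eta), _P_CLIP, 1 - _P_CLIP)
    y = (rng.random(len(df)) < p).astype(int)
    df["fgm_status"] = y
    ages = df["girl_age"].to_numpy(dtype=int)
    aac = np.full(len(df), np.nan)
    cut = np.flatnonzero(y == 1)
    for i in cut:
        if rng.random() < early_cutting_mass or ages[i] < 2:
            aac[i] = min(int(rng.integers(0, 2)), ages[i])
        else:
            aac[i] = int(rng.integers(2, ages[i] + 1))
    df["age_at_cutting"] = aac
    return df


def default_true_params(
    structure: ICARStructure,
    period: str = "pre",
    seed: int = 0,
    tau_str: float = 2.0,
    tau_unstr: float = 25.0,
    include_unstructured: bool = False,
    smooths: tuple[str, ...] = ("girl_age", "mother_age", "pct_cut", "pct_support"),
) -> TrueParams:
    """Study-condition generating parameters.

    Fixed-effect log-odds are the logs of the published posterior odds
    ratios of the fitted model for the corresponding survey period (pre =
    2018 DHS, post = 2021 MICS), including the mother-cut effect (OR 8.145
    pre / 10.992 post) and the support-continuation effect rising 16.4 ->
    26.7.  ORs printed as 0.000 (truncated) are represented by 0.01.
    Smooth functions are centred mild trends: risk rising with girl age, a
    shallow U in mother age, rising community %-cut and %-support effects.
    """
    if period not in ("pre", "post"):
        raise ValueError("period must be 'pre' or 'post'")
    if period == "pre":
        beta0 = float(np.log(0.022))
        beta = {
            "mother_education": {"primary": 1.033, "secondary": 0.971, "higher": 0.708},
            "mother_marital": {"former": 0.764, "never": 1.207},
            "mother_support": {"yes": 16.436, "dk": 2.311},
            "mother_fgm": {"cut": 8.145},
            "wealth": {"poorer": 0.937, "middle": 0.952, "richer": 0.804, "richest": 0.606},
            "ethnicity": {
                "hausa": 0.930,
                "ibibio": 0.851,
                "igbo": 1.043,
                "ijaw": 0.01,
                "kanuri": 0.614,
                "tiv": 0.086,
                "yoruba": 0.809,
                "other": 0.552,
            },
            "religion": {"islam": 1.344, "traditional": 0.163, "other": 0.01},
        }
        beta_w = float(np.log(1.018))
    else:
        beta0 = float(np.log(0.0076))
        beta = {
            "mother_education": {"primary": 1.1743, "secondary": 1.1939, "higher": 0.8362},
            "mother_marital": {"former": 0.8262, "never": 2.099},
            "mother_support": {"yes": 26.728, "dk": 3.620},
            "mother_fgm": {"cut": 10.992},
            "wealth": {"poorer": 1.006, "middle": 1.060, "richer": 1.212, "richest": 0.800},
            "ethnicity": {
                "hausa": 0.478,
                "ibibio": 0.246,
                "igbo": 0.241,
                "ijaw": 0.016,
                "kanuri": 0.242,
                "tiv": 0.140,
                "yoruba": 0.654,
                "other": 0.147,
            },
            "religion": {"islam": 1.998, "traditional": 2.779, "other": 0.01},
        }
        beta_w = float(np.log(0.8901))
    beta_log = {cov: {l: float(np.log(v)) for l, v in lv.items()} for cov, lv in beta.items()}

    def centred(vals: np.ndarray) -> np.ndarray:
        return vals - vals.mean()

    ga = SMOOTH_GRIDS["girl_age"]
    ma = SMOOTH_GRIDS["mother_age"]
    pr = SMOOTH_GRIDS["pct_cut"]
    smooth_fns = {
        "girl_age": centred(0.1 * (ga - ga.mean())),
        "mother_age": centred(0.5 * ((ma - 32.0) / 17.0) ** 2),
        "pct_cut": centred(1.0 * pr),
        "pct_support": centred(0.8 * pr),
    }
    smooth_fns = {k: v for k, v in smooth_fns.items() if k in smooths}
    u, v = draw_spatial_effects(structure, tau_str, tau_unstr, seed=seed)
    return TrueParams(
        beta0=beta0,
        beta=beta_log,
        beta_w=beta_w,
        smooth_fns=smooth_fns,
        tau_str=tau_str,
        tau_unstr=tau_unstr,
        u_str=u,
        v_unstr=v if include_unstructured else np.zeros(structure.n),
    )


def make_two_period(
    graph: AdjacencyGraph,
    zones: dict[str, str],
    pre_params: TrueParams,
    post_params: TrueParams,
    n_clusters_per_state: int = 5,
    n_girls_per_cluster: int = 50,
    config: CovariateConfig | None = None,
    seed: int = 0,
    target_prevalence: dict[str, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate two independent surveys (pre/post) on a shared geography.

    ``target_prevalence`` (default: the observed national prevalences of
    the two surveys, 19.2% pre and 14.1% post) calibrates each period's
    intercept via :func:`calibrate_intercept`; pass ``{}`` to disable.
    """
    if target_prevalence is None:
        target_prevalence = {"pre": 0.192, "post": 0.141}
    n = graph.n_nodes
    for name, p in (("pre", pre_params), ("post", post_params)):
        if len(p.u_str) not in (0, n) or len(p.v_unstr) not in (0, n):
            raise ValueError(f"{name} params reference a different geography ({n} states)")
    structure = icar_precision(graph)
    out = {}
    for off, (name, params) in enumerate([("pre", pre_params), ("post", post_params)]):
        pop = generate_population(
            graph,
            zones,
            n_clusters_per_state,
            n_girls_per_cluster,
            config=config,
            seed=seed * 2 + off,
            period=name,
        )
        if name in target_prevalence:
            params = calibrate_intercept(pop, params, target_prevalence[name], structure)
        out[name] = simulate_outcomes(
            pop,
            params,
            structure,
            seed=seed * 2 + off,
            early_cutting_mass=(config or CovariateConfig()).early_cutting_mass,
        )
    return out


def write_params(params: TrueParams, path: str | Path) -> None:
    """Persist generating parameters as a JSON sidecar for recovery tests."""
    obj = asdict(params)
    obj["smooth_fns"] = {k: np.asarray(v).tolist() for k, v in params.smooth_fns.items()}
    obj["u_str"] = np.asarray(params.u_str).tolist()
    obj["v_unstr"] = np.asarray(params.v_unstr).tolist()
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_params(path: str | Path) -> TrueParams:
    obj = json.loads(Path(path).read_text())
    obj["smooth_fns"] = {k: np.asarray(v) for k, v in obj["smooth_fns"].items()}
    obj["u_str"] = np.asarray(obj["u_str"])
    obj["v_unstr"] = np.asarray(obj["v_unstr"])
    return TrueParams(**obj)
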