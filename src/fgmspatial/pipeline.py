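"""Reproducible end-to-end pipeline: simulate/read -> fit -> select -> report.

A run is driven by a :class:`RunConfig` (YAML or JSON).  Every stage that
consumes randomness derives its stream from the single mandatory ``seed``;
outputs are stamped with a hash of the canonical config so byte-identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import community as comm
from .design import ModelSpec
from .evaluate import (
    agreement,
    cross_validate,
    pooled_cv_summary,
    prevalence_change,
    select_model,
)
from .geo import adjacency_from_edgelist, adjacency_from_geojson, icar_precision
from .model import BayesSpatialLogit
from .schema import read_records, write_records
from .synthetic import default_true_params, generate_geography, make_two_period, write_params

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


_ALLOWED = {
    "seed",
    "out_dir",
    "records",
    "geography",
    "simulate",
    "model",
    "mcmc",
    "cv",
}
_SIM_KEYS = {"n_states", "grid_shape", "n_clusters_per_state", "n_girls_per_cluster"}
_MODEL_KEYS = {"complexities", "covariate_set", "include_weight_covariate"}
_MCMC_KEYS = {"iterations", "burn_in", "thin"}
_CV_KEYS = {"enabled", "k", "repeats", "iterations", "burn_in", "threshold"}


@dataclass
class RunConfig:
    """Validated run configuration.

    ``records`` maps period -> CSV path (for real/pre-generated data);
    ``simulate`` holds generator sizes instead.  ``geography`` points at a
    GeoJSON file, an edge list, or is omitted when simulating (the
    generated lattice is used).
    """

    seed: int
    out_dir: str = "out"
    records: dict[str, str] = field(default_factory=dict)
    geography: dict[str, str] = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=lambda: {"iterations": 4000, "burn_in": 1000, "thin": 1})
    cv: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        unknown = set(obj) - _ALLOWED
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in obj or obj["seed"] is None:
            raise ConfigError("config must set an explicit seed")
        for sect, allowed in (
            ("simulate", _SIM_KEYS),
            ("model", _MODEL_KEYS),
            ("mcmc", _MCMC_KEYS),
            ("cv", _CV_KEYS),
        ):
            bad = set(obj.get(sect, {})) - allowed
            if bad:
                raise ConfigError(f"unknown keys in {sect!r}: {sorted(bad)}")
        cfg = cls(
            seed=int(obj["seed"]),
            out_dir=str(obj.get("out_dir", "out")),
            records=dict(obj.get("records", {})),
            geography=dict(obj.get("geography", {})),
            simulate=dict(obj.get("simulate", {})),
            model=dict(obj.get("model", {})),
            mcmc={**{"iterations": 4000, "burn_in": 1000, "thin": 1}, **obj.get("mcmc", {})},
            cv=dict(obj.get("cv", {})),
        )
        complexities = cfg.model.get("complexities", ["m1", "m2", "m3"])
        needs_graph = any(c in ("m2", "m3") for c in complexities)
        if needs_graph and not cfg.simulate and not cfg.geography:
            raise ConfigError(
                "spatial models requested but no geography (polygons/edge list) given"
            )
        if not cfg.simulate and not cfg.records:
            raise ConfigError("config must either simulate data or point at records CSVs")
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "records": self.records,
            "geography": self.geography,
            "simulate": self.simulate,
            "model": self.model,
            "mcmc": self.mcmc,
            "cv": self.cv,
        }

    def hash(self) -> str:
        obj = self.to_dict()
        obj.pop("out_dir")  # output location does not change the run
        blob = json.dumps(obj, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    obj = yaml.safe_load(text)
    if not isinstance(obj, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return RunConfig.from_dict(obj)


def _get_geography(cfg: RunConfig):
    if cfg.simulate:
        n_states = int(cfg.simulate.get("n_states", 12))
        shape = cfg.simulate.get("grid_shape")
        shape = tuple(shape) if shape else None
        return generate_geography(n_states, shape, seed=cfg.seed)
    geo = cfg.geography
    if "geojson" in geo:
        graph = adjacency_from_geojson(geo["geojson"], geo.get("id_property", "id"))
    elif "edgelist" in geo:
        graph = adjacency_from_edgelist(geo["edgelist"])
    else:
        return None, None
    return graph, None


def _get_datasets(cfg: RunConfig, graph, zones, out: Path) -> dict[str, pd.DataFrame]:
    if cfg.simulate:
        structure = icar_precision(graph)
        pre_p = default_true_params(structure, "pre", seed=cfg.seed)
        post_p = default_true_params(structure, "post", seed=cfg.seed)
        data = make_two_period(
            graph,
            zones,
            pre_p,
            post_p,
            n_clusters_per_state=int(cfg.simulate.get("n_clusters_per_state", 5)),
            n_girls_per_cluster=int(cfg.simulate.get("n_girls_per_cluster", 50)),
            seed=cfg.seed,
        )
        for period, df in data.items():
            write_records(df, out / f"records_{period}.csv")
        write_params(pre_p, out / "true_params_pre.json")
        write_params(post_p, out / "true_params_post.json")
        return data
    return {period: read_records(path) for period, path in cfg.records.items()}


def run_pipeline(cfg: RunConfig, stages: str = "report") -> dict:
    """Run the pipeline up to ``stages``: simulate | fit | evaluate | cv | report.

    Returns (and writes) the run-summary dict.  All emitted CSVs re-parse
    under the package's own readers.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.hash(), "seed": cfg.seed, "stages": stages}

    graph, zones = _get_geography(cfg)
    if graph is not None:
        (out / "adjacency.json").write_text(graph.to_json())
        summary["n_states"] = graph.n_nodes
        summary["n_edges"] = graph.n_edges
    logger.info("geography: %s states", None if graph is None else graph.n_nodes)

    data = _get_datasets(cfg, graph, zones, out)
    summary["records"] = {k: len(v) for k, v in data.items()}
    logger.info("datasets: %s", summary["records"])
    if stages == "simulate":
        _write_summary(summary, out)
        return summary

    covariate_set = cfg.model.get("covariate_set", "individual")
    complexities = cfg.model.get("complexities", ["m1", "m2", "m3"])
    structure = icar_precision(graph) if graph is not None else None
    mcmc = cfg.mcmc

    results_by_period: dict[str, dict] = {}
    dic_table = []
    for pi, (period, df) in enumerate(sorted(data.items())):
        dfc = comm.attach_community(df) if covariate_set != "individual" else df
        fits = {}
        for ci, cx in enumerate(complexities):
            spec = ModelSpec(
                cx,
                covariate_set,
                include_weight_covariate=cfg.model.get("include_weight_covariate", True),
            )
            model = BayesSpatialLogit.from_dataframe(
                dfc, spec, graph=graph if spec.has_structured else None
            )
            res = model.fit(seed=cfg.seed * 100 + pi * 10 + ci, **mcmc)
            fits[cx] = res
            d = res.dic()
            dic_table.append({"period": period, "model": cx, **d})
            logger.info("%s %s: DIC %.1f", period, cx, d["DIC"])
        chosen = select_model(
            {cx: r.dic()["DIC"] for cx, r in fits.items()}
        )
        results_by_period[period] = {"fits": fits, "chosen": chosen, "records": dfc}
        fits[chosen].save(out / f"draws_{period}_{chosen}")
    pd.DataFrame(dic_table).to_csv(out / "dic.csv", index=False)
    summary["dic"] = {
        f"{r['period']}:{r['model']}": round(r["DIC"], 3) for r in dic_table
    }
    summary["selected_model"] = {
        p: info["chosen"] for p, info in results_by_period.items()
    }
    if stages == "fit":
        _write_summary(summary, out)
        return summary

    prev_tables = {}
    for period, info in sorted(results_by_period.items()):
        res = info["fits"][info["chosen"]]
        prev = res.state_prevalence()
        prev.to_csv(out / f"prevalence_{period}.csv", index=False)
        prev_tables[period] = prev
        por = res.odds_ratios()
        por.to_csv(out / f"por_{period}.csv", index=False)
        observed = comm.weighted_prevalence(info["records"], by=["state_id"])
        agr = agreement(observed, prev)
        summary[f"agreement_{period}"] = {k: round(v, 4) for k, v in agr.items()}
        nat = prev.loc[prev["state_id"] == "(national)", "mean_pct"].iloc[0]
        summary[f"national_prevalence_{period}_pct"] = round(float(nat), 3)
    if len(prev_tables) == 2 and {"pre", "post"} <= set(prev_tables):
        change = prevalence_change(prev_tables["pre"], prev_tables["post"])
        change.to_csv(out / "prevalence_change.csv", index=False)
    if stages == "evaluate":
        _write_summary(summary, out)
        return summary

    if cfg.cv.get("enabled", stages in ("cv", "report")):
        cv_rows = []
        for period, info in sorted(results_by_period.items()):
            spec = info["fits"][info["chosen"]].model.spec
            rep = cross_validate(
                info["records"],
                spec,
                structure=structure if spec.has_structured else None,
                k=int(cfg.cv.get("k", 5)),
                repeats=int(cfg.cv.get("repeats", 5)),
                threshold=float(cfg.cv.get("threshold", 0.5)),
                mcmc={
                    "iterations": int(cfg.cv.get("iterations", 800)),
                    "burn_in": int(cfg.cv.get("burn_in", 300)),
                    "thin": 1,
                },
                seed=cfg.seed,
            )
            rep.insert(0, "period", period)
            cv_rows.append(rep)
            summary[f"cv_{period}"] = {
                k: round(v, 4) for k, v in pooled_cv_summary(rep).items()
            }
        pd.concat(cv_rows, ignore_index=True).to_csv(out / "cv.csv", index=False)

    _write_summary(summary, out)
    return summary


def _write_summary(summary: dict, out: Path) -> None:
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
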