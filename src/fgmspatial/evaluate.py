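"""Model selection, agreement metrics, cross-validation and change tables.

Functional layer over the model results: DIC-based selection with the
"difference below 2 favours the simpler model" rule, state-level agreement
(R² / RMSE / MAE) between observed weighted prevalence and posterior
predictions, repeated stratified cluster-blocked cross-validation, and
two-period prevalence-change summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .design import ModelSpec
from .geo import ICARStructure
from .model import BayesSpatialLogit, BayesSpatialLogitResults

logger = logging.getLogger(__name__)

__all__ = [
    "dic",
    "select_model",
    "agreement",
    "classification_scores",
    "cross_validate",
    "posterior_odds_ratios",
    "state_prevalence",
    "prevalence_change",
]

_COMPLEXITY_ORDER = {"m1": 0, "m2": 1, "m3": 2}


def dic(results: BayesSpatialLogitResults) -> dict[str, float]:
    """DIC report for one fit: Dbar, pD = Dbar - D(theta_bar), DIC."""
    if len(results.deviance_draws) < 100:
        raise ValueError("need at least 100 post-burn-in draws for DIC")
    return results.dic()


def select_model(dic_by_model: dict[str, float], threshold: float = 2.0) -> str:
    """Pick the best model by DIC, preferring simpler models within threshold.

    Models are ordered by complexity (m1 < m2 < m3); a more complex model
    replaces the current choice only when it improves DIC by more than
    ``threshold``.  Applied transitively from the simplest upward.
    """
    if not dic_by_model:
        raise ValueError("no models to select from")
    items = sorted(dic_by_model.items(), key=lambda kv: _COMPLEXITY_ORDER[kv[0]])
    best_name, best_dic = items[0]
    for name, val in items[1:]:
        if best_dic - val > threshold:
            best_name, best_dic = name, val
    return best_name


def state_prevalence(results: BayesSpatialLogitResults, max_draws: int = 300) -> pd.DataFrame:
    """Posterior per-state (and national) weighted prevalence summaries."""
    return results.state_prevalence(max_draws=max_draws)


def posterior_odds_ratios(results: BayesSpatialLogitResults) -> pd.DataFrame:
    """Fixed-effect POR table with 95% intervals and significance flags."""
    return results.odds_ratios()


def agreement(observed: pd.DataFrame, predicted: pd.DataFrame) -> dict[str, float]:
    """State-level agreement between observed and predicted prevalence (%).

    ``observed`` needs columns state_id + prevalence_pct; ``predicted``
    state_id + mean_pct.  R² is the squared Pearson correlation; RMSE/MAE
    are on the percentage-point scale.
    """
    merged = observed.merge(
        predicted[predicted["state_id"] != "(national)"], on="state_id", how="inner"
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 states common to both tables")
    o = merged["prevalence_pct"].to_numpy(dtype=float)
    p = merged["mean_pct"].to_numpy(dtype=float)
    if o.std() == 0 or p.std() == 0:
        raise ValueError("zero variance in observed or predicted prevalences; R2 undefined")
    r = np.corrcoef(o, p)[0, 1]
    return {
        "R2": float(r * r),
        "RMSE": float(np.sqrt(np.mean((o - p) ** 2))),
        "MAE": float(np.mean(np.abs(o - p))),
    }


def classification_scores(
    y: np.ndarray,
    p_hat: np.ndarray,
    threshold: float = 0.5,
    precision_over_all: bool = False,
) -> dict[str, float]:
    """Accuracy, precision, recall and AUC for one scored fold.

    ``precision`` is TP / predicted positives (0 when nothing is predicted
    positive); ``precision_over_all=True`` instead reports TP over all
    predictions.  AUC uses midranks, so a constant score gives 0.5.
    """
    y = np.asarray(y, dtype=int)
    pred = (np.asarray(p_hat, dtype=float) >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    n = len(y)
    if precision_over_all:
        precision = tp / n
    else:
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    if len(np.unique(y)) < 2:
        auc = float("nan")
    elif np.ptp(p_hat) == 0:
        auc = 0.5
    else:
        auc = float(roc_auc_score(y, p_hat))
    return {
        "accuracy": (tp + tn) / n,
        "precision": precision,
        "recall": recall,
        "auc": auc,
    }


def _cluster_folds(
    records: pd.DataFrame, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign clusters to k folds, stratified by cluster-level prevalence.

    Clusters are shuffled, sorted by prevalence and dealt snake-wise so
    every fold sees a similar outcome mix; all girls of a cluster share a
    fold (respecting the survey design).
    """
    prev = records.groupby("cluster_id")["fgm_status"].mean()
    clusters = prev.index.to_numpy()
    order = rng.permutation(len(clusters))
    clusters = clusters[order]
    p = prev.to_numpy()[order]
    clusters = clusters[np.argsort(p, kind="stable")]
    fold_of = {}
    f, step = 0, 1
    for c in clusters:
        fold_of[c] = f
        f += step
        if f == k or f == -1:
            step = -step
            f += step
    return records["cluster_id"].map(fold_of).to_numpy()


def cross_validate(
    records: pd.DataFrame,
    spec: ModelSpec,
    structure: ICARStructure | None = None,
    k: int = 5,
    repeats: int = 5,
    threshold: float = 0.5,
    mcmc: dict | None = None,
    seed: int = 0,
    precision_over_all: bool = False,
) -> pd.DataFrame:
    """k-fold, r-repeated cross-validation of the hierarchical model.

    Folds are stratified by outcome and blocked by cluster; the model is
    refit on each training set (at the — typically reduced — MCMC settings
    in ``mcmc``) and held-out records are scored by their posterior-mean
    probability.  Returns one row per fold x repeat plus pooled means.
    """
    mcmc = mcmc or {"iterations": 800, "burn_in": 300, "thin": 1}
    graph = structure.graph if (structure is not None and spec.has_structured) else None
    rows = []
    for rep in range(repeats):
        folds = None
        for attempt in range(10):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), rep, attempt))
            )
            cand = _cluster_folds(records, k, rng)
            ok = all(
                records.loc[cand != f, "fgm_status"].nunique() == 2 for f in range(k)
            )
            if ok:
                folds = cand
                break
        if folds is None:
            raise RuntimeError("could not build folds with both classes in every training set")
        for f in range(k):
            train = records[folds != f]
            test = records[folds == f]
            model = BayesSpatialLogit.from_dataframe(train, spec, graph=graph)
            res = model.fit(seed=int(seed) * 1000 + rep * 10 + f, **mcmc)
            p_hat = res.predict_proba(test)
            scores = classification_scores(
                test["fgm_status"].to_numpy(), p_hat, threshold, precision_over_all
            )
            rows.append({"repeat": rep, "fold": f, **scores})
    report = pd.DataFrame(rows)
    return report


def pooled_cv_summary(report: pd.DataFrame) -> dict[str, float]:
    """Mean of each CV metric over all fold x repeat rows."""
    return {
        m: float(np.nanmean(report[m])) for m in ("accuracy", "precision", "recall", "auc")
    }


def prevalence_change(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Per-state post-minus-pre change in posterior prevalence (points).

    States present in only one period are omitted with a warning; the
    rounded column mirrors map-label conventions, full precision is kept.
    """
    a = pre[pre["state_id"] != "(national)"][["state_id", "mean_pct"]]
    b = post[post["state_id"] != "(national)"][["state_id", "mean_pct"]]
    only = set(a["state_id"]).symmetric_difference(b["state_id"])
    if only:
        logger.warning("states %s present in only one period; omitted", sorted(only))
    merged = a.merge(b, on="state_id", suffixes=("_pre", "_post"))
    merged["change_pct"] = merged["mean_pct_post"] - merged["mean_pct_pre"]
    merged["change_rounded"] = merged["change_pct"].round().astype(int)
    return merged
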