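"""Model specifications and design-matrix construction.

Three nested specifications are supported:

* ``m1`` — fixed effects + nonlinear smooths + weight covariate;
* ``m2`` — m1 + structured (Besag ICAR) state effect;
* ``m3`` — m2 + unstructured iid Gaussian state effect (the BYM pair).

Fixed categorical covariates are reference-coded (reference level first in
the declared category order contributes no column).  Nonlinear covariates
are discretised onto fixed grids — ages in 1-year bins, community
proportions in 20 equal-width bins — and modelled with a random-walk prior
over the grid values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import CATEGORIES

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "DesignInfo", "DesignMatrices", "build_design", "smooth_bin_index"]

INDIVIDUAL_FIXED = [
    "mother_education",
    "mother_marital",
    "mother_support",
    "mother_fgm",
    "wealth",
    "ethnicity",
    "religion",
]
COMMUNITY_FIXED = ["zone", "residence", "main_religion", "main_wealth"]
COMMUNITY_LINEAR = ["efi", "pct_secondary_plus"]  # continuous, entered linearly
INDIVIDUAL_SMOOTHS = ["girl_age", "mother_age"]
COMMUNITY_SMOOTHS = ["pct_cut", "pct_support"]

# Community covariate columns carry the girl's cluster profile; categorical
# ones reuse the girl-level category orders.
_COMMUNITY_CATEGORIES = {
    "main_religion": CATEGORIES["religion"],
    "main_wealth": CATEGORIES["wealth"],
}

SMOOTH_GRIDS: dict[str, np.ndarray] = {
    "girl_age": np.arange(0, 15, dtype=float),
    "mother_age": np.arange(15, 50, dtype=float),
    "pct_cut": (np.arange(20) + 0.5) / 20.0,
    "pct_support": (np.arange(20) + 0.5) / 20.0,
}


def smooth_bin_index(name: str, values: np.ndarray) -> np.ndarray:
    """Map raw covariate values onto the fixed grid of a smooth term.

    Ages use unit bins anchored at the grid start; proportions (fractions in
    [0, 1]) use ``floor(p * 20)`` clamped to the last bin.
    """
    values = np.asarray(values, dtype=float)
    if name in ("girl_age", "mother_age"):
        lo = SMOOTH_GRIDS[name][0]
        idx = np.round(values - lo).astype(int)
        n = len(SMOOTH_GRIDS[name])
        if (idx < 0).any() or (idx >= n).any():
            raise ValueError(f"{name} values outside grid [{lo}, {lo + n - 1}]")
        return idx
    if name in ("pct_cut", "pct_support"):
        if (values < 0).any() or (values > 1).any():
            raise ValueError(f"{name} proportions must lie in [0, 1]")
        return np.minimum((values * 20).astype(int), 19)
    raise KeyError(f"unknown smooth covariate {name!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Which model complexity and covariate set to fit.

    ``complexity``: m1 (no spatial), m2 (structured only), m3 (structured +
    unstructured).  ``covariate_set`` selects individual-level, community-
    level, or both covariate blocks.
    """

    complexity: str = "m2"
    covariate_set: str = "individual"
    smooth_covariates: tuple[str, ...] | None = None
    include_weight_covariate: bool = True

    def __post_init__(self) -> None:
        if self.complexity not in ("m1", "m2", "m3"):
            raise ValueError(f"complexity must be m1/m2/m3, got {self.complexity!r}")
        if self.covariate_set not in ("individual", "community", "both"):
            raise ValueError(f"bad covariate_set {self.covariate_set!r}")

    @property
    def has_structured(self) -> bool:
        return self.complexity in ("m2", "m3")

    @property
    def has_unstructured(self) -> bool:
        return self.complexity == "m3"

    def fixed_covariates(self) -> list[str]:
        out: list[str] = []
        if self.covariate_set in ("individual", "both"):
            out += INDIVIDUAL_FIXED
        if self.covariate_set in ("community", "both"):
            out += COMMUNITY_FIXED
        return out

    def linear_covariates(self) -> list[str]:
        if self.covariate_set in ("community", "both"):
            return list(COMMUNITY_LINEAR)
        return []

    def smooths(self) -> list[str]:
        if self.smooth_covariates is not None:
            return list(self.smooth_covariates)
        out: list[str] = []
        if self.covariate_set in ("individual", "both"):
            out += INDIVIDUAL_SMOOTHS
        if self.covariate_set in ("community", "both"):
            out += COMMUNITY_SMOOTHS
        return out

    def to_dict(self) -> dict:
        return {
            "complexity": self.complexity,
            "covariate_set": self.covariate_set,
            "smooth_covariates": list(self.smooths()),
            "include_weight_covariate": self.include_weight_covariate,
        }


@dataclass(frozen=True)
class DesignInfo:
    """Frozen encoding context so new records can be coded identically."""

    spec: ModelSpec
    fixed_terms: tuple[tuple[str, str], ...]  # (covariate, level) per column
    linear_terms: tuple[str, ...]
    smooth_names: tuple[str, ...]
    state_labels: tuple[str, ...]


@dataclass
class DesignMatrices:
    """Encoded model inputs: fixed block, smooth bins, state index, outcome."""

    X_fixed: np.ndarray  # (n, p_fixed) incl. intercept (+ weight col last)
    fixed_names: list[str]
    smooth_idx: dict[str, np.ndarray]  # name -> per-record bin index
    smooth_grids: dict[str, np.ndarray]
    state_index: np.ndarray
    weight: np.ndarray  # sampling weight (kept distinct from the covariate)
    y: np.ndarray
    info: DesignInfo

    @property
    def n(self) -> int:
        return len(self.y)


def _categories_for(cov: str) -> list[str]:
    if cov in CATEGORIES:
        return CATEGORIES[cov]
    if cov in _COMMUNITY_CATEGORIES:
        return _COMMUNITY_CATEGORIES[cov]
    raise KeyError(f"no declared categories for covariate {cov!r}")


def _fixed_terms(
    records: pd.DataFrame, spec: ModelSpec
) -> list[tuple[str, str]]:
    terms: list[tuple[str, str]] = []
    for cov in spec.fixed_covariates():
        if cov not in records.columns:
            raise ValueError(f"records lack covariate column {cov!r}")
        levels = _categories_for(cov)
        observed = set(records[cov].astype(str))
        unknown = observed - set(levels)
        if unknown:
            raise ValueError(f"covariate {cov!r} has undeclared level(s) {sorted(unknown)}")
        if len(observed) < 2:
            logger.warning("covariate %r has a single observed level; dropped", cov)
            continue
        for lev in levels[1:]:
            if lev in observed:
                terms.append((cov, lev))
            else:
                logger.warning("level %s[%s] unobserved; column dropped", cov, lev)
    return terms


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    state_labels: Sequence[str] | None = None,
    like: DesignInfo | None = None,
) -> DesignMatrices:
    """Encode records into the design blocks of the hierarchical model.

    ``state_labels`` fixes the state order (use the adjacency graph's node
    order for spatial models).  ``like`` re-applies a previously frozen
    encoding, as needed when scoring held-out records.
    """
    n = len(records)
    if n == 0:
        raise ValueError("no records")
    if like is not None:
        spec = like.spec
        terms = list(like.fixed_terms)
        linear = list(like.linear_terms)
        smooth_names = list(like.smooth_names)
        labels = list(like.state_labels)
    else:
        terms = _fixed_terms(records, spec)
        linear = spec.linear_covariates()
        smooth_names = spec.smooths()
        labels = (
            list(state_labels)
            if state_labels is not None
            else sorted(records["state_id"].astype(str).unique())
        )

    cols = [np.ones(n)]
    names = ["intercept"]
    for cov, lev in terms:
        cols.append((records[cov].astype(str) == lev).to_numpy(dtype=float))
        names.append(f"{cov}[{lev}]")
    for cov in linear:
        if cov not in records.columns:
            raise ValueError(f"records lack community column {cov!r}")
        vals = records[cov].to_numpy(dtype=float)
        cols.append(vals / 100.0 if cov == "pct_secondary_plus" else vals)
        names.append(cov)
    weight = records["weight"].to_numpy(dtype=float)
    if spec.include_weight_covariate:
        cols.append(weight)
        names.append("weight")
    X_fixed = np.column_stack(cols)

    smooth_idx: dict[str, np.ndarray] = {}
    smooth_grids: dict[str, np.ndarray] = {}
    for name in smooth_names:
        if name in ("pct_cut", "pct_support"):
            if name not in records.columns:
                raise ValueError(f"records lack community column {name!r}")
            vals = records[name].to_numpy(dtype=float) / 100.0
        else:
            vals = records[name].to_numpy(dtype=float)
        smooth_idx[name] = smooth_bin_index(name, vals)
        smooth_grids[name] = SMOOTH_GRIDS[name].copy()

    label_pos = {lab: i for i, lab in enumerate(labels)}
    states = records["state_id"].astype(str)
    unknown_states = set(states) - set(labels)
    if unknown_states:
        raise ValueError(f"records reference unknown state(s) {sorted(unknown_states)}")
    state_index = states.map(label_pos).to_numpy(dtype=int)

    y = records["fgm_status"].to_numpy(dtype=float)
    info = like or DesignInfo(
        spec=spec,
        fixed_terms=tuple(terms),
        linear_terms=tuple(linear),
        smooth_names=tuple(smooth_names),
        state_labels=tuple(labels),
    )
    return DesignMatrices(
        X_fixed=X_fixed,
        fixed_names=names,
        smooth_idx=smooth_idx,
        smooth_grids=smooth_grids,
        state_index=state_index,
        weight=weight,
        y=y,
        info=info,
    )
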