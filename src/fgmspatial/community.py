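"""Community-level covariates and weighted descriptive prevalence tables.

The community is the survey cluster.  Cluster profiles summarise the women
(mothers) interviewed in the cluster: education, support for continuation,
FGM status, the Ethnic Fractionalisation Index (EFI), and modal religion /
wealth quintile.  All percentages are weighted ratio estimators, so they
are invariant to rescaling the weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import CATEGORIES

__all__ = [
    "efi",
    "community_aggregates",
    "weighted_prevalence",
    "age_at_cutting_distribution",
    "AGE_AT_CUTTING_BANDS",
]

# Age-at-cutting bands for the descriptive distribution (upper edges incl.)
AGE_AT_CUTTING_BANDS: list[tuple[str, int, int]] = [
    ("<=1", 0, 1),
    ("2-4", 2, 4),
    ("5-9", 5, 9),
    ("10-14", 10, 14),
]


def efi(proportions: np.ndarray) -> float:
    """Ethnic Fractionalisation Index ``1 - sum(s_k^2)`` of group shares.

    The probability that two randomly drawn community members belong to
    different groups: 0 for a mono-ethnic community, at most ``1 - 1/n``
    for ``n`` equally sized groups.
    """
    s = np.asarray(proportions, dtype=float)
    if s.size < 1:
        raise ValueError("need at least one group share")
    if (s < 0).any():
        raise ValueError("group shares must be nonnegative")
    if abs(s.sum() - 1.0) > 1e-9:
        raise ValueError(f"group shares sum to {s.sum():.6g}, not 1")
    return float(1.0 - np.sum(s * s))


def _weighted_mode(values: pd.Series, weights: np.ndarray, order: list[str]) -> str:
    totals = {}
    for v, w in zip(values, weights):
        totals[v] = totals.get(v, 0.0) + w
    best = max(totals.values())
    for lev in order:  # declared category order breaks ties deterministically
        if totals.get(lev, -1.0) >= best - 1e-12:
            return lev
    raise ValueError("modal category outside declared levels")


def community_aggregates(women: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster profile of the women's covariates (weighted).

    Expects mother-level columns (``mother_education``, ``mother_support``,
    ``mother_fgm``, ``ethnicity``, ``religion``, ``wealth``, ``weight``)
    alongside ``cluster_id``/``state_id``/``zone``/``residence``.
    """
    if "cluster_id" not in women.columns:
        raise ValueError("records lack cluster_id")
    if len(women) == 0:
        raise ValueError("no records")
    rows = []
    for cid, grp in women.groupby("cluster_id", sort=True):
        w = grp["weight"].to_numpy(dtype=float)
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"cluster {cid} has zero total weight")

        def wpct(mask: pd.Series) -> float:
            return float(100.0 * (w * mask.to_numpy(dtype=float)).sum() / tot)

        shares = (
            grp.groupby("ethnicity")["weight"].sum().to_numpy(dtype=float) / tot
        )
        rows.append(
            {
                "cluster_id": cid,
                "state_id": grp["state_id"].iloc[0],
                "zone": grp["zone"].iloc[0],
                "residence": grp["residence"].iloc[0],
                "pct_secondary_plus": wpct(
                    grp["mother_education"].isin(["secondary", "higher"])
                ),
                "pct_support": wpct(grp["mother_support"] == "yes"),
                "pct_cut": wpct(grp["mother_fgm"] == "cut"),
                "efi": efi(shares),
                "main_religion": _weighted_mode(
                    grp["religion"], w, CATEGORIES["religion"]
                ),
                "main_wealth": _weighted_mode(grp["wealth"], w, CATEGORIES["wealth"]),
            }
        )
    return pd.DataFrame(rows)


def attach_community(records: pd.DataFrame) -> pd.DataFrame:
    """Merge cluster profiles back onto the girl records (by cluster)."""
    prof = community_aggregates(records)
    return records.merge(
        prof.drop(columns=["state_id", "zone", "residence"]),
        on="cluster_id",
        how="left",
        validate="many_to_one",
    )


def weighted_prevalence(
    records: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Weighted FGM prevalence table, optionally grouped.

    Each row reports ``sum(w*y)/sum(w)`` in percent plus weighted and
    unweighted counts; an empty grouping yields the single national row.
    """
    w = records["weight"].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    y = records["fgm_status"].to_numpy(dtype=float)
    if not by:
        return pd.DataFrame(
            {
                "prevalence_pct": [100.0 * (w * y).sum() / w.sum()],
                "n_weighted": [w.sum()],
                "n_unweighted": [len(records)],
            }
        )
    rows = []
    for key, grp in records.groupby(by, sort=True):
        gw = grp["weight"].to_numpy(dtype=float)
        gy = grp["fgm_status"].to_numpy(dtype=float)
        if gw.sum() <= 0:
            raise ValueError(f"group {key} has zero total weight")
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(by, key))
            | {
                "prevalence_pct": 100.0 * (gw * gy).sum() / gw.sum(),
                "n_weighted": gw.sum(),
                "n_unweighted": len(grp),
            }
        )
    return pd.DataFrame(rows)


def age_at_cutting_distribution(records: pd.DataFrame) -> pd.DataFrame:
    """Weighted distribution of age at cutting over fixed bands.

    Only cut girls contribute; the band percentages sum to 100.
    """
    cut = records[records["fgm_status"] == 1]
    if len(cut) == 0:
        raise ValueError("no cut girls in records")
    aac = cut["age_at_cutting"].to_numpy(dtype=float)
    if np.isnan(aac).any():
        raise ValueError("cut girls with missing age_at_cutting")
    w = cut["weight"].to_numpy(dtype=float)
    tot = w.sum()
    rows = []
    for label, lo, hi in AGE_AT_CUTTING_BANDS:
        m = (aac >= lo) & (aac <= hi)
        rows.append(
            {
                "band": label,
                "pct": 100.0 * w[m].sum() / tot,
                "n_weighted": w[m].sum(),
                "n_unweighted": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)
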