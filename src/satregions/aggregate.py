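"""Survey-weighted regional estimates of the outcome and covariates."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .regionalize import Partition

COVARIATE_COLUMNS = ("log_income", "unemployment", "log_density", "median_commute")


class DegenerateWeightsError(ValueError):
    """Raised when all weights are zero or no observations remain."""


def weighted_mean(values, weights) -> float:
    """Survey-weighted mean sum(w*x)/sum(w); weights must not all be zero."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if not total > 0:
        raise DegenerateWeightsError("sum of weights must be positive")
    return float(np.dot(weights, values) / total)


def weighted_sd(values, weights) -> float:
    """Unbiased weighted SD (reliability-weight denominator).

    Uses sum(w*(x-xbar)^2) / (sum(w) - sum(w^2)/sum(w)), which reduces to
    the classical n-1 sample SD under equal weights of any scale.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    mean = weighted_mean(values, weights)
    denom = total - np.dot(weights, weights) / total
    if denom <= 0:
        return 0.0
    return float(np.sqrt(np.dot(weights, (values - mean) ** 2) / denom))


def effective_n(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum(w^2)."""
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if not total > 0:
        raise DegenerateWeightsError("sum of weights must be positive")
    return float(total**2 / np.dot(weights, weights))


def region_estimates(
    partition: Partition,
    individuals: pd.DataFrame,
    tracts: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-region weighted mean, SE and SD of the outcome plus covariates.

    The SE is the weighted SD over the square root of the Kish effective
    sample size.  Covariate means are aggregated over tracts, weighted by
    tract weight totals ``w_k``; a region is flagged urban if the
    majority of its total weight comes from urban tracts.

    Raises ``DegenerateWeightsError`` if any region has no respondents,
    which makes the partition invalid for this sample.
    """
    ind = individuals.merge(
        partition.labels.rename("region_id"),
        left_on="tract_id",
        right_index=True,
        how="left",
    )
    if ind["region_id"].isna().any():
        missing = ind.loc[ind["region_id"].isna(), "tract_id"].unique()[:5]
        raise KeyError(f"individuals reference tracts outside the partition: {missing}")

    rows = []
    for region in partition.regions:
        sub = ind[ind["region_id"] == region.region_id]
        if len(sub) == 0:
            raise DegenerateWeightsError(
                f"region {region.region_id} has no respondents; "
                "partition invalid for this sample"
            )
        w = sub["weight"].to_numpy()
        x = sub["ls"].to_numpy()
        sd = weighted_sd(x, w)
        se = sd / np.sqrt(effective_n(w))
        rows.append(
            {
                "region_id": region.region_id,
                "ls_mean": weighted_mean(x, w),
                "ls_se": se,
                "ls_sd": sd,
                "n": len(sub),
                "total_weight": float(w.sum()),
            }
        )
    est = pd.DataFrame(rows).set_index("region_id")

    if tracts is not None:
        t = tracts.merge(
            partition.labels.rename("region_id"), left_on="tract_id", right_index=True
        )
        grouped = t.groupby("region_id")
        for col in COVARIATE_COLUMNS:
            if col in t.columns:
                est[col] = grouped.apply(
                    lambda g: weighted_mean(g[col], g["w_k"]) if g["w_k"].sum() > 0
                    else float(g[col].mean()),
                    include_groups=False,
                )
        urban_w = grouped.apply(
            lambda g: float(g.loc[g["urban"], "w_k"].sum()), include_groups=False
        )
        est["urban"] = urban_w > 0.5 * grouped["w_k"].sum()
    return est


def quintile_split(estimates: pd.DataFrame) -> pd.Series:
    """Label regions 1 (least happy fifth) to 5 (happiest fifth).

    Regions are ranked by mean outcome with ties broken by region id;
    quintile sizes differ by at most one.
    """
    n = len(estimates)
    if n < 5:
        raise ValueError("need at least 5 regions to form quintiles")
    ranked = estimates.assign(_rid=estimates.index).sort_values(
        ["ls_mean", "_rid"], kind="mergesort"
    )
    labels = np.empty(n, dtype=int)
    for q, chunk in enumerate(np.array_split(np.arange(n), 5)):
        labels[chunk] = q + 1
    return pd.Series(labels, index=ranked.index, name="quintile").reindex(estimates.index)
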