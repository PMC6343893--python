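"""Two-group comparisons of regional estimates with robust uncertainty.

Regions enter as equally weighted observations.  The difference of group
means carries an unequal-variance (Welch-form) standard error, which for
a two-group mean contrast coincides with heteroskedasticity-robust
regression on a group dummy up to the HC variant's small-sample factor.
Differences are also expressed in units of the all-regions SD of the
variable so that effect sizes are comparable across variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

Z95 = 1.96

#: Display order of the comparison tables (outcome first, then covariates).
TABLE_ORDER = (
    "ls_mean",
    "ls_sd",
    "log_income",
    "unemployment",
    "log_density",
    "median_commute",
)


@dataclass
class GroupComparison:
    variable: str
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    diff: float
    diff_se: float
    ci95: Tuple[float, float]
    normalized_diff: float
    n_a: int
    n_b: int


def _group_stats(x: np.ndarray) -> Tuple[float, float]:
    n = len(x)
    if n == 0:
        raise ValueError("empty group")
    if n == 1:
        raise ValueError("group of size 1: standard error undefined")
    mean = float(x.mean())
    se2 = float(((x - mean) ** 2).sum() / (n * (n - 1)))
    return mean, float(np.sqrt(se2))


def compare_groups(
    estimates: pd.DataFrame,
    variable: str,
    group_a_ids: Sequence,
    group_b_ids: Sequence,
    sd_all: float,
) -> GroupComparison:
    """Compare the means of a variable across two sets of regions.

    ``sd_all`` is the SD of the variable over all regions, used to
    express the difference as an effect size.
    """
    if variable not in estimates.columns:
        raise KeyError(f"estimates table has no column '{variable}'")
    if sd_all <= 0:
        raise ValueError("sd_all must be positive")
    a = estimates.loc[list(group_a_ids), variable].to_numpy(dtype=float)
    b = estimates.loc[list(group_b_ids), variable].to_numpy(dtype=float)
    mean_a, se_a = _group_stats(a)
    mean_b, se_b = _group_stats(b)
    diff = mean_a - mean_b
    diff_se = float(np.sqrt(se_a**2 + se_b**2))
    return GroupComparison(
        variable=variable,
        mean_a=mean_a,
        mean_b=mean_b,
        se_a=se_a,
        se_b=se_b,
        diff=diff,
        diff_se=diff_se,
        ci95=(diff - Z95 * diff_se, diff + Z95 * diff_se),
        normalized_diff=normalize_difference(diff, sd_all),
        n_a=len(a),
        n_b=len(b),
    )


def normalize_difference(diff: float, sd_all: float) -> float:
    """Difference in units of the variable's all-regions SD."""
    if sd_all <= 0:
        raise ValueError("sd_all must be positive for normalization")
    return float(diff / sd_all)


def weighted_correlation(x, y, w) -> float:
    """Weighted Pearson correlation from weighted central moments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    total = w.sum()
    xm = np.dot(w, x) / total
    ym = np.dot(w, y) / total
    cov = np.dot(w, (x - xm) * (y - ym)) / total
    vx = np.dot(w, (x - xm) ** 2) / total
    vy = np.dot(w, (y - ym) ** 2) / total
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance: correlation undefined")
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def comparison_table(
    estimates: pd.DataFrame,
    grouping: str,
    quintiles: Optional[pd.Series] = None,
    subset: Optional[str] = None,
    sd_all: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """One GroupComparison per variable for a standard grouping.

    ``grouping`` is ``"quintile"`` (top fifth vs bottom fifth by mean
    outcome; pass the labels from :func:`~satregions.aggregate.quintile_split`
    computed on the same subset) or ``"urban"`` (urban vs rural regions).
    ``subset`` optionally restricts to the ``"urban"`` or ``"rural"``
    regions before comparing quintiles.  ``sd_all`` maps variables to the
    SD used for normalization; by default the SD across the regions
    compared is used.
    """
    est = estimates
    if subset is not None:
        if subset not in ("urban", "rural"):
            raise ValueError("subset must be 'urban' or 'rural'")
        est = est[est["urban"] == (subset == "urban")]
    if grouping == "quintile":
        if quintiles is None:
            from .aggregate import quintile_split

            quintiles = quintile_split(est)
        quintiles = quintiles.reindex(est.index)
        ids_a = est.index[quintiles == 5]
        ids_b = est.index[quintiles == 1]
    elif grouping == "urban":
        ids_a = est.index[est["urban"]]
        ids_b = est.index[~est["urban"]]
    else:
        raise ValueError("grouping must be 'quintile' or 'urban'")

    variables = [v for v in TABLE_ORDER if v in est.columns]
    missing = [v for v in ("ls_mean",) if v not in est.columns]
    if missing:
        raise KeyError(f"estimates table lacks required column(s): {missing}")
    rows = []
    for var in variables:
        sd = (
            sd_all[var]
            if sd_all is not None and var in sd_all
            else float(est[var].std(ddof=1))
        )
        c = compare_groups(est, var, ids_a, ids_b, sd)
        rows.append(
            {
                "variable": var,
                "mean_a": c.mean_a,
                "se_a": c.se_a,
                "mean_b": c.mean_b,
                "se_b": c.se_b,
                "diff": c.diff,
                "diff_se": c.diff_se,
                "ci_low": c.ci95[0],
                "ci_high": c.ci95[1],
                "normalized_diff": c.normalized_diff,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
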