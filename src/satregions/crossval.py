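"""Leave-one-tract-out cross-validation of the aggregation scale.

For a partition induced by a sampling threshold, one tract is held out
of each region; the region's survey-weighted leave-out mean predicts the
held-out tract's mean via weighted least squares

    y_ij = b0 + b1 * xbar_{j,-i} + u_ij,    obs. weight = w_ij,

where y_ij is the held-out tract mean, xbar_{j,-i} the weighted mean of
the remaining tracts, and w_ij the held-out tract's weight total (tract
means are measured with noise inversely related to their sampling).
Sweeping the threshold and averaging the weighted R^2 over validation
draws and grid offsets traces predictive power against scale: small
regions predict with noisy but local means, large regions with precise
but biased ones, so R^2 peaks at an interior scale.  Holding the omitted
tracts fixed, maximizing R^2 is equivalent to minimizing the weighted
mean squared prediction error, and R^2 equals the squared weighted
correlation of prediction and outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .aggregate import weighted_mean
from .regionalize import Partition, default_cell_size, regionalize

logger = logging.getLogger(__name__)


@dataclass
class CVFit:
    """One omitted-tract regression: coefficients, weighted R^2, residuals."""

    beta0: float
    beta1: float
    r2: float
    residuals: np.ndarray
    n_pairs: int
    threshold_n: Optional[int] = None
    draw_index: Optional[int] = None
    offset_index: Optional[int] = None


def select_validation(
    partition: Partition,
    tracts: pd.DataFrame,
    rng: np.random.Generator,
) -> List[Tuple[str, str]]:
    """Pick one sampled tract per region, uniformly at random.

    Regions with fewer than two sampled tracts are skipped (the leave-out
    mean would be undefined) and logged.  Deterministic given the
    generator state.
    """
    sampled = set(tracts.loc[tracts["n_k"] > 0, "tract_id"])
    picks = []
    skipped = 0
    for region in partition.regions:
        usable = sorted(t for t in region.tract_ids if t in sampled)
        if len(usable) < 2:
            skipped += 1
            continue
        picks.append((region.region_id, usable[rng.integers(len(usable))]))
    if skipped:
        logger.debug("skipped %d region(s) with < 2 sampled tracts", skipped)
    return picks


def leave_out_mean(
    region_tracts: pd.DataFrame, omitted_tract_id: str
) -> float:
    """Weighted mean outcome over a region's tracts, excluding one.

    ``region_tracts`` holds the region's rows of the tract table; weights
    are the tract weight totals ``w_k``.
    """
    rest = region_tracts[
        (region_tracts["tract_id"] != omitted_tract_id) & (region_tracts["w_k"] > 0)
    ]
    if len(rest) == 0:
        raise ValueError(
            f"leave-out mean undefined: no weighted tracts remain after omitting "
            f"{omitted_tract_id}"
        )
    return weighted_mean(rest["ls_mean_k"], rest["w_k"])


def build_validation_pairs(
    partition: Partition,
    tracts: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assemble (y, x, weight) per region from a random validation draw."""
    t = tracts.set_index("tract_id", drop=False)
    region_of = {r.region_id: r for r in partition.regions}
    rows = []
    for region_id, omitted in select_validation(partition, tracts, rng):
        sub = t.loc[region_of[region_id].tract_ids]
        rows.append(
            {
                "region_id": region_id,
                "omitted_tract_id": omitted,
                "y": float(sub.at[omitted, "ls_mean_k"]),
                "x": leave_out_mean(sub, omitted),
                "weight": float(sub.at[omitted, "w_k"]),
            }
        )
    return pd.DataFrame(rows)


def fit_wls(pairs: pd.DataFrame) -> CVFit:
    """Weighted least squares of y on x with intercept.

    R^2 uses the weight-centred total sum of squares,
    1 - sum(w u^2) / sum(w (y - ybar_w)^2), so it equals the squared
    weighted correlation of x and y.  A constant predictor yields r2 = 0
    with a warning.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 validation pairs to fit")
    y = pairs["y"].to_numpy(dtype=float)
    x = pairs["x"].to_numpy(dtype=float)
    w = pairs["weight"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        warnings.warn("constant leave-out means: slope undefined, returning r2=0")
        ybar = weighted_mean(y, w)
        return CVFit(beta0=ybar, beta1=0.0, r2=0.0, residuals=y - ybar, n_pairs=len(y))
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    resid = y - model.fittedvalues
    ybar = weighted_mean(y, w)
    tss = np.dot(w, (y - ybar) ** 2)
    r2 = 1.0 - np.dot(w, resid**2) / tss if tss > 0 else 0.0
    return CVFit(
        beta0=float(model.params[0]),
        beta1=float(model.params[1]),
        r2=float(r2),
        residuals=resid,
        n_pairs=len(y),
    )


def sweep_scales(
    tracts: pd.DataFrame,
    thresholds: Sequence[int],
    n_draws: int = 20,
    n_offsets: int = 5,
    cell_size: Optional[float] = None,
    seed: int = 0,
    axis_rule: str = "halve-longer",
) -> pd.DataFrame:
    """Average the validation R^2 over draws and grid offsets per threshold.

    Returns the cross-validation curve: one row per threshold with the
    mean regional sample size, mean weighted R^2, its Monte-Carlo
    standard error, and the repeat count.  Offsets are drawn uniformly
    on one starting cell per axis; all randomness derives from ``seed``.
    Thresholds yielding fewer than 3 usable pairs are excluded with a
    warning.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    thresholds = sorted(int(t) for t in thresholds)
    if cell_size is None:
        cell_size = default_cell_size(tracts[["x", "y"]].to_numpy(dtype=float))
    rows = []
    for ti, threshold in enumerate(thresholds):
        r2s, sizes, n_pairs = [], [], []
        for oi in range(n_offsets):
            child = np.random.default_rng(
                np.random.SeedSequence([int(seed), 17, ti, oi])
            )
            offset = tuple(child.uniform(0.0, cell_size, size=2))
            part = regionalize(tracts, threshold, cell_size, offset, axis_rule)
            total_n = sum(r.count for r in part.regions)
            sizes.append(total_n / part.n_regions)
            for di in range(n_draws):
                draw_rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), 19, ti, oi, di])
                )
                pairs = build_validation_pairs(part, tracts, draw_rng)
                if len(pairs) < 3:
                    continue
                r2s.append(fit_wls(pairs).r2)
                n_pairs.append(len(pairs))
        if not r2s:
            warnings.warn(f"threshold {threshold} yields < 3 usable pairs; excluded")
            continue
        r2s = np.asarray(r2s)
        rows.append(
            {
                "threshold_n": threshold,
                "mean_region_sample": float(np.mean(sizes)),
                "mean_r2": float(r2s.mean()),
                "mc_se": float(r2s.std(ddof=1) / np.sqrt(len(r2s))) if len(r2s) > 1 else np.nan,
                "mean_n_pairs": float(np.mean(n_pairs)),
                "n_repeats": int(len(r2s)),
            }
        )
    return pd.DataFrame(rows)


def optimal_scale(curve: pd.DataFrame) -> int:
    """Threshold with maximal mean R^2; ties go to the smaller threshold."""
    if len(curve) == 0:
        raise ValueError("empty cross-validation curve")
    c = curve.sort_values("threshold_n")
    best = c["mean_r2"].to_numpy().argmax()  # argmax takes the first maximum
    return int(c["threshold_n"].iloc[best])


class ScaleSelectionCV(BaseEstimator):
    """Scikit-learn style scale selector for the sampling threshold.

    Fitting sweeps the candidate thresholds with repeated validation
    draws and grid offsets and records the R^2 curve.

    Parameters
    ----------
    thresholds : sequence of int
        Candidate minimum samples per region.
    n_draws, n_offsets : int
        Validation draws per regionalization and random grid offsets per
        threshold; their product is the repeat count per threshold.
    cell_size : float or None
        Starting grid cell side; ``None`` uses a quarter of the extent.
    axis_rule : str
        Bisection reading passed to the regionalizer.
    random_state : int
        Master seed for offsets and validation draws.

    Attributes
    ----------
    curve_ : DataFrame
        threshold_n, mean_region_sample, mean_r2, mc_se, n_repeats.
    best_threshold_ : int
        R^2-maximizing threshold (ties -> smaller).
    best_score_ : float
        Mean R^2 at the selected threshold.
    """

    def __init__(
        self,
        thresholds: Sequence[int] = (50, 100, 200, 400, 800, 1600, 3200, 6400),
        n_draws: int = 20,
        n_offsets: int = 5,
        cell_size: Optional[float] = None,
        axis_rule: str = "halve-longer",
        random_state: int = 0,
    ):
        self.thresholds = thresholds
        self.n_draws = n_draws
        self.n_offsets = n_offsets
        self.cell_size = cell_size
        self.axis_rule = axis_rule
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        """Sweep scales on a tract table (needs x, y, n_k, w_k, ls_mean_k)."""
        self.curve_ = sweep_scales(
            X,
            self.thresholds,
            n_draws=self.n_draws,
            n_offsets=self.n_offsets,
            cell_size=self.cell_size,
            seed=self.random_state,
            axis_rule=self.axis_rule,
        )
        self.best_threshold_ = optimal_scale(self.curve_)
        row = self.curve_[self.curve_["threshold_n"] == self.best_threshold_]
        self.best_score_ = float(row["mean_r2"].iloc[0])
        return self
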