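"""Synthetic survey geography: tracts, covariates, and individual responses.

The generator stands in for a restricted national survey linked to census
geography.  It produces

* a planar map of tract centroids, urban ones clustered around city
  centres and rural ones dispersed, each tract assigned to a coarse
  sampling stratum (a city or a rural block);
* neighbourhood "communities" (spatial clusters of ~8 tracts) carrying
  nested random effects, so that true mean outcomes are spatially
  clustered with an urban/rural level difference;
* tract-level covariates (income, unemployment, density, commute) that
  can feed back into community means with configurable slopes;
* individual 0-10 integer responses with a large idiosyncratic variance
  relative to the between-community variance, lognormal survey weights,
  and a 13-bin age structure whose mix differs between urban and rural
  strata.

Sampling intensity varies at the *stratum* level: each stratum draws an
expected per-tract rate and distributes its total sample multinomially
over its tracts, which reproduces the uneven tract sampling induced by
coarse survey stratification.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans

from .config import N_AGE_BINS, ConfigError, SimConfig

logger = logging.getLogger(__name__)

TRACT_COLUMNS = ["tract_id", "x", "y", "stratum_id", "urban", "community_id",
                 "n_k", "w_k", "ls_mean_k"]

# Age-mix tilt: urban strata over-represent the young, rural the old,
# with near-equal middle-aged shares.  The size is set so the
# composition-only share of the urban/rural outcome gap stays a few
# percent (the estimated national per-bin means embed the urban penalty
# of the young bins, which roughly triples the configured asymmetry).
_AGE_TILT = 0.25


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    """Stage-scoped generator so each stage's stream is independent."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def generate_geography(config: SimConfig) -> pd.DataFrame:
    """Generate tract centroids, strata and neighbourhood communities.

    Returns a tract table without outcome statistics (``n_k`` and ``w_k``
    zero, ``ls_mean_k`` missing).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_tracts
    area = config.area_size

    n_urban = int(round(config.urban_fraction * n))
    n_rural = n - n_urban

    x = np.empty(n)
    y = np.empty(n)
    stratum = np.empty(n, dtype=object)
    urban = np.zeros(n, dtype=bool)

    if n_urban > 0:
        margin = min(0.1 * area, 3 * config.city_spread)
        centres = rng.uniform(margin, area - margin, size=(config.n_cities, 2))
        # Zipf-like city sizes: a few large cities, many smaller ones.
        size_w = 1.0 / np.arange(1, config.n_cities + 1)
        size_w /= size_w.sum()
        city = rng.choice(config.n_cities, size=n_urban, p=size_w)
        scatter = rng.normal(0.0, config.city_spread, size=(n_urban, 2))
        pos = np.clip(centres[city] + scatter, 0.0, area)
        x[:n_urban], y[:n_urban] = pos[:, 0], pos[:, 1]
        stratum[:n_urban] = np.array([f"C{c:02d}" for c in city], dtype=object)
        urban[:n_urban] = True

    if n_rural > 0:
        pos = rng.uniform(0.0, area, size=(n_rural, 2))
        x[n_urban:], y[n_urban:] = pos[:, 0], pos[:, 1]
        block = area / config.rural_blocks
        bx = np.minimum((pos[:, 0] // block).astype(int), config.rural_blocks - 1)
        by = np.minimum((pos[:, 1] // block).astype(int), config.rural_blocks - 1)
        stratum[n_urban:] = np.array(
            [f"R{i:02d}{j:02d}" for i, j in zip(bx, by)], dtype=object
        )

    tracts = pd.DataFrame(
        {
            "tract_id": [f"T{i:05d}" for i in range(n)],
            "x": x,
            "y": y,
            "stratum_id": stratum,
            "urban": urban,
        }
    )
    tracts["community_id"] = _assign_communities(tracts, config)
    tracts["n_k"] = 0
    tracts["w_k"] = 0.0
    tracts["ls_mean_k"] = np.nan
    return tracts


def _assign_communities(tracts: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Cluster each stratum's tracts into spatial neighbourhood communities."""
    seed_rng = _rng(config, 3)
    out = np.empty(len(tracts), dtype=object)
    for stratum_id in sorted(tracts["stratum_id"].unique()):
        idx = np.flatnonzero((tracts["stratum_id"] == stratum_id).to_numpy())
        k = max(1, int(round(len(idx) / config.tracts_per_community)))
        sub_seed = int(seed_rng.integers(0, 2**31 - 1))
        if k == 1 or len(idx) <= k:
            labels = np.zeros(len(idx), dtype=int)
        else:
            coords = tracts.iloc[idx][["x", "y"]].to_numpy()
            labels = KMeans(n_clusters=k, n_init=1, random_state=sub_seed).fit_predict(coords)
        for j, lab in zip(idx, labels):
            out[j] = f"{stratum_id}.{lab:03d}"
    return out


def generate_covariates(tracts: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Attach tract covariates with urban/rural structure.

    Income and unemployment mix a community-level component with tract
    noise; density falls with distance from the city core and carries an
    urban premium; commute times are longer in cities.  Units follow the
    national aggregates these emulate (log dollars, percent, log persons
    per km^2, minutes).
    """
    config.validate()
    rng = _rng(config, 1)
    tracts = tracts.copy()
    comm_ids = np.sort(tracts["community_id"].unique())
    comm_index = pd.Series(np.arange(len(comm_ids)), index=comm_ids)
    c_of = comm_index[tracts["community_id"]].to_numpy()
    n = len(tracts)

    z_inc = rng.normal(size=len(comm_ids))
    tracts["log_income"] = 11.23 + 0.27 * (0.75 * z_inc[c_of] + 0.66 * rng.normal(size=n))
    z_un = rng.normal(size=len(comm_ids))
    tracts["unemployment"] = np.clip(
        7.95 + 3.81 * (0.70 * z_un[c_of] + 0.71 * rng.normal(size=n)), 0.0, None
    )

    urban = tracts["urban"].to_numpy()
    dens = np.empty(n)
    dens[~urban] = 2.3 + 1.0 * rng.normal(size=(~urban).sum())
    if urban.any():
        # Density decays away from the stratum's centre of mass.
        ux = tracts.loc[urban, "x"].to_numpy()
        uy = tracts.loc[urban, "y"].to_numpy()
        g = tracts.loc[urban].groupby("stratum_id")
        cx = g["x"].transform("mean").to_numpy()
        cy = g["y"].transform("mean").to_numpy()
        dist = np.hypot(ux - cx, uy - cy)
        dens[urban] = 6.9 - 0.5 * (dist / config.city_spread - 1.25) + 0.6 * rng.normal(size=urban.sum())
    tracts["log_density"] = dens

    commute = np.where(urban, 21.7, 14.7) + 4.0 * rng.normal(size=n)
    tracts["median_commute"] = np.clip(commute, 2.0, None)
    return tracts


def discretized_mean(c: float, sigma: float) -> float:
    """Exact mean of round-and-clip of N(c, sigma) on the 0-10 scale."""
    if sigma == 0:
        return float(np.clip(np.rint(c), 0.0, 10.0))
    ks = np.arange(11)
    upper = stats.norm.cdf((ks + 0.5 - c) / sigma)
    upper[-1] = 1.0  # the top category absorbs the upper tail
    lower = np.concatenate([[0.0], upper[:-1]])  # bottom absorbs the lower tail
    return float(np.dot(ks, upper - lower))


def _clip_compensation(mu_latent: float, sigma: float) -> float:
    """Location shift so the round-and-clip response keeps its target mean.

    Rounding a latent normal to the integer 0-10 instrument is almost
    mean-preserving in the interior but the bounded end categories pull
    the realized mean toward the centre of the scale.  Returns the delta
    such that E[clip(round(N(mu+delta, sigma)))] == mu exactly.
    """
    if sigma == 0:
        return 0.0
    return float(
        optimize.brentq(
            lambda d: discretized_mean(mu_latent + d, sigma) - mu_latent, -5.0, 5.0
        )
    )


def _age_mix(urban: bool) -> np.ndarray:
    """Population shares over the 13 age bins for one stratum type."""
    bins = np.arange(1, N_AGE_BINS + 1)
    mid = (N_AGE_BINS + 1) / 2.0
    tilt = _AGE_TILT * (mid - bins) / (N_AGE_BINS / 2.0)
    p = 1.0 + (tilt if urban else -tilt)
    return p / p.sum()


def generate_responses(
    tracts: pd.DataFrame, config: SimConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw individual responses and recompute tract outcome statistics.

    Returns ``(individuals, tracts)``.  The individual response is a
    round-and-clipped latent normal: grand mean + urban/rural offset +
    stratum effect + community effect + covariate terms + age-profile
    deviation + idiosyncratic noise.  Tract ``n_k``, ``w_k`` and
    ``ls_mean_k`` are recomputed from the drawn individuals; the latent
    (noise-free) community mean is kept in ``true_mean``.
    """
    config.validate()
    for name in config.covariate_effects:
        if name not in tracts.columns:
            raise ConfigError(
                f"covariate_effects refers to '{name}' but tracts carry no such column; "
                "run generate_covariates first"
            )
    rng = _rng(config, 2)
    tracts = tracts.copy()
    n = len(tracts)

    strata = np.sort(tracts["stratum_id"].unique())
    comm_ids = np.sort(tracts["community_id"].unique())
    s_idx = pd.Series(np.arange(len(strata)), index=strata)
    c_idx = pd.Series(np.arange(len(comm_ids)), index=comm_ids)
    s_of = s_idx[tracts["stratum_id"]].to_numpy()
    c_of = c_idx[tracts["community_id"]].to_numpy()

    stratum_eff = rng.normal(0.0, config.sigma_city, size=len(strata))
    comm_eff = rng.normal(0.0, config.sigma_community, size=len(comm_ids))

    f = config.urban_fraction
    urban = tracts["urban"].to_numpy()
    offset = np.where(urban, -config.urban_gap * (1.0 - f), config.urban_gap * f)

    cov_term = np.zeros(len(comm_ids))
    for name, slope in config.covariate_effects.items():
        comm_mean = tracts.groupby("community_id")[name].mean().reindex(comm_ids).to_numpy()
        sd = comm_mean.std()
        if sd > 0:
            cov_term += slope * (comm_mean - comm_mean.mean()) / sd

    # Stratum-level sampling intensity, multinomial allocation to tracts.
    lo, hi = config.sampling_rate_range
    counts = np.zeros(n, dtype=int)
    for si, stratum_id in enumerate(strata):
        members = np.flatnonzero(s_of == si)
        rate = rng.uniform(lo, hi)
        total = int(round(rate * len(members)))
        if total > 0:
            counts[members] = rng.multinomial(total, np.full(len(members), 1.0 / len(members)))

    # Centre the combined effects on the realized sample so the population
    # mean is pinned at mu; a constant shift preserves every gap and SD.
    effect = offset + stratum_eff[s_of] + comm_eff[c_of] + cov_term[c_of]
    if counts.sum() > 0:
        effect = effect - np.average(effect, weights=counts)
    true_mean = config.mu + effect
    tracts["true_mean"] = true_mean

    tract_of_ind = np.repeat(np.arange(n), counts)
    n_ind = len(tract_of_ind)

    # Survey weights: lognormal, mean `mean_weight`, CV `weight_cv`.
    if config.weight_cv > 0:
        s2 = np.log1p(config.weight_cv**2)
        weights = rng.lognormal(np.log(config.mean_weight) - s2 / 2.0, np.sqrt(s2), size=n_ind)
    else:
        weights = np.full(n_ind, config.mean_weight)

    profile = np.asarray(config.age_profile, dtype=float)
    age_dev = profile - profile.mean()
    ind_urban = urban[tract_of_ind]
    age_bin = np.empty(n_ind, dtype=int)
    for flag in (True, False):
        mask = ind_urban == flag
        if mask.any():
            age_bin[mask] = rng.choice(
                np.arange(1, N_AGE_BINS + 1), size=int(mask.sum()), p=_age_mix(flag)
            )

    delta = _clip_compensation(config.mu, config.sigma_individual)
    latent = (
        true_mean[tract_of_ind]
        + delta
        + age_dev[age_bin - 1]
        + rng.normal(0.0, config.sigma_individual, size=n_ind)
    )
    if config.discretize:
        ls = np.clip(np.rint(latent), 0.0, 10.0)
        n_clipped = int(np.sum((latent < -0.5) | (latent > 10.5)))
        if n_clipped:
            logger.info("clipped %d of %d responses to the 0-10 scale", n_clipped, n_ind)
    else:
        ls = latent

    individuals = pd.DataFrame(
        {
            "tract_id": tracts["tract_id"].to_numpy()[tract_of_ind],
            "weight": weights,
            "ls": ls,
            "age_bin": age_bin,
            "urban": ind_urban,
        }
    )

    tracts["n_k"] = counts
    w_k = np.zeros(n)
    np.add.at(w_k, tract_of_ind, weights)
    wls = np.zeros(n)
    np.add.at(wls, tract_of_ind, weights * ls)
    tracts["w_k"] = w_k
    with np.errstate(invalid="ignore"):
        tracts["ls_mean_k"] = np.where(counts > 0, wls / np.where(w_k > 0, w_k, 1.0), np.nan)
    return individuals, tracts


def simulate(config: SimConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run geography -> covariates -> responses; returns (tracts, individuals)."""
    tracts = generate_geography(config)
    tracts = generate_covariates(tracts, config)
    individuals, tracts = generate_responses(tracts, config)
    return tracts, individuals
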