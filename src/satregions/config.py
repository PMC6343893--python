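"""Simulation configuration for the synthetic survey geography.

The generator emulates a national point-referenced well-being survey:
census-tract-like units with planar centroids, coarse sampling strata
(cities and rural blocks), spatially clustered community means, and
individual 0-10 life-satisfaction responses with a large idiosyncratic
variance relative to the variance between communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np

#: Number of respondent age bins (the CCHS convention).
N_AGE_BINS = 13

#: Mild U-shape over the life course: the young and the old report higher
#: life satisfaction than the middle-aged.  The U is nearly symmetric with
#: a slight old-end tilt, so the urban (young-heavy) and rural (old-heavy)
#: composition effects almost cancel and the composition-only gap stays a
#: few percent of the urban/rural outcome gap.
DEFAULT_AGE_PROFILE: Tuple[float, ...] = (
    8.30, 8.14, 8.00, 7.90, 7.84, 7.81, 7.80,
    7.82, 7.86, 7.92, 8.02, 8.16, 8.32,
)

#: Known covariates and the direction urban strata shift them.
KNOWN_COVARIATES = ("log_income", "unemployment", "log_density", "median_commute")


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of the synthetic survey-geography generator.

    Defaults are calibrated to the published national summary statistics:
    grand mean 8.04 on the 0-10 scale, within-community SD 1.66, SD of
    community means ~= 0.22, and a rural-minus-urban gap of 0.17 points.

    Parameters
    ----------
    n_tracts
        Number of atomic spatial units (census-tract analogues).
    n_cities
        Number of urban centres; each city is one sampling stratum.
    urban_fraction
        Expected fraction of tracts attached to cities (the national data
        has 776 of 1216 regions urban).
    mu
        Grand mean of the outcome, in points on the 0-10 scale.
    sigma_city
        SD of city-level mean effects (points).
    sigma_community
        SD of neighbourhood-cluster effects (points); together with
        ``sigma_city``, the urban gap and covariate slopes this sets the
        between-community SD of true means.
    sigma_individual
        SD of idiosyncratic respondent noise (points).
    urban_gap
        Mean rural-minus-urban offset (points); split around ``mu`` so the
        grand mean is preserved.
    sampling_rate_range
        (min, max) expected respondents per tract; the realized rate is
        drawn per *stratum*, so sampling intensity varies at a much coarser
        level than the tract.
    weight_cv
        Coefficient of variation of the lognormal survey weights.
    covariate_effects
        Slope (points per SD of the community-level covariate) each named
        covariate contributes to community means.
    age_profile
        13 national mean-outcome values, one per age bin; respondents get
        the mean-centred profile value of their bin added to the latent
        response.
    seed
        Master seed; every stream of randomness derives from it.
    area_size
        Side of the square study area, abstract distance units.
    city_spread
        SD of urban tract scatter around its city centre (distance units).
    rural_blocks
        Rural strata form a ``rural_blocks x rural_blocks`` grid.
    tracts_per_community
        Target neighbourhood-cluster size, in tracts.
    mean_weight
        Mean survey weight (persons represented per respondent).
    discretize
        Round-and-clip latent responses to the integer 0-10 instrument.
        Disable to study the continuous latent outcome.
    """

    n_tracts: int = 5000
    n_cities: int = 6
    urban_fraction: float = 0.62
    mu: float = 8.04
    sigma_city: float = 0.10
    sigma_community: float = 0.18
    sigma_individual: float = 1.66
    urban_gap: float = 0.17
    sampling_rate_range: Tuple[float, float] = (10.0, 110.0)
    weight_cv: float = 0.5
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"log_income": 0.04, "unemployment": -0.02}
    )
    age_profile: Sequence[float] = DEFAULT_AGE_PROFILE
    seed: int = 0
    area_size: float = 100.0
    city_spread: float = 3.0
    rural_blocks: int = 5
    tracts_per_community: int = 8
    mean_weight: float = 100.0
    discretize: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_tracts < 1:
            raise ConfigError("n_tracts must be a positive integer")
        if self.n_cities < 0:
            raise ConfigError("n_cities must be non-negative")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ConfigError("urban_fraction must lie in [0, 1]")
        if self.n_cities == 0 and self.urban_fraction > 0:
            raise ConfigError(
                "inconsistent config: urban_fraction > 0 requires n_cities >= 1"
            )
        for name in ("sigma_city", "sigma_community", "sigma_individual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.sampling_rate_range
        if lo < 1 or hi < lo:
            raise ConfigError("sampling_rate_range must satisfy 1 <= min <= max")
        if self.weight_cv < 0:
            raise ConfigError("weight_cv must be >= 0")
        if len(self.age_profile) != N_AGE_BINS:
            raise ConfigError(f"age_profile must have exactly {N_AGE_BINS} entries")
        unknown = set(self.covariate_effects) - set(KNOWN_COVARIATES)
        if unknown:
            raise ConfigError(f"unknown covariate(s) in covariate_effects: {sorted(unknown)}")
        if self.area_size <= 0 or self.city_spread <= 0:
            raise ConfigError("area_size and city_spread must be positive")
        if self.rural_blocks < 1 or self.tracts_per_community < 1:
            raise ConfigError("rural_blocks and tracts_per_community must be >= 1")
        if self.mean_weight <= 0:
            raise ConfigError("mean_weight must be positive")

    @property
    def between_community_sd(self) -> float:
        """SD of true community means implied by the variance components.

        City, neighbourhood and covariate effects are independent; the
        urban/rural offset contributes a two-point-mixture variance of
        ``urban_gap**2 * f * (1 - f)``.
        """
        f = self.urban_fraction
        var = (
            self.sigma_city**2
            + self.sigma_community**2
            + sum(v**2 for v in self.covariate_effects.values())
            + self.urban_gap**2 * f * (1.0 - f)
        )
        return float(np.sqrt(var))

    def replace(self, **changes) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        import dataclasses

        return dataclasses.replace(self, **changes)
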