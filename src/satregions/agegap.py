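"""Age-composition counterfactual for the urban/rural outcome gap.

Life satisfaction is U-shaped over the life course, and cities hold more
of the young while rural areas hold more of the old.  Holding the
age-specific national means fixed and swapping only the two groups' age
mixes simulates the part of the rural-minus-urban gap attributable to
age composition alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import N_AGE_BINS


def _validate_profile(profile) -> np.ndarray:
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (N_AGE_BINS,):
        raise ValueError(f"age profile must have exactly {N_AGE_BINS} values")
    if np.any((profile < 0) | (profile > 10)):
        raise ValueError("age profile values must lie on the 0-10 scale")
    return profile


def _validate_mix(mix) -> np.ndarray:
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (N_AGE_BINS,):
        raise ValueError(f"age mix must have exactly {N_AGE_BINS} shares")
    if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("age mix shares must be non-negative and sum to 1")
    return mix


def group_age_mix(individuals: pd.DataFrame, mask) -> np.ndarray:
    """Survey-weighted population shares over the 13 age bins for a group.

    ``mask`` selects the group's rows of the individual table (e.g. the
    urban respondents).  Shares use survey weights, matching the weighted
    outcome means they multiply.
    """
    sub = individuals[np.asarray(mask, dtype=bool)]
    if len(sub) == 0:
        raise ValueError("empty group: age mix undefined")
    totals = np.zeros(N_AGE_BINS)
    np.add.at(totals, sub["age_bin"].to_numpy() - 1, sub["weight"].to_numpy())
    return totals / totals.sum()


def age_profile_from_individuals(individuals: pd.DataFrame) -> np.ndarray:
    """National weighted mean outcome per age bin (13 values).

    Bins never observed fall back to the national mean, keeping the
    profile defined while contributing nothing to any mix actually
    observed.
    """
    w = individuals["weight"].to_numpy()
    ls = individuals["ls"].to_numpy(dtype=float)
    bins = individuals["age_bin"].to_numpy() - 1
    wsum = np.zeros(N_AGE_BINS)
    wls = np.zeros(N_AGE_BINS)
    np.add.at(wsum, bins, w)
    np.add.at(wls, bins, w * ls)
    national = wls.sum() / wsum.sum()
    with np.errstate(invalid="ignore"):
        profile = np.where(wsum > 0, wls / np.where(wsum > 0, wsum, 1.0), national)
    return profile


def counterfactual_gap(mix_urban, mix_rural, profile) -> float:
    """Rural-minus-urban gap implied by age composition alone.

    sum_a share_rural(a) * profile(a) - sum_a share_urban(a) * profile(a).
    """
    profile = _validate_profile(profile)
    mu = _validate_mix(mix_urban)
    mr = _validate_mix(mix_rural)
    return float(np.dot(mr, profile) - np.dot(mu, profile))


def gap_share(simulated_gap: float, observed_gap: float) -> float:
    """Simulated gap as a fraction of the observed gap."""
    if observed_gap == 0:
        raise ZeroDivisionError("observed gap is zero: share undefined")
    return float(simulated_gap / observed_gap)
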