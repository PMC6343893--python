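# Methods

This note documents the statistical model behind `satregions`, the
calibration of its synthetic-data generator, the numerical choices made
where the design was genuinely open, and what the package's tests do
and do not establish about real survey data.

## The problem

Point-referenced survey outcomes (here: life satisfaction on the 0–10
Likert scale) are far noisier within communities than between them:
the within-community SD of responses is ≈ 1.66 points while community
means vary with an SD of only ≈ 0.22 around a grand mean of ≈ 8.04.
A tract with 50 respondents therefore measures its own mean with an SE
(≈ 0.23) as large as the entire between-community spread. Aggregating
tracts into regions buys precision at the cost of locality — the scale
effect of the modifiable areal unit problem. The package implements
(i) an algorithm that builds candidate regionalizations at any sampling
threshold, (ii) a cross-validation criterion for choosing the
threshold, and (iii) the estimation and comparison machinery applied to
the chosen partition.

## Synthetic geography and responses

The generator (`satregions.synthetic`) emulates the structure of a
national health/social survey linked to census geography.

**Geography.** `n_tracts` centroids on an abstract planar square of
side `area_size` (default 100 units; no lat/lon or projection — the
algorithms only use relative positions). A fraction `urban_fraction`
(default 0.62, matching 776 of 1216 communities urban) scatter
normally (SD `city_spread` = 3) around `n_cities` = 6 city centres with
Zipf-like size shares; the rest are uniform. Sampling strata are the
cities plus a 5×5 grid of rural blocks.

**Communities.** Each stratum's tracts are clustered spatially
(k-means on centroids) into "communities" of ≈ 8 tracts. True
community means combine nested random effects — a stratum effect
(SD `sigma_city` = 0.10) and a community effect (SD `sigma_community` =
0.18) — plus an urban/rural offset splitting the `urban_gap` = 0.17
rural advantage around the grand mean, plus optional covariate slopes.
The implied between-community SD,
√(σ_city² + σ_comm² + Σβ² + gap²·f(1−f)) ≈ 0.22, matches the published
calibration. A continuous spatial covariance was deliberately not
modelled: hard spatial clusters are cheaper and suffice to give the
cross-validation curve its interior optimum; the spatial covariance of
real community means is not published, so any richer choice would be
invented anyway.

The combined effects are centred with sample-count weights, so the
population mean of true community means equals `mu` exactly rather than
wobbling (SD ≈ 0.05) with the handful of stratum-level draws.

**Sampling.** Survey stratification is much coarser than the tract:
each stratum draws one expected per-tract rate, uniform on
`sampling_rate_range` = (10, 110), and allocates its total sample
multinomially over its tracts. This reproduces the key feature that
tract sample sizes vary widely (roughly half below 50) for reasons
unrelated to the tract itself. Survey weights are lognormal with mean
100 and CV 0.5.

**Responses.** The individual response is a latent normal — true
community mean + age-profile deviation + N(0, `sigma_individual` = 1.66)
— rounded to the nearest integer and clipped to 0–10. The bounded
instrument pulls the realized mean toward the scale centre, so the
latent location is shifted by the exact amount (solved from the
discrete category probabilities) that keeps the realized mean at `mu`.
Two consequences are intentional and documented: realized within-tract
SDs (~1.5) sit slightly below the latent 1.66, and configured group
gaps are mildly attenuated (≈ 15%) by the ceiling. Setting
`discretize=False` exposes the latent continuous response, which the
noise-free validation control uses (an all-integer response with zero
noise would collapse to a constant).

**Ages.** Respondents carry one of 13 age bins. Urban strata
over-represent the young and rural strata the old via a linear tilt
(±25% at the extreme bins, near-equal middle shares); the default age
profile of mean outcomes is a U over the life course with a +0.02-point
old-end tilt. Estimated national per-bin means embed the urban penalty
of the young-heavy bins, which amplifies the configured asymmetry
roughly threefold; the tilt is sized so the measured composition-only
share of the urban/rural gap stays at a few percent, the regime the
real data exhibit.

**What the generator does not emulate:** real census geography,
household structure, nonresponse, design-based weighting, item
missingness, or any spatial covariance beyond the cluster structure.
Tests passing on this generator show the *algorithms* behave as
specified under the published variance calibration — not that any
particular real-data number would be reproduced.

## Regionalization algorithm

`regionalize` composes three stages, all deterministic given inputs:

1. **Grid.** Tract centroids are binned into a very coarse grid
   (default cell = a quarter of the larger coordinate extent,
   configurable, with an arbitrary origin offset). Cells are half-open
   so a centroid on a shared edge belongs to the higher cell.
2. **Refine.** Any cell with more observations than the threshold *n*
   is bisected at the midpoint of its longer side — the cut runs
   parallel to the shorter axis, the compactness-preserving reading of
   "bisecting along its shortest axis"; the opposite reading is
   available as `axis_rule="halve-shorter"`. A split is kept only if at
   least one child reaches the threshold; empty children are dropped;
   cells with one distinct position are never split. Termination:
   every kept split either reduces membership or halves the bounding
   box, which eventually separates distinct points.
3. **Merge.** Proto-regions below the threshold are merged, lowest
   count first, each with the proto-region whose member-centroid is
   nearest, until all regions comply (or one region remains, when the
   total sample is below the threshold). Never-split sparse cells are
   merged too — leaving them would break the partition contract. No
   strict edge-contiguity is enforced; the source method itself
   tolerates occasional non-contiguity.

All tie-breaks (equal side lengths, counts, distances) resolve by
lexicographic cell id, making the result invariant to tract input
order. The partition laws — coverage, disjointness, count conservation,
threshold compliance, monotone mean region size — are property-tested
over fuzzed inputs.

## Regional estimates

Regional outcome means are survey-weighted. The weighted SD uses the
unbiased reliability-weight denominator Σw − Σw²/Σw, which reduces to
the classical n−1 sample SD under constant weights of any scale; the SE
divides by √n_eff with the Kish effective sample size (Σw)²/Σw². A
full design-based variance is not attempted — no design information
survives in public aggregates of such surveys. Covariate means weight
tracts by their weight totals; a region is urban when the majority of
its total weight comes from urban tracts. Quintile labels rank regions
by mean outcome with id tie-breaks and sizes within one of each other.

## Scale cross-validation

One sampled tract per region is held out, uniformly at random (regions
with fewer than two sampled tracts are skipped). The held-out tract
mean is regressed on the region's leave-out weighted mean by WLS with
the held-out tract's weight total as observation weight — tract means
are measured with noise inversely related to their sampling. R² is
defined with the weight-centred total sum of squares, which makes it
exactly the squared weighted correlation of prediction and outcome, and
makes maximizing R² equivalent to minimizing weighted mean squared
prediction error when the held-out set is fixed. The curve averages
R² over `n_draws` validation draws × `n_offsets` uniform grid offsets
per threshold (defaults 5 × 4 = 20 repeats); every repeat's randomness
derives from the master seed through fixed-position children, so curves
are reproducible and repeats independent. Pairs are pooled across
regions into a single regression per repeat. Thresholds producing
fewer than three usable pairs are excluded with a warning.

At the default calibration the curve rises from R² ≈ 0.04 at
tract-sized regions (~70 samples) to ≈ 0.22 at a few hundred samples
per region, then falls as regions smooth over community structure —
the interior optimum lands where regions are about community-sized.

**Controls.** With the between-community variance switched off, the
curve's mean R² must show no predictive power; since R² ≥ 0 has a
strictly positive null mean (≈ 1/(n−1), further shifted by the
correlation between pair weights and the heteroskedastic noise of
unevenly sampled tract means), "no power" is asserted against a matched
permutation null — shuffling (outcome, weight) pairs against the
leave-out means — which is distribution-identical under independence.
With idiosyncratic noise switched off instead, prediction error is
pure smoothing bias and mean R² falls monotonically from the community
scale upward. Below the community scale this monotonicity does not
hold for clustered geographies: a one-tract predictor is a coin flip
between same-community (perfect) and neighbouring-community
(independent), a penalty that *shrinks* as regions approach community
size; the control therefore starts its sweep at the community scale.

## Group comparisons

Regions enter comparisons unweighted — communities are the units of
analysis. Group means carry SEs Σ(x−x̄)²/(n(n−1)); the difference SE is
the Welch form √(se_a²+se_b²), which for a two-group mean contrast
coincides with HC-robust regression on a group dummy up to the small-
sample factor of the HC variant. Intervals use ±1.96 (group sizes in
the hundreds make the t correction negligible). Differences are also
normalized by the all-regions SD of the variable. The published
comparison tables shipped in `satregions.reference` are reproduced
exactly by this arithmetic wherever the printed (2-decimal) means are
internally consistent — 8 to 13 of 13 rows per table; the remainder
differ by one unit in the last printed digit because the underlying
means were rounded for display.

## Age-composition counterfactual

Group age mixes are survey-weight shares over the 13 bins; the
counterfactual gap is the difference of mix-weighted national mean
outcomes per bin (rural minus urban), and is reported as a share of the
observed gap. The profile is estimated from the full sample — national
averages, not group-specific ones — so it embeds any group composition
within bins, exactly as in the real-data exercise it mirrors.

## Problem sizes and defaults

The shipped defaults run the full pipeline at 5000 tracts
(≈ 300 000 respondents) with a 7-point threshold sweep spanning mean
regional samples from ≈ 70 to ≈ 11 000 and 20 repeats per threshold;
the end-to-end acceptance computation completes in a couple of minutes
on one CPU. Unit tests use 150–3000-tract maps. These sizes were
chosen so Monte-Carlo standard errors are small relative to the effects
asserted (the interior-optimum peak exceeds the endpoint R² by far more
than 3 MC SEs) while keeping the suite quick to run.

## Known limitations

- Regions are only approximately contiguous; no road-network, water,
  or administrative boundaries inform the algorithm (by design — the
  manual, expert-drawn regionalization it mimics is not reproducible).
- The SE estimator ignores survey design effects beyond unequal
  weights.
- The discretized instrument attenuates configured gaps near the scale
  ceiling; comparisons against configured latent values must allow for
  this (~15% at the default calibration).
- Population-based (rather than sample-based) thresholds are out of
  scope, as is any causal interpretation of the group contrasts.
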