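# Methods

This note documents the statistical procedures implemented in
`flightline`, the defaults and why they were chosen, what the simulator
does and does not emulate, and the numerical decisions a user auditing
results should know about.

## Record definition and inclusion

A *record* is a unique (observer, date, county, species) combination;
individual counts are discarded before any analysis. This neutralises
mass survey events whose large tallies would otherwise dominate the
early-season cumulative curve. Deduplication is idempotent and
order-insensitive; invalid rows (unparseable dates, counties outside
the configured set) are collected into a rejects report, or raise in
strict mode.

Inclusion: a species-year must have ≥ 10 unique (observer, date) pairs
(`min_obs_dates_per_year`); a species must have ≥ 10 such years
(`min_years`). Both thresholds are inclusive. "Unique observer dates"
counts observer × date pairs ignoring county, because the phrase names
observer and date only; counting full record keys instead is available
via `count_unit="records"`, and both counts are stored on every series.
The inclusion rules are evaluated after all spatial and temporal
filters. Migratory species are excluded by an explicit config list —
there is no algorithmic migrancy criterion. Taxon merges (e.g. sibling
*Erynnis* species that observers separate mainly by season) are alias
config data, not code.

Day-of-year is leap-aware (Jan 1 = 1; Dec 31 = 365 or 366): onsets are
dated events on a real calendar, and a fabricated 365-day normalisation
would shift leap-year records after February for no gain.

## Onset estimator

Onset of a species-year with n record days is the smallest observed day
d whose cumulative record count reaches ⌈q·n⌉, q = 0.10 by default. The
estimator is discrete — it returns an observed day, which is how an
onset can be drawn on a histogram of records — and ties on heavy days
are handled by the cumulative count itself. A strictly-greater variant
(count > q·n, differing only when q·n is an integer) is available as
`rule="strict"` for sensitivity analysis, as is any quantile level
(first record = small q, median = 0.5). The 10% level is the default
because the first record is an extreme order statistic with poor
robustness, while the 10% point stabilises quickly with effort.

Properties guaranteed (and property-tested): the onset is an element of
the observed days, monotone non-decreasing in q, and shift-equivariant.

## Spring temperature index

Mean of the March–June monthly mean temperatures within each county,
then the unweighted mean across counties; with complete cells this is
the grand mean of the 12 county × month values. Months are equally
weighted (not day-count weighted) and counties equally weighted (not
area weighted): the index is an interannual *anomaly carrier*, and any
fixed weighting changes it by a constant that the regressions absorb.
Under the strict missing-data policy an absent cell fails loudly with
its (county, year, month) name; the "allow" policy averages available
cells and reports how many months/counties were used.

## Sensitivity regressions and influence screening

Per species and predictor (spring temperature, or calendar year), onset
day is regressed on the predictor by OLS. Cook's distance is computed
from the initial fit in closed form,

    D_i = e_i² / (p·s²) · h_ii / (1 − h_ii)²,   p = 2,

which equals the leave-one-out definition; the tests verify this
against brute-force refits and against an independent library
implementation. Points with D_i > 4/n (n = the *initial* number of
points, per the conventional rule) are removed in a single pass and the
model is refit once. Iterating to convergence is available behind
`iterate=True` but is not the default: the standard procedure is one
exclusion step, and iterated deletion on clean data is increasingly
anticonservative. Screening is a set operation on the initial fit, so
it is invariant to point order.

Mean and SD of onset are computed per predictor on that predictor's
surviving points (config: `moments_on="all"` uses every point). A fit
is reported only when ≥ 5 points survive (`min_points`); below that the
species gets a flagged null result, never a silent omission. With
`remove_outliers=False` the output is exactly the plain OLS fit — the
"outliers included" variant.

Calibration: on clean simulated data the plain fit's 95% slope CI
covers at its nominal rate, and the screened slope estimator is
unbiased (removal is symmetric in the residual sign). The screened
fit's own CI undercovers somewhat (~91% at n = 28 in our simulations):
deleting high-influence points from clean data shrinks the residual
variance estimate. This is a known property of outlier-deletion
inference, not of this implementation; the screen buys robustness to
burst-distorted years at that cost, and the "outliers kept" switch
exists precisely so users can compare.

## Trait meta-models

One row per species: sensitivity slope, voltinism (continuous
generations/year; range midpoints such as 3.5 for "3–4"), overwintering
stage (larva/pupa/adult — no egg-overwintering species in this fauna),
mean onset date, and the onset SD. Weighted least squares with weights
1/SD of onset date down-weights species whose slopes are least precise;
the weight is 1/SD as conventionally *stated* for this analysis, with
the variance-weighted alternative (1/SD²) available via
`weight_rule="inv_var"`. Estimates are invariant to rescaling all
weights by a constant.

The standard model set: voltinism alone; voltinism + mean onset
(additive); voltinism × mean onset (interaction); voltinism ×
overwintering stage; interaction + stage. Overwintering stage is coded
with sum-to-zero contrasts — required for the marginal tests below to
be meaningful, and documented because factor coding changes Type III
results.

Type III (marginal) tests are implemented as drop-term refits: each
term's F compares the full model with the full model minus that term's
columns, on identical weights. For a single-df continuous term this
equals t². Nested models are compared by the extra-sum-of-squares F
test; non-nested or identical pairs are rejected with an explicit
error. With few species the voltinism × stage design can be rank
deficient (a stage level observed at a single voltinism); the pipeline
flags and skips such models rather than aborting the run.

## Taxonomic variance components

Nested random intercepts (family, subfamily-in-family,
genus-in-subfamily; species as residual) estimated by REML with
components constrained non-negative, reported as percentages of total
(summing to 100). When (nearly) every genus holds one species — the
realistic situation for a 38-species, 33-genus assemblage — the genus
component is confounded with the residual, so the decomposition also
reports their sum ("genus or below"), which remains identifiable.
Singular fits (e.g. exactly one species per genus everywhere) are
returned flagged, with all variance in the residual, rather than
raising mid-pipeline. The nested-random-intercepts structure is one
defensible formalisation of "variance attributable to taxonomic level";
a phylogenetic regression with branch lengths is out of scope.

On balanced nested designs with interior estimates, REML coincides with
the classical expected-mean-squares ANOVA estimators; the tests use
that identity as an independent oracle, plus simulation recovery.
One caveat found while validating: the *mean of per-replicate
percentage estimates* is a ratio of noisy variance estimates and
carries a Jensen-type bias (several points for the family share at
realistic sizes) that no number of replicates removes. Recovery is
therefore assessed on the components themselves, with shares computed
from the averaged components.

## The simulator

`flightline.synth` emulates the structure of an opportunistic archive:

- **Spring temperature**: annual index ~ Normal(17.9 °C, 0.8 °C), no
  secular trend by default (the study region's winters/springs show
  interannual variation without a consistent warming trend); monthly
  county cells are the index plus fixed month/county offsets and
  bounded (±0.1 °C) uniform noise, so the pipeline's computed index
  recovers the drawn truth to the noise bound.
- **Species truth**: mean onset μₛ ~ U(70, 200) days (the range seen in
  regional onset tables); sensitivity βₛ = γ₀ + γ_volt·v + γ_onset·(μₛ−c)
  + γ_v×o·v·(μₛ−c) + taxonomic effects + noise, with defaults
  γ₀ = −4.7 days/°C (a realistic median), γ_v×o = −0.045 (late-emerging
  multivoltine species most sensitive), noise SD 3, taxonomic SDs
  (0.5, 0.5, 1.5) over a 5-family / 9-subfamily / 33-genus hierarchy.
- **True onsets**: onsetₛ,ᵧ = μₛ + βₛ·(Tᵧ − T̄) exactly, recorded in
  `GroundTruth`.
- **Records**: per species-year, Poisson(λₛ) sightings (λₛ ~ U(25, 60),
  matching ~30 records/species-year in a comparable archive) with days
  drawn from a right-skewed lognormal flight curve anchored so its 10th
  percentile equals the true onset — the simulated estimand matches the
  estimator; a symmetric curve (`flight_curve="normal"`) exposes the
  estimator's bias when that anchoring fails. Reports are thinned by a
  daily reporting probability with a weekend boost and mild seasonal
  ramp, assigned to a Zipf-skewed observer pool and uniform counties,
  and then inflated with exact duplicate rows (rate 0.3) to exercise
  deduplication. The unique-key count before duplicate injection is
  stored so dedup can be checked exactly.
- **Survey bursts**: with probability 0.08 per species-year (of the
  order of the omitted-outlier rate in comparable analyses), a burst of
  12 distinct observers reports on one day ~35 days before the true
  onset, planting exactly the artefact the Cook's screen targets.
- **Traits**: voltinism from {1, 2, 3, 3.5, 4}; overwintering stage
  follows the onset tercile (adult-early / pupa-mid / larva-late) with
  probability 0.7, uniform otherwise, emulating the stage–onset
  confounding that motivates preferring mean onset over stage.

Randomness is one root seed split into independent substreams (climate,
species, records, outliers), so the same seed gives byte-identical CSVs
and changing e.g. the outlier model leaves the climate draws untouched.

Not emulated: within-county space, species interactions, detection or
misidentification error, observer turnover, and real flight-curve
multimodality (multivoltine species have one simulated emergence pulse
per year). Passing tests therefore demonstrate correctness of the
statistical chain under a structurally realistic but simplified effort
model — not that any particular real archive satisfies the model.

## Problem sizes and numerical choices

- Monte-Carlo validations simulate at the *onset* level (onset = μ +
  β·(T−T̄) + N(0, 5 days), 38 species × 28 years) for the repetition
  counts — 1,000 reps for slope recovery, 500 for meta-model error
  rates and variance components; record-level generation is exercised
  end-to-end separately (smaller simulations in the test suite, the
  full default study in `scripts/acceptance.py`). Onset noise of 5 days
  reflects the empirical onset error the simulator produces at default
  effort.
- Ties and degenerate inputs: constant predictor, < 3 points, leverage
  = 1, zero/negative weights, rank-deficient designs, inconsistent
  taxonomy, duplicate climate cells and duplicate species-year onsets
  all raise named errors rather than propagating NaNs.
- The meta-model power check plants γ_v×o = −0.08 (a large effect ~
  twice the default) for the >80%-power claim; the type-I check sets
  all trait effects to zero.
- Tolerances: exact-arithmetic oracles (normal equations, leave-one-out
  Cook's) are checked to 1e-8–1e-10 relative; Monte-Carlo quantities to
  3 standard errors of the mean.

## Known limitations

- The onset estimator is consistent for the flight curve's 10th
  percentile only when effort is stationary within the season; the
  seasonal effort ramp in the simulator induces a small early bias that
  the sensitivity regressions absorb into the intercept.
- Influence screening assumes at most a few contaminated years; heavy
  contamination (many burst years) degrades both the screen and the
  refit.
- The 1/SD weighting treats the onset SD as a precision proxy; it is
  not the slope's sampling SE, and species with few years are not
  additionally down-weighted.
- Variance-component estimates at 38 species / 5 families are
  inevitably noisy; single-study shares should be read qualitatively
  (the confounded "genus or below" sum is the robust quantity).
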