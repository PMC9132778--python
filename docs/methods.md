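# Methods

This package implements the analysis pipeline for global surveys built on
the WHO Hand Hygiene Self-Assessment Framework (HHSAF): instrument scoring,
selection of unique facility responses, representativeness weighting,
weighted estimation of implementation levels and their drivers, and paired
comparison of survey waves.  Because the survey microdata are not publicly
shared, the package ships a synthetic-data generator with known ground
truth; all statistical claims made by the test suite are claims about
recovery of that configured truth.

## The instrument and its scoring

The HHSAF is a facility self-assessment of 27 indicators grouped into the
five elements of the WHO Multimodal Hand Hygiene Improvement Strategy:
System Change, Training and Education, Evaluation and Feedback, Reminders
in the Workplace, and Institutional Safety Climate.  Each indicator's
maximum option is worth 10–50 points, each element exactly 100 points, the
whole instrument 500.  The total maps onto four implementation levels:
inadequate (0–125), basic (126–250), intermediate (251–375) and advanced
(376–500) — closed integer bands partitioning [0, 500].

The bundled instrument file (`hhsaf/data/hhsaf_structure.yaml`) encodes the
*structure* of the 2010 WHO tool; question wording and option labels are
paraphrases written for this package, not a verbatim reproduction of the
WHO questionnaire.  Analyses that depend only on structure (score ranges,
element caps, level bands) are unaffected; anyone holding the official tool
can supply it as a drop-in YAML and the loader will validate it against the
same structural invariants.

Scoring rules:

* An element is scored only when **all** of its indicators are answered;
  a partially answered element is *missing*, never zero.  (The selection
  step below keys on element completeness, which presupposes that partial
  elements are not scored.)
* The total score and level exist only when all five elements are complete.
* All scores are integers; there are no fractional points anywhere in the
  instrument, so no rounding is ever needed at the scoring stage.

## Selection of analysis responses

Participation is on an individual basis, so the raw response table is
filtered in three steps:

1. **Element completeness** — keep responses with at least one fully
   completed element.
2. **Deduplication** — facilities submitting several responses are found by
   single-linkage agglomerative clustering *within country* (country is a
   hard blocking key): two responses link when their haversine distance
   (Earth radius 6371 km) is ≤ `radius_km` (default 0.5 km) **and** their
   facility-name token-set similarity is ≥ `name_threshold` (default 0.6,
   computed on case-folded, punctuation-stripped strings).  Clusters are
   connected components, so the partition is independent of row order.  One
   representative per cluster is retained, ranked by: most complete
   elements, most answered indicators, latest submission, smallest response
   id.  Responses without coordinates become singletons with a warning
   rather than being dropped.
3. **Per-capita ventile** — for each responding country compute
   responses per 100 000 inhabitants; pool the ratio over *responses* (each
   response carries its country's ratio) and take the lower empirical
   quantile at index ⌈0.05 n⌉ − 1 as the cutoff.  Whole countries with
   ratio strictly below the cutoff are excluded; ties at the cutoff are
   retained.  The response-level convention keeps the excluded share at or
   just below 5% of responses regardless of how unequal country sizes are;
   a country-level ventile would not.

The same distance + name-similarity constraints drive one-to-one matching
of facilities across two survey waves, assigned greedily by increasing
distance with each facility used at most once.

## Post-stratification weighting

Weights are raked (iterative proportional fitting) to target margins for
country, World Bank income level, WHO region, facility level and facility
type.  The IPF loop cycles over margins, multiplying weights so each
variable's weighted category shares equal its targets, and stops when the
largest absolute margin error is below `tol` (default 1e-6) or errors out
after `max_iter` (default 100) cycles, reporting the last error vector.
Weights are normalised to sum to the sample size.

Numerical choices:

* Countries observed fewer than `min_country_count` (default 2) times are
  pooled into one category before the country margin is applied; with ~90
  country categories, one-response cells make IPF fragile.
* Target categories never observed in the sample are unreachable; they are
  dropped and the remaining targets renormalised.  This matters because
  income level and WHO region are deterministic functions of country: after
  the ventile exclusion, registry-wide targets would be structurally
  inconsistent with the country margin and IPF would oscillate instead of
  converging.  Margins should therefore be built for the analysis
  population (the retained countries), which is what the synthetic
  workflow does.
* A margin category observed in the sample but carrying zero target, or a
  positive target with an empty cell, is a structural error, raised as
  such rather than silently absorbed.
* No weight trimming is applied by default.

Weight diagnostics report the effective sample size `(Σw)²/Σw²`, the
coefficient of variation, and the weight range.

## Estimation

**Weighted quantiles.**  All reported medians and IQRs are weighted.  The
estimator is the cumulative-weight step function: the q-quantile is the
smallest value whose cumulative normalised weight reaches q, with the
midpoint of the straddling values when the cumulative weight hits q
exactly.  With equal weights this reproduces the ordinary sample quantile
of the same convention; it is used consistently for medians and quartiles.
Element summaries use every response with that element complete; total
score summaries use fully complete surveys only.

**Level distribution.**  Weighted counts per level are rounded half-even
for display; proportions are computed on unrounded weights and sum to 1.

**Drivers of the total score.**  A linear (identity-link) generalised
estimating equation with country clusters estimates the association between
the total score and income level, WHO region, nationally coordinated data
collection, facility level and facility type, with reference categories
high income, Africa, no coordination, primary and public.  The working
correlation defaults to exchangeable (countries plausibly induce
within-cluster correlation); independence is available.  Post-stratification
weights enter the estimating equations.  Inference uses a cluster-robust
sandwich covariance; for unweighted fits the default is the Mancl–DeRouen
bias-reduced sandwich, because with ~90 clusters the uncorrected sandwich
is anti-conservative for country-level covariates (a 50-replicate
experiment in the test suite measures ~82% coverage uncorrected versus ~96%
bias-reduced for a nominal 95% interval).  The bias-reduced form is not
defined for weighted estimating equations, so weighted fits report the
plain robust sandwich.  With singleton clusters, independence correlation
and unit weights the point estimates reduce exactly to ordinary least
squares, which the suite checks against directly solved normal equations.

**Model adequacy.**  A Box-Cox profile log-likelihood over λ ∈ [−2, 2]
(step 0.01, Jacobian term included, outcome shifted by `1 − min(y)` when
non-positive) checks the linear specification: the fit is flagged adequate
when λ = 1 lies within the 95% profile-likelihood interval (log-likelihood
within 1.92 of the maximum).

**Paired wave comparison.**  Facilities matched across waves are compared
on the *median of paired differences* (not the difference of medians —
the two are not equal) with a two-sided Wilcoxon signed-rank test:
zero differences are dropped (classical procedure; the data are integer
scores so exact zeros occur), midranks handle ties, and the null
distribution is exact up to 25 non-zero pairs (dynamic programming over the
doubled midranks, whose distribution is symmetric) with a
continuity-corrected normal approximation beyond.  Strata with no pairs, or
with all-zero differences, are reported as not applicable rather than
tested.  Significance is read at two-sided p < 0.05 with no multiplicity
adjustment, mirroring standard practice for these surveys.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

* ~96 countries cycled over the six WHO regions, income levels drawn with
  probabilities 0.15 / 0.25 / 0.30 / 0.30 (low to high); log-normal
  populations (median ≈ 10 M) and log-normal per-country response counts,
  independent of population — which naturally produces the wide
  responses-per-capita range with a thin lower ventile seen in global
  convenience samples; ~3500 responses by default.
* Facility type and level drawn with the observed global mix (75.6% public,
  20.6% private; 39.1% primary, 28.1% secondary, 22.6% tertiary).
* Each facility has a latent quality `f ∈ [0, 1]`.  Its mean is
  `(baseline + effects) / 500` with baseline 380 points and default
  additive effects calibrated to the published regression pattern: income
  0 / −20 / −76 / −138 (high to low), facility type +80 private and +62
  other versus public, level −33 secondary / 0 tertiary / +13 other.
  Facility-level noise (default sd 50 points) is a **symmetrically
  truncated** Gaussian (truncated at the distance to the nearer boundary,
  capped at 3 sd), so stratum means stay exactly linear in the configured
  effects even near the 500-point ceiling — a clipped Gaussian would bias
  high-scoring strata downward and invalidate parameter-recovery truth.
* Answers are drawn per indicator from the two options straddling
  `f × max_points`, with probabilities making the expected points exactly
  equal the target; hence E[total | f] = 500 f exactly.
* Duplicates: a facility submits extra responses with probability 0.12
  (1 + Geometric(½) submissions), jittered isotropically with sd 0.2 km
  truncated at twice that, and occasionally under a name variant (case
  change, dropped or appended token).
* ~5% of responses are partial, keeping 1–4 complete elements.
* Two waves share a configurable number of facilities (default 190) at
  unchanged true locations, with configurable per-facility score drift.
* Participation defaults to a census of the registry; per-income and
  per-type participation rates can be lowered to create the differential
  non-response that makes raking do non-trivial work (the pipeline tests
  do this and verify that underrepresented strata are upweighted).

What the generator does **not** emulate: answer-level dependence between
indicators beyond the shared latent quality, social-desirability bias,
geocoding error beyond isotropic jitter, non-ignorable missingness (which
elements are incomplete is random), and real-world name messiness
(abbreviations, transliteration).  Passing recovery tests therefore show
the estimators are correct under the stated model, not that the original
survey's convenience sample was unbiased.

## Problem sizes used in the checks

The acceptance suite runs the GEE recovery experiment at 50 replicates of
~2000 responses over 90 countries, the deduplication recovery on one
default-scale dataset (~3500 responses), and the wave-matching recovery at
the default 190-facility overlap; the published-arithmetic checks
(3372 → 3206 selection, 500-point maximum, level-band boundaries, coverage
percentages) are exact and instantaneous.  The Box-Cox calibration check
uses 200 replicates of n = 120 because at 50 replicates the Monte-Carlo
noise of a ~94%-coverage interval makes a ≥ 90% assertion unreliable.

## Known limitations

* The bundled instrument is a structural stand-in; per-indicator point
  values of the official tool are not reproduced.
* Raking offers no GREG/entropy-balancing alternatives and no design-based
  variance estimation; downstream analyses treat weights as fixed.
* The GEE assumes a linear mean in categorical covariates; interactions are
  not modelled (none are in the reference analysis).
* Exact signed-rank inference is capped at 25 non-zero pairs; beyond that
  the continuity-corrected normal approximation is used.
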