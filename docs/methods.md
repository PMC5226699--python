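# Methods

## Design and estimand

`heatscan` estimates how the short-term association between daily mean
humidex and mortality differs between areas of a city, using a
time-stratified case-crossover design. The unit of inference is the matched
set (stratum) of one decedent: the death date plus all other same-weekday
dates in the same month and year (3–4 controls; the case day itself is
excluded from the referent list, the standard bidirectional convention — an
`include_case` flag provides the unidirectional variant). Conditioning on
the stratum removes all personal covariates and any exposure term constant
within a month-weekday cell; what remains identifiable is the slope of
log-odds of death in daily mean humidex, reported as an odds ratio (OR) per
1 °C.

The analytic set is restricted to strata that touch at least one "extremely
hot day": a day whose mean air temperature is at or above a high empirical
quantile (default 99.9th percentile, linear-interpolation definition,
configurable) of the *entire* daily series. This yields two death groups —
deaths on extreme days, and deaths on cooler days that have an extreme day
as a control — which the group summary tabulates separately (Welch t-tests,
α = 0.05).

## Exposure metrics

The humidex is `H = Ta + 0.5555·(e − 10)` with
`e = 6.11·exp(5417.7530·(1/273.16 − 1/T_dew[K]))` hPa. Dew points are
accepted in °C and converted internally. The adjustment is negative in dry
air and is not clipped, so `H ≥ Ta` exactly when `e ≥ 10` hPa (dew point
≈ 7 °C); this identity anchors the closed-form tests. Daily aggregation
averages hourly humidex values (a flag computes humidex from daily-mean
inputs instead) and drops days with fewer than 18 of 24 hours (configurable;
the count is logged). Hours with dew point > air temperature + 0.5 °C are
flagged as sensor noise but retained.

## Conditional logistic regression

The solver maximises the exact 1:M conditional likelihood by Newton–Raphson
with the analytic score (case covariates minus within-stratum softmax means)
and observed information (sum of within-stratum softmax covariances),
step-halving on any likelihood decrease, convergence at max |score| < 1e-8,
and a 50-iteration cap. The covariance is the inverse observed information
at the optimum. Strata without within-stratum covariate variation contribute
only constants; they are counted out of `n_informative_strata`, and a fit
with none is an error. Complete separation is detected two ways: diverging
coefficients during iteration, and a numerically vanishing score at
|β| > 15 (a flat plateau whose true optimum is at infinity); both flag
non-convergence rather than raising. Exactly one case per stratum is
enforced, so no tie-breaking method (Breslow/Efron) is needed.

The split-scan interaction model has two estimable slopes, `β_below` on
`H·(1−A)` and `β_above` on `H·A`, where `A` indicates residence at/above the
split. Since `A` is constant within a stratum, the joint conditional
likelihood factorises block-diagonally over the two decedent groups; the
scan therefore fits each side as an independent single-slope model, which is
algebraically identical to the joint fit (asserted numerically in the tests)
and degrades gracefully when a side is empty. Warm-starting each side from
the previous split's solution roughly halves Newton iterations across the
grid.

## Split scan and cut-point rule

Splits: 100 values from the 1st to the 99th percentile of the decedent-level
variable, equally spaced in *value*, so skewed variables concentrate most
splits in their sparse tail — deliberate, as the grid is meant to probe the
variable's range rather than its mass. Separation at a split means the
above-split 95% CI lies strictly above the below-split CI with the
above-split OR larger; the cut point is the first (smallest) separating
split, with no persistence requirement by default (a `persistence` window is
available). If nothing separates, the largest CI gap with the correct
direction is reported as `max_separation`; a protective direction yields
`none`. The post-cut slope is unweighted least squares of the OR (not
log-OR; a flag switches) on split value over converged splits at/after the
cut, undefined below 3 points. Non-converged or empty-side splits are
skipped by the search but retained in outputs, and the full CI-gap profile
is serialised so max-separation claims are auditable.

No multiplicity correction is applied across the 100 splits or across
variables — the scan is exploratory by design. The cost is quantified
rather than corrected: under the null (equal slopes), the scan-wide
probability of a false full separation is ~10% under default conditions
(200-replicate simulation in the acceptance tests) against a 5% per-split
nominal level, while per-split CI coverage stays at ~95%.

**Known limitation — the first-separation cut is left-biased.** At a split
k steps below a true threshold θ, the above-split group is the elevated-risk
group plus only the thin slice of decedents in [split, θ); the fitted
above-split slope is an information-weighted mixture that decays by only
~Δβ·n_slice/n_above per step. With any smooth unimodal exposure distribution
(one grid step ≈ 1–3% of the sample), the expected CI gap is still positive
several steps below θ, so the *first* separation fires systematically below
the generating threshold — in the default recovery simulation (n = 2000,
true ORs 1.10/1.03, θ at the 70th percentile), declared cuts land a median
of ~11 grid steps low, even though the above-split CI at θ itself covers the
true OR at its nominal ~95% rate. Users who need an unbiased threshold
location should read the cut as a conservative *outer* boundary of the
high-risk area, or inspect the full OR curve and gap profile; the binned
variant (20/10/5/2% rank bins) provides a complementary low-resolution view
whose thin bins are power-limited and flagged as such.

## Composite index

Each chosen variable is reclassified onto a hinged percentile scale: values
below its cut point are ranked within the below-cut subset into 100
equal-count bins mapped to (0, 50], and values at/above the cut likewise to
(50, 100]; ties share their average rank's bin. A bin width of 0.5% of the
*whole* sample can hold on both sides simultaneously only when the cut sits
at the median, so bins are defined per side (each bin is 0.5% of that side's
data), which reproduces the 0–50/50–100 ranges for any cut position; a
whole-sample-percentile alternative sits behind a flag.
Reclassification operates on decedent-level values — the statistical unit of
this package — not map pixels. The composite is the elementwise mean of the
two reclassified variables and is rescanned with the same grid/cut
machinery. Default cut points for the canonical pair (mapped maximum
humidex 34.4 °C, labor nonparticipation 60%) are configuration defaults
only.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes:

* **Weather** — a full-year daily series over 17 years (1998 start). Daily
  mean air temperature follows a sinusoidal annual cycle with July–August
  bulk N(18, 2) °C; summer days draw with probability 0.015 from a hot
  component N(23.5, 1.5). Over ~6200 days the 99.9th-percentile threshold
  lands near 24 °C with ~6–7 exceedances — the full-series geometry that
  a summer-only sample cannot reproduce (a 1054-day series has only ~2 days
  at/above its own 99.9th percentile). Daily mean humidex adds a
  non-negative humidity offset (mean 1.5, sd 1 °C); the daily maximum adds a
  further positive offset (mean 5.5, sd 1.5 °C).
* **Spatial variables** — independent draws by default (a Gaussian-copula
  correlation is available). The scanned exposure variable defaults to
  28 + LogNormal(ln 4, 0.9) °C: right-skewed like mapped exposure and
  density surfaces, with 70th percentile 34.41 °C so the canonical 34.4 °C
  threshold is the default θ. The social variable defaults to N(37, 14)%
  clipped to [0, 100], a realistic range for a census labor
  nonparticipation rate.
* **Death days** — each decedent is assigned a summer stratum containing an
  extreme day (a configurable share goes to non-qualifying strata) and dies
  on day d with probability ∝ exp(β_A·H_d) within the stratum, where
  A = 1{scan value ≥ θ}. This *is* the conditional-logistic kernel, so the
  estimator is consistent for (β_below, β_above) by construction — orders of
  magnitude cheaper than person-day Bernoulli thinning and equivalent under
  the matched-set likelihood. Place of death is out-of-hospital with
  probability 0.258, split care-facility:home ≈ 160:97.

All randomness derives from `SeedSequence((seed, stream))` with fixed stream
ids per stage; regeneration from (config, seed) is bit-identical. Truth
(θ, both slopes, group labels, qualifying-stratum labels) is stored apart
from the data tables.

What the generator does **not** emulate: spatial autocorrelation and
contiguity of exposure surfaces, correlated measurement error between
variables, seasonal confounding beyond the stratum structure, and
demographic dependence of risk (age/sex are decorative). Passing tests
therefore certify the statistical machinery under correct model
specification, not robustness to the misclassification and clustering of
real administrative data.

## Numerical and design choices

* Quantile definition: linear interpolation between order statistics
  (configurable), both for extreme-day thresholds and the 1st/99th
  percentile grid anchors.
* ICD-10 filtering compares the three-character root lexicographically
  (transport accidents V01–V99 inclusive); sub-codes inherit the root's
  fate; codes without a leading letter are flagged and retained.
* Out-of-hospital = place of death ∈ {home, care_facility, other}; records
  with unknown place (the field did not exist before 2008) are excluded from
  that subset.
* Control days lacking weather coverage are dropped from their stratum
  (logged); a case day without weather drops the record (counted).
* Simulation sizes in the test suite: 200 replicates at n = 2000 for
  recovery and null calibration, 50 oracle instances for the solver, one
  997-decedent preset for end-to-end determinism. These match the scale at
  which the calibration claims above are stated.
* The run report accounts for every input record exactly once: included,
  excluded-by-ICD, excluded-by-restriction, excluded-no-weather, or
  excluded-no-qualifying-stratum.

## Known limitations

Beyond the left bias of the first-separation rule discussed above: the scan
assumes a single reference station (no network interpolation); boundaries
are crisp (no moving windows or fuzzy membership); the composite index
weights its two components equally with no data-driven weighting; and the
uncorrected 100-split multiplicity means isolated full separations under
null-like variables should be expected at the ~10% scan-wide rate quantified
in the acceptance tests.
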