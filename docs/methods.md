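# Methods

## Setting and notation

Two probability samples from the same adult population: a **donor**
survey with measured *and* self-reported height/weight (plus
demographics and design weights) and a much larger **recipient** survey
with self-reported values only, plus a state code.  Write
`BMI = w / (h/100)²` (kg/m², h in cm, w in kg), and for a weighted
sample let `F̂(x) = Σᵢ wᵢ 1[xᵢ ≤ x] / Σᵢ wᵢ` be its weighted ECDF.
Percentile ranks use the midrank convention
`r(x) = (W_below + ½·W_at) / W_total`; quantiles are the
left-continuous inverse of `F̂`.  Prevalence at cutoff `c` is
`Σ wᵢ 1[BMIᵢ ≥ c] / Σ wᵢ` (the boundary counts as positive), with
normal-approximation CIs on the Kish effective sample size
`n_eff = (Σw)²/Σw²`; a Taylor-linearized stratified-cluster variance is
used when stratum/PSU labels are supplied.

## The matching correction

Within a demographic subgroup g (sex × 5-year age band ×
race/ethnicity × income band), each recipient record's self-reported
BMI rank `r` is computed against the *recipient* survey's weighted
distribution in g, and each donor's against the *donor* pool in g.
Matching a recipient at rank `r` to a donor near rank `r` and imputing
that donor's measured pair is therefore an equipercentile transform
from the recipient's self-report scale onto the donor's measured scale:
it reproduces the donor pool's weighted measured-BMI distribution
(marginal preservation) while recipient-side covariates — notably
state — ride along untouched.

Concretely, per recipient and iteration:

1. **Dynamic subgroups.** If the donor pool in g has fewer than
   `n_min(g)` records, g is coarsened: income → "any", then
   race/ethnicity → "any", then the age band widens one adjacent band
   per side until the full 18–80+ range; sex never collapses.  If the
   sex-level pool is still too small it is used as-is with a warning.
2. **Bandwidth expansion.** Eligibility starts at an exact rank tie and
   the tolerance grows in steps of 0.005 (half a percentile point)
   until ≥ 1 donor's rank lies within ± bandwidth; the match is drawn
   from eligible donors with probability proportional to donor sample
   weight.
3. **Jitter.** The matched donor's measured height and weight are each
   perturbed by an independent multiplicative Uniform(−1%, +1%) draw,
   smoothing the imputed distribution between donor atoms.

The per-record corrected BMI is the mean over `K = 100` iterations.
Per-record randomness is seeded from (master seed, hash of record id),
so results are bit-reproducible and independent of row order.

**Matching variable.** By default the rank is that of self-reported
BMI (`match_on="bmi"`), and the *pair* (height, weight) of the matched
donor is imputed, so imputed height–weight covariance is the donor's
conditional covariance.  A joint variant (`match_on="height_weight"`)
matches on the (height-rank, weight-rank) pair with a Chebyshev box.
We default to the scalar match because the joint variant's
nearest-donor geometry on the 2-d rank square cannot cover the square
at finite pool sizes and measurably contracts the imputed BMI marginal
toward the dense diagonal (≈ 0.5–0.9 points of severe-obesity
prevalence at pools of 50–200 donors in our experiments, versus ≤ 0.05
points for the scalar match) — a direct violation of the marginal
preservation the method exists to provide.

**Averaging.** Averaging K iterations trades marginal fidelity for
stability: as K grows the per-record value approaches the conditional
mean of measured BMI given the self-report rank, which slightly
compresses the extreme tails (the same mechanism, far weaker, that
makes regression corrections understate severe obesity).  At K = 100
and calibrated thresholds the measured compression is ≈ 0.1–0.3
prevalence points at BMI ≥ 35; it is visible in the corrected-vs-donor
KS distance but does not approach significance at the sample sizes
used.

**Threshold calibration.** `n_min` defaults to 50 donors and may be a
sex/age-specific map.  `grid_search_thresholds` evaluates a candidate
grid (default {25, 50, 100, 200}; extendable upward for large donor
pools) by running the correction at a reduced iteration count and
scoring the weighted KS distance between corrected and donor measured
BMI within each sex × age cell; it reports per-cell selections, the
max-distance objective, and its global argmin (ties toward the smaller
threshold, which preserves subgroup specificity).  The evaluation
workflow calibrates once on a dedicated draw and freezes the selected
map — tight subgroups win on within-cell fidelity, large pools on
national tail fidelity, and the grid search is the instrument that sets
that balance empirically rather than by fiat.

**Hawaii rule.** For recipients in the configured state (default
`HI`) whose race/ethnicity is a non-Black minority (Hispanic or
Other), the race dimension becomes "any except NH-Black": the pooled
"Other" category conflates distinct populations there, and matching
across all non-Black races avoids biasing the imputed distribution.
The exact minority set is configurable since reasonable definitions
differ.

## Comparator corrections

* **Individual-level regression**: per sex stratum, weighted least
  squares of measured on self-reported values,
  `measured = b₀ + b₁·self + b₂·self²`, fitted separately for height
  and weight on the donor; recipients receive the *point prediction*
  (a residual-draw variant exists for sensitivity analysis).  Point
  prediction discards the conditional spread, so the corrected
  distribution is compressed toward its conditional mean: mean BMI is
  recovered almost exactly while tail prevalence (BMI ≥ 35) is
  understated.
* **Aggregate alignment**: within sex × age-band strata, every
  recipient BMI is scaled by (donor stratum weighted mean / recipient
  stratum weighted mean) — mean alignment is exact by construction; a
  shift variant is provided since the original aggregate method's
  functional form is not fully specified.

## Validation machinery

χ² comparisons of two prevalences use the Pearson statistic on the 2×2
table of *effective* counts `p·n_eff` (df = 1) — a conservative,
simple design adjustment; Rao–Scott-type corrections are out of scope.
Two-sample KS tests run on weighted ECDFs with the asymptotic
Kolmogorov p-value at `√(n_e)·D`, `n_e = n_eff,a·n_eff,b/(n_eff,a +
n_eff,b)`.  Under integer replication weights both reduce exactly to
their unweighted textbook forms (tested against scipy).  Report
builders produce method × stratum × cutoff prevalence tables with χ²
columns, per-cell KS tables, and per-state prevalence tables (map-ready
CSV).

## The synthetic population

The generator emulates the two-survey structure with a known ground
truth so every claim is testable without restricted microdata:

* demographics from configurable marginals (defaults approximate the
  US adult distribution);
* true height normal within sex (175.3/161.8 cm means, ≈ 7 cm SD) with
  small race and age effects; true weight lognormal around a log-linear
  height relation calibrated so median BMI ≈ 27.7, log-SD 0.21 —
  national true obesity ≈ 37%, severe obesity ≈ 15%;
* per-state additive shifts on log weight (range ≈ −0.04…+0.05),
  giving state obesity prevalences spanning roughly 15 points;
* self-report bias: height over-reported +1 cm (SD 2.5 cm both sexes);
  weight under-reported (means −1 kg women, −0.3 kg men) with the
  under-report growing at 0.15 kg per kg above the sex mean weight and
  heteroscedastic noise (SD 6 kg at the mean weight, scaling with
  weight).  The mean biases are the documented ≈1 kg / ≈1 cm figures;
  the slope and noise magnitudes were calibrated once against the
  published national contrasts (self-report hides ≈ 4–5 points of
  obesity and ≈ 3 points of severe obesity; individual-level regression
  correction still understates severe obesity by ≈ 1 point) and then
  frozen;
* sample weights: lognormal (σ = 0.5, Kish n_eff/n ≈ 0.78), raked to
  the population margins (sex × age joint, race, income; 3 IPF rounds)
  the way production survey weights are calibrated to census control
  totals.  Without raking, the two surveys' weighted compositions
  disagree by sampling noise that real calibrated surveys do not
  exhibit.

What the generator does **not** emulate: complex design strata/PSUs
(only unequal weights), digit heaping in self-reports (flag available,
off by default), secular trends across pooled donor cycles, and any
regional variation in *bias* (state effects shift true weight, not the
misreporting model).  Passing tests therefore demonstrate the
correction's behavior under subgroup-structured bias and unequal
calibrated weights — not robustness to design clustering or
region-varying bias.

## Numerical choices and degenerate inputs

Plausibility bounds [122, 241] cm and [30, 295] kg reject only
data-entry impossibilities at load (overridable).  The top-coded age
band "80+" maps to 80.0 years.  Bandwidths round *up* to the step
schedule with a 10⁻¹² tolerance so exact rank ties match at bandwidth
zero.  Ties in weighted quantiles resolve to the smallest qualifying
value; the midrank convention keeps ranks symmetric under reflection.
Empty pools, empty strata, unmapped crosswalk codes, and datasets
emptied by exclusions raise typed errors rather than propagating NaNs.
Evaluation runs in this repository use a 50,000-record recipient (the
full telephone survey is ≈ 8× larger) and 100 iterations; all reported
quantities are computed at those sizes.

## Known limitations

* Matching quality degrades when the donor lacks coverage of a
  recipient subgroup; loosening guarantees termination, not local
  fidelity (the audit columns `final_loosen_level`/`final_bandwidth`
  flag affected records).
* Iteration-averaging slightly compresses extreme tails (see above);
  per-iteration output is available (`keep_iterations`) when exact
  marginal draws are needed.
* CIs for corrected prevalences ignore the imputation uncertainty of
  the matching step itself (they condition on the corrected values);
  replicate-weight variance estimation is not implemented.
* The χ²/KS design adjustments via Kish effective size are
  conservative approximations, not full design-based tests.
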