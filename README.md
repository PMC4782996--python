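# bmimatch

Bias correction of self-reported height and weight in population surveys
by survey-weighted percentile-rank **statistical matching**, with the two
standard regression-based corrections as comparators and a full
validation suite.

## The problem

Large surveillance surveys (telephone surveys such as BRFSS) collect
*self-reported* height and weight from hundreds of thousands of adults
and are the basis of state-level obesity prevalence estimates.
Self-report is biased: on average women under-report their weight by
about 1 kg and adults over-report their height by about 1 cm, and the
under-report grows with weight.  Because BMI = weight/height², both
errors push BMI down, so obesity prevalence (BMI ≥ 30 kg/m²) and
especially severe obesity (BMI ≥ 35) are substantially understated.
Smaller examination surveys (NHANES-like) measure height and weight
directly — but are far too small for yearly state-level estimates.

`bmimatch` fuses the two: every respondent of the large *recipient*
survey is matched to a respondent of the small *donor* survey (who has
**both** self-reported and measured values) and receives the donor's
measured height–weight pair.  Matching is *equipercentile*: within
demographic subgroups (sex × 5-year age band × race/ethnicity ×
household income) a recipient at the *p*-th survey-weighted percentile
of self-reported BMI is matched to a donor near the *p*-th percentile of
the donor subgroup.  Because each survey's percentile ranks are computed
against its own weighted distribution, the imputation reproduces the
donor's *measured* BMI distribution (marginal preservation) while
retaining the recipient's state-level variation — unlike regression
corrections, which estimate a conditional mean and therefore compress
the BMI tails and understate severe obesity.

The algorithm (per recipient record, repeated for `K` iterations):

1. find the donor subgroup pool; if it has fewer than `n_min` donors,
   coarsen the subgroup stepwise (collapse income, then race/ethnicity,
   then widen the age band one band per side; sex never collapses);
2. expand the percentile-matching bandwidth from 0 in steps of 0.5
   percentile points until at least one donor's rank lies within it,
   then draw one eligible donor with probability proportional to its
   sample weight;
3. impute the donor's measured values with up to ±1% multiplicative
   jitter, and record the implied BMI.

The corrected BMI is the mean of the `K = 100` per-iteration values.
The subgroup-size thresholds `n_min` are tuned by a grid search that
minimizes the Kolmogorov–Smirnov distance between corrected and donor
measured BMI distributions within sex/age cells.

## Worked example

```python
import bmimatch as bm

# a synthetic donor/recipient pair with known ground truth
donor, recipient, truth = bm.generate(bm.PopulationSpec(), 16_924, 50_000, seed=1)

model = bm.StatisticalMatchingModel(recipient, donor,
                                    bm.MatchConfig(n_iterations=100))
result = model.fit(seed=1001)
print(result.summary())
```

```
Statistical matching correction
===============================================
recipient records:      50000
donor records:          16924
iterations:               100
jitter:                 0.010
seed:                    1001
-----------------------------------------------
mean BMI (self-reported):   28.13
mean BMI (corrected):       28.72
obesity (BMI>=30): uncorrected 33.24%  corrected 37.95% (37.46-38.43)
severe obesity (BMI>=35): uncorrected 12.22%  corrected 15.57% (15.21-15.93)
-----------------------------------------------
KS vs donor measured BMI: D=0.0071  p=0.703
max loosening level: 2
median bandwidth:    0.0050
```

Self-report hid 4.7 points of obesity prevalence here: the generator's
true prevalence is 37.2%, self-reported data show 33.2%, and the
correction recovers 37.9% (the donor's own measured prevalence is the
estimand the match reproduces; its KS distance to the corrected
distribution is 0.007, p = 0.70).  Per-state tables come from
`result.state_table()`, e.g. corrected obesity prevalence 31.6%
(CO) to 45.9% (WV) across the synthetic states, and comparator models
from `bm.IndividualRegressionCorrection(recipient, donor).fit()` and
`bm.AggregateAlignmentCorrection(recipient, donor).fit()`.

A command-line interface mirrors the library:

```bash
bmimatch simulate --n-donor 16924 --n-recipient 50000 --seed 1 --out sim/
bmimatch correct --donor sim/donor.csv --recipient sim/recipient.csv \
        --method all --iterations 100 --seed 1 --out corrected/
bmimatch validate --donor sim/donor.csv \
        --corrected corrected/corrected_matching.csv --out validation/
bmimatch state-table --corrected corrected/corrected_matching.csv
bmimatch run --config run.yaml        # full pipeline with manifest
```

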