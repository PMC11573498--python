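# Methods

`ostrea` implements a growth-based demographic analysis of archaeological
oyster (*Ostrea edulis*) assemblages.  The scientific problem is an
attribution question: shells in midden deposits get smaller or larger
through time, and the cause can be **harvesting pressure** (people removing
shells younger, shifting the age-at-death distribution) or **growing
conditions** (temperature, salinity, food supply changing how fast shells
grow at a given age).  Size alone cannot separate the two; size *and*
biological age together can.

## Data model

The analysis unit is a per-shell record: hinge size in mm (caliper
precision, one decimal — the hinge is the dense, well-preserved part of the
shell and the standard size proxy), an integer age in years from counting
annual increment lines in thin section, a cultural period (Mesolithic /
Neolithic), and optionally an ordered stratigraphic layer.  Either
measurement may be missing; a record missing both carries no information
and is rejected at ingest with a row-numbered diagnostic.  Unrecognized
period labels map to `unassigned`: such shells are excluded from period
comparisons but retained for site-level and stratigraphic work.

Summary tables use linear-interpolation quantiles (the default convention
of mainstream statistical software), fixed so outputs are reproducible, and
report hinge/length to one decimal, age means to one decimal and age
min/max as integers.

## Hinge-to-length conversion

Total shell length is reconstructed as `length = c * ln(hinge)` with both
in mm and `c = 35.4` by default.  The logarithm is natural: only base e
reproduces the published summary cells (35.4·ln 1.3 = 9.3,
35.4·ln 6.0 = 63.4) at one-decimal precision.  Back-calculation from the
remaining cells of the same published table suggests the original
unrounded coefficient was ≈ 35.37 (with 35.4 the median cell computes as
71.8 against a printed 71.7), so the coefficient is a parameter rather
than a constant.  Conversion is always derived on demand; hinge remains
the single source of truth.

## Standardized growth curve and residuals

Hinge-at-age follows the von Bertalanffy growth function
`H_s(A) = H_inf (1 − e^(−k(A − t0)))` with `H_inf` the asymptotic hinge
size (mm), `k` the growth-rate coefficient (1/yr) and `t0` the hypothetical
age of zero size (yr).  One *global* curve is fitted by nonlinear least
squares over all shells with both measurements, pooled across sites and
periods — it is the standard against which individual growing conditions
are judged.  A shell's growth residual `r_i = H_i − H_s(A_i)` is positive
when it grew faster than a typical shell of its age and negative when
slower; residuals are the environmental channel throughout the pipeline.

Numerical choices (the fit must be deterministic and library-version
stable):

* starting values — `H_inf0 = 1.05 × max(hinge)`; `k0` from the slope of
  the log-linearized curve `ln(1 − H/H_inf0)` on age; `t00 = 0`, clipped
  below the youngest age;
* trust-region least squares with an analytic Jacobian, parameter tolerance
  1e-8, at most 500 objective evaluations;
* bounds `H_inf ∈ (0, 10·max hinge]`, `k ∈ (0, 10]`, `t0 ∈ [−10, min age)`
  to exclude degenerate sign flips — wide enough never to bind on realistic
  data;
* preconditions: ≥ 4 complete records, ≥ 3 distinct ages, non-constant
  hinges (constant hinges leave `k` unidentified and raise a degenerate-fit
  error);
* ages are integer annual-line counts and are used as-is, with no
  fractional-season adjustment.

On noise-free synthetic curves the fitter recovers generating parameters to
≤ 1e-6; with additive 0.5 mm noise at n = 500 the median absolute relative
error per parameter stays below 5% (both checked in the test suite, the
latter over 100 seeded replicates with generating values
`H_inf = 20, k = 0.3, t0 = −1` — a nonzero `t0` chosen so relative error is
well defined for all three parameters).

## Statistical comparisons

Mesolithic-vs-Neolithic differences in hinge, derived length, age and
residual are tested with two-sided Mann–Whitney U tests; hinge spread
additionally with the variance-ratio F test (larger variance in the
numerator) and Levene's test (classical mean-centered by default; the
median-centered Brown–Forsythe variant is an option).  Ages are small
integers, so ties are pervasive: groups of ≥ 8 use mid-ranks with the
tie-corrected, continuity-corrected normal approximation; smaller groups
use full enumeration of the null distribution over all assignments of the
pooled mid-ranks, which remains exact under ties.  Null calibration is part
of the test suite: the rejection rate at α = 0.05 over 2,000 null
replicates (n = 50 per group) must lie in [0.04, 0.06].

Site-level period tests form one Bonferroni family per variable
(`p_adj = min(1, m·p)` with m the number of qualifying sites), matching how
such results are reported site by site; pooled tests are a family of one.
Both raw and adjusted p-values are reported, with the usual star
convention (p < 0.05 / 0.01 / 0.001).

## Variance partitioning (age vs growth rate)

Per site, hinge size is regressed on age and the growth residual (ordinary
least squares with intercept; standardized coefficients from the z-scored
model; variance inflation factors as multicollinearity diagnostics).  Each
predictor's share of the explained variance comes from **Johnson's
relative weights**: the predictor correlation matrix `R` is factored
through its eigendecomposition into `R^(1/2)`, the response is regressed on
the implied best-fitting orthogonal counterparts of the predictors, and
squared loadings map the shares back to the original, correlated
predictors.  Unnormalized weights sum to R² (enforced to 1e-10); reported
percentages sum to 100.  For two predictors the weights coincide with the
LMG decomposition (incremental R² averaged over both entry orders), which
the test suite verifies against a brute-force LMG oracle to within 2
percentage points across randomized correlated designs.

The growth-rate predictor is the per-shell residual from the *global*
curve, not a per-layer mean, because residuals are defined per shell.
Sites with fewer than 30 complete records or fewer than 4 distinct
stratigraphic levels are flagged `reliable=False` and excluded from
headline tables — short sequences give unstable attributions; the
thresholds operationalize the exclusion of one short (n = 3 layer)
sequence in the source analysis.  The published study's own results text
and its attribution table disagree for two sites (63% vs 67%, 23% vs 25%);
this package targets the table values.

## Stratigraphic trends

Per site, shells are grouped by `layer_order` (context-excavated layers and
arbitrary 10 cm spits are treated identically once ranked; the distinction
is metadata).  Each layer gets counts, means and standard deviations of
hinge, age and residual, in stratigraphic order.  Trend descriptors
condense a sequence into runs of same-sign layer-to-layer change plus an
age–size concordance: the fraction of adjacent-layer steps where age and
hinge move in the same non-tied direction.  Step signs use a dead band
(0.05 mm for hinge/residual, 0.1 yr for age — below one-decimal
measurement precision a step is noise); within-band steps are ties, ties
break runs and count as non-concordant.  Concordance is an
operationalization of "moving in tandem", not a reproduction of any
published statistic.

## Synthetic assemblage generator

Because the study's raw per-shell data live in an external repository, a
simulator provides ground-truth data with the same causal structure, and
every pipeline stage is validated against it:

* **age-at-harvest**: geometric on {1, 2, …} years truncated at 25,
  success probability = `harvest_pressure` (untruncated mean 1/pressure).
  A single monotone pressure knob reproducing the right-skewed observed
  age structure (median ~3 yr, rare 20+ yr individuals);
* **size**: `hinge = env_multiplier × individual_factor × H_s(age) +
  N(0, sd)`, floored at 0.1 mm, rounded to one decimal last (the caliper
  convention).  The environmental multiplier acts per layer and
  multiplicatively on size-at-age — the only environmental effect
  identifiable from a single terminal measurement per shell.  Individual
  growth heterogeneity is a lognormal factor with mean 1 and configured CV
  (keeps hinges positive, residuals roughly symmetric);
* **missingness**: drawn disjointly so no record loses both measurements
  (an uninformative record the reader would reject anyway); configured
  marginal rates are therefore realized exactly in expectation.

Defaults emulate a large multi-site archaeological dataset: 20 sites × 8
ordered layers × 15 shells, generating curve `H_inf = 25 mm, k = 0.13 /yr,
t0 = 0`, individual CV 0.15, measurement sd 0.3 mm, pressure 0.30, 30%
missing ages, 7% missing hinges, lower half of each sequence Mesolithic.
These values were chosen so the simulated six-number summaries and extremes
match the published dataset's (hinge ≈ 1.3–34 mm with median ≈ 7,
ages 1–23+ with median 2–3) and were fixed before the validation suite was
finalized.

Named scenarios move one causal channel each:

* `stable` — both channels constant; the null for calibration;
* `harvest_pressure_shift` — pressure ramps 0.2 → 0.65 up-sequence, growing
  conditions constant: age must get the majority relative weight;
* `environmental_decline` — intense but constant pressure (0.85, pinning
  ages low and stable) while the environmental multiplier falls
  1.5 → 0.4: growth rate must get the majority weight;
* `mixed` — both drift together; the ambiguous case.

The scenario contrasts are deliberately stylized — one channel dominant per
scenario — so that attribution has a well-defined right answer.  The
validation suite requires the correct majority attribution in ≥ 95% of 200
seeded replicates per scenario, and the `stable` scenario to produce no
significant adjusted period differences in ≥ 90% of 100 replicates.

### What the simulator does not emulate

Real middens add taphonomic loss correlated with shell size, inter-site
differences in the growth curve itself, non-geometric harvest selectivity
(e.g. gatherers preferring large shells), sampling bias toward sectionable
shells, and chronological uncertainty in period assignment.  Passing the
simulation-based checks therefore demonstrates that the *methods* recover
known structure under the model's assumptions — it does not by itself
validate conclusions about any particular archaeological dataset.

## Problem sizes

The validation suite and analysis scripts use assemblages of 720–3,200
shells and replicate counts of 100–200 per stochastic check; these sizes
give stable attribution rates and tight calibration estimates while keeping
a full run in the tens of seconds on one CPU.

## Known limitations

* The single global growth curve averages over sites and periods; per-site
  curves exist behind an option but are not the default, matching the
  standardized-curve design.
* Relative weights are limited to the two-predictor case in the headline
  analysis; no dominance analysis, no bootstrap intervals on weights.
* The hinge-to-length conversion is taken as given; the paired
  hinge/length data behind it are not re-fitted here.
* Ages below 1 yr and fractional ages are out of model by construction.
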