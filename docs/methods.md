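# Methods

This note documents the statistical procedures `wildri` implements, the
synthetic-data model used to validate them, and the design decisions made
where practice in the reference-interval literature is not unique.

## Data model

The canonical input is a long-format table: one row per blood sample with
an animal identifier, ISO-8601 collection date, site, sex, age class, two
boolean quality flags (clinically significant exam abnormality; poor
sample quality such as clotting, hemolysis or lymph contamination), and
one column per analyte. Missing analyte values are legal per sample; each
analyte's pipeline operates on its own complete subset, so per-analyte
sample sizes differ. Month and year are derived from the date but may be
supplied explicitly (explicit columns win, with a warning, since they are
analysis factors in their own right).

Analyte metadata carries units, a nonnegativity flag, an optional lower
quantitation limit (values below it are reported at the limit — e.g. a
uric acid assay floor of 0.8 mg/dl), and an optional analytical
coefficient of variation CV_A from instrument validation studies.

## Screening

Samples failing either quality flag are excluded whole; outliers are then
flagged **per analyte** among the remaining non-missing values, in a
single pass:

* **horn** (default): shift values to be strictly positive if needed, fit
  a maximum-likelihood Box-Cox transform, and flag points outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] on the transformed scale. This is the
  standard screen for reference-interval work; on null Gaussian data it
  flags well under 2% of points.
* **tukey_raw**: the same fences on the raw scale (invariant under
  positive affine transforms).
* **none**: keep everything.

The original study this design follows used a commercial package's
outlier routine that is not publicly specified; Horn's method is the
documented replacement. Fewer than 20 values skips the screen with a
warning. Screening precedes normality assessment; whether the original
analysis ordered these steps the same way is unknown.

Normality is called by the Shapiro-Wilk test at alpha 0.05 (3 ≤ n ≤ 5000);
sample skewness and excess kurtosis are reported as diagnostics but do
not override the test, since no numeric thresholds for them are
established. Constant vectors are classified non-normal with a warning
rather than erroring the pipeline.

## Variance components, individuality, RCV

For each analyte, animals with ≥ 2 non-missing samples form the
repeat-measures subset (singleton animals are excluded here; they still
contribute to reference intervals). With per-animal counts n_a, k
animals, N samples total:

    s_w² = Σ_a Σ_j (x_aj − x̄_a)² / (N − k)            (pooled within)
    MS_b = Σ_a n_a (x̄_a − x̄)² / (k − 1)
    n₀   = (N − Σ_a n_a²/N) / (k − 1)
    s_b² = max(0, (MS_b − s_w²) / n₀)                  (method of moments)

CV_I = s_w/x̄ and CV_G = s_b/x̄ with x̄ the grand mean of the subset. On a
balanced design this reduces exactly to classical one-way ANOVA
components; negative moment estimates truncate to zero. CVs are computed
on the raw scale with no removal of month/year effects — the
repeat-capture interval within a field season is short enough that
seasonal drift is treated as part of within-animal variation.

Two index-of-individuality variants are computed, because published
formulas and published tables disagree on whether analytical variation
enters the numerator:

    index_with_cva    = (CV_I + CV_A) / CV_G
    index_without_cva =  CV_I / CV_G

The decision rule — **subject-based** below 0.6, **population-based** at
or above it (the boundary goes to population, the more general object) —
uses `index_without_cva` by default; the variant and threshold are
configurable. Similarly both RCV variants are reported:

    rcv_stated   = 1.96 · √2 · CV_I
    rcv_combined = 1.96 · √2 · √(CV_A² + CV_I²)

with `rcv_combined` the headline value (it reduces to `rcv_stated` when
no analytical CV is known).

## Reference intervals

Population-type analytes whose retained values pass the normality screen
get the parametric interval mean ± 1.96·SD; lower bounds of nonnegative
analytes clamp at zero (flagged). Non-normal analytes default to the
Box-Cox parametric method — fit a maximum-likelihood λ, compute
mean ± 1.96·SD on the transformed scale, back-transform — which produces
the asymmetric intervals right-skewed analytes need; the raw parametric
and the nonparametric (interpolated 2.5th/97.5th percentile) methods are
selectable. Guideline sample-size minima (40 parametric, 120
nonparametric) are enforced as warnings, not errors, since subgroup
analytes routinely fall below them.

Each bound's 90% confidence interval comes from a percentile bootstrap:
resample n-with-replacement B = 1000 times, recompute both bounds
(including the Box-Cox refit, so transform uncertainty propagates), take
the 5th/95th percentiles of each bound's bootstrap distribution. Fully
seeded and deterministic. The Box-Cox λ search uses a coarse profile-
likelihood grid on [−3, 3] refined by bounded Brent iteration (agreement
with a full scalar MLE to ~10⁻³ in λ, far below λ's own sampling noise);
this keeps the bootstrap loop fast.

Subject-type analytes get descriptive statistics (n, mean, SD, median,
range) and their RCV instead of population bounds.

## Partition statistics

For each analyte × factor (age class, sex, month, year, site), levels
with n < 2 are dropped with a warning — in the default synthetic design
this removes the single August sample from month comparisons. Level
summaries report the mean with its t-based 95% CI when the level passes
the normality screen, else the median with 10th/90th percentiles; min and
max always.

Omnibus comparisons are normality-gated: the parametric branch
(independent-samples t-test for two levels, one-way ANOVA for more) runs
only when **every** level passes Shapiro-Wilk; otherwise Mann-Whitney U /
Kruskal-Wallis. A significant omnibus (p < alpha, default 0.05) triggers
pairwise two-sample tests with the same per-pair gate. For sex, the
unknown-sex level participates in the omnibus test and in modeling, but
pairwise reporting is restricted to female vs male. Raw p-values are
reported with no cross-analyte multiplicity correction, matching
convention in wildlife clinical-pathology surveys; a Holm adjustment can
be applied downstream by the user.

The model-selection stage fits ordinary least squares (statsmodels,
treatment-coded factors; aliased columns dropped with a warning) for a
candidate set that defaults to all 2⁵ subsets of the five main effects
plus the global model (all mains + all ten two-way interactions), ranked
by the small-sample criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1)

with k = estimated coefficients + 1 (residual variance), plus Akaike
weights. Candidates with n − k − 1 ≤ 0 are skipped. Because repeat
captures of one animal are not independent, modeling defaults to each
animal's first capture (`dedup="first"`); an all-samples mode exists for
sensitivity analysis. Mixed models with animal as a random effect are out
of scope — the first-capture design removes the dependence they would
address at a modest cost in data.

## Synthetic data

The generator draws, per animal, a latent mean μ_a ~ N(μ + Σ shifts,
σ_between²) and per sample x ~ N(μ_a, σ_within²); in log-normal mode the
same construction happens on the log scale with moments matched so the
configured mean and SDs are the raw-scale targets, producing the right
skew of leukocyte counts and muscle enzymes. Group effects are additive
shifts on the mean keyed by (factor, level); interactions are not
generated (so model selection can be validated for *not* finding them).
Nonnegative draws truncate at zero; a quantitation floor left-censors at
the reporting limit. Site, sex, age class and year are constant within an
animal; month varies across an animal's repeat captures (sorted
chronologically within the season).

`default_study_config` emulates the reference sampling design: 157
single-capture animals plus 70 repeat animals split {2: 22, 3: 20, 4: 13,
5: 10, 6: 5} — exactly 393 samples from 227 animals — with demographic
marginals matching the published sample composition (sites 224:169, sexes
254:103:36, age classes 268:85:40, months 134:160:98 plus one forced
August capture, years 233:160). Analyte means and SDs are the published
healthy-population values. The published table gives CV_I/CV_G pairs only
for the seven subject-type analytes; those ratios split each analyte's
total variance (on the log scale for log-normal analytes, so the ratio
survives exponentiation). Population-type analytes use a within:between
ratio of 1.2, placing their index above the 0.6 threshold by
construction. One published inconsistency is inherited deliberately: the
uric acid row's mean (2.8) and SD (0.2) are not compatible with its
printed CVs; the generator uses the printed mean/SD for the marginal and
the printed CV ratio only for the split.

What the generator does **not** emulate: lymph hemodilution and other
pre-analytical artifacts, assay drift, clinically abnormal animals,
month-by-demographic interactions, and any distributional family beyond
Gaussian/log-normal. Passing tests therefore demonstrate estimator
correctness and calibration under the assumed two-level model, not
robustness to every pathology of real field data.

## Validation and problem sizes

The test suite validates each estimator against independent oracles
(hand-computed balanced ANOVA, brute-force least squares, interpolation
arithmetic) and by parameter recovery / calibration simulations sized to
run in seconds on one core: CV recovery uses 20 seeds of 70 animals × 3
samples (median relative error ≤ 15%); parametric-interval coverage uses
50 seeds of n = 400 with 10⁵ fresh draws each (mean coverage 95% ± 1%);
omnibus type-I error uses 200 replicates of 3 × 30 null Gaussian groups
(rejection rate within [2%, 9%] at alpha 0.05); determinism is checked by
byte-comparing two end-to-end pipeline runs at the same seed.

## Known limitations

* Method-of-moments components on heavily skewed analytes are noisy at 70
  repeat animals; indexes near 0.6 can flip type between realizations.
* The Box-Cox interval assumes normality is achievable by a power
  transform; heavy-tailed or multimodal analytes should use the
  nonparametric method at adequate n.
* Left-censored values (quantitation floors) are used as-is; no censored
  likelihood is fit, which biases CVs of floor-heavy analytes downward.
* No mixed-effects modeling; repeat-measure dependence is handled by
  de-duplication only.
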