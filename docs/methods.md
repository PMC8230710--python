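# Methods

## Setting

Urinary arsenic in populations near legacy contamination sources is carried
almost entirely by dimethylarsenic acid (DMA), with arsenite (AsIII),
arsenate (AsV) and monomethylarsinic acid (MMA) as minor species whose
shares vary systematically with the total. Two assay families are in
routine use: HG-AAS returns a single summed hazardous-arsenic reading
(hAs_AAS), HPLC-ICP-MS returns the four species individually, whose sum is
hAs_ICP. This package implements the comparison and interchangeability
analysis between the two, plus the synthetic cohort machinery needed to
exercise it, since cohorts of this kind are typically access-restricted.

All statistics operate on creatinine-standardized concentrations,
µg/g-creatinine = (µg/L analyte) / (g/L creatinine), the standard dilution
adjustment for spot urine. Subjects are eligible when creatinine lies in
the clinical reference range 0.3–3.0 g/L, bounds inclusive (the permissive
reading of "within the range").

## Censoring

Readings below a species' limit of detection (defaults: AsIII 0.100, AsV
0.164, MMA 0.078, DMA 0.022 µg/L) are replaced by LOD/2 and contribute to
every statistic, including geometric means, at that value. No
Kaplan–Meier or regression-on-order-statistics estimator is offered: LOD/2
substitution is the convention this analysis is built around, and its
simplicity is what makes the downstream identities testable. Substitution
is idempotent and never touches uncensored values.

## Distribution summaries

Each stratum × quantity cell reports n, arithmetic mean ± SD (n−1),
geometric mean with a log-scale t-interval
exp(mean(log x) ± t₀.₉₇₅,ₙ₋₁ · sd(log x)/√n), median, range, and the
75/90/95/99th percentiles with linear interpolation. The t multiplier
(rather than z) is the standard small-sample biomonitoring choice. The
pipeline's summary table drops non-positive values (with a logged note) for
the summed-assay quantity only — the generator floors that reading at zero
when a subject's total falls under the inter-assay offset — and reports n
as the count actually summarized.

## Agreement and calibration

Lin's concordance correlation coefficient uses population (1/n) moments,
the convention of the original estimator; a 1/(n−1) variant is available
via `sample_moments=True` and differs by O(1/n). The calibration line is
OLS of the speciated sum on the summed assay. The additive bias correction
defines the shift as the calibration intercept (not mean(y−x)): when the
slope is near one the intercept *is* the additive inter-method offset, and
the two definitions coincide only at slope exactly one. After shifting,
slope is unchanged (OLS translation equivariance) and the new intercept is
β₀(1−β₁); both are re-fit from the corrected series rather than derived,
so the report reflects actual recomputation. No bootstrap CI is attached
by default.

A caveat worth stating explicitly: when the summed assay carries
multiplicative measurement noise, it is the *regressor* of the calibration
line, so the fitted slope is attenuated toward zero (classical
errors-in-variables) and the intercept is biased upward by roughly
(1−λ)·E[x], λ = var(x_true)/var(x_observed). At the default noise level
(CV 0.1) this inflates the recovered offset from 18 to ≈19.4 µg/g-cr.
The estimator itself is exact: with noiseless data the offset is recovered
to numerical precision. Consumers comparing assays with substantial
within-method noise should prefer an errors-in-variables (Deming) fit,
which is deliberately out of scope here.

## Adjusted proportion means

For each proportion outcome an additive linear model on all adjustment
factors at once is fit by OLS. The least-squares mean of a factor level is
defined by prediction averaging: every subject keeps their observed
covariates except the focal factor, which is forced to the level; the LSM
is the mean prediction. In a balanced orthogonal design this equals the
raw group mean. Confidence intervals come from the t distribution on the
residual degrees of freedom and are symmetric about the LSM; proportions
are modelled on the raw percentage scale (no logit), so small LSMs can go
slightly negative — they are reported as-is, and any truncation at zero is
a rendering concern. The overall factor p-value is the partial F-test of
the factor's coefficients given the other factors. Pairwise level
contrasts are Bonferroni-corrected with m = pairs within the factor
(α = 0.05 default) and summarized by an insert-and-absorb compact letter
display: levels sharing a letter are not significantly different after
correction; significant pairs never share a letter. Ties in the LSM
ordering break by level order. Missing covariate values form an explicit
"missing" level. Aliased (rank-deficient) designs raise rather than
silently dropping columns; the pipeline degrades this stage to a warning
and empty output when the cohort is too sparse to support the model.

## Proportion-versus-total curves

Subjects are ranked by the speciated total and split into equal-count
sections (default 100, i.e. percentile sections; the remainder of n mod
bins goes to the lowest sections). Curves are fit to the per-section mean
proportion versus mean total, unweighted (a bin-size-weighted fit is a
flag away): quadratics by linear least squares, power curves a·h^(−b) by
nonlinear least squares seeded from the log–log fit. R² and adjusted R²
(1−(1−R²)(n−1)/(n−p−1)) are both reported for every model. A constant
outcome short-circuits to (a = constant, b = 0) with R² defined as 0.
Curve evaluation returns the raw value and a [0,100]-clamped value side by
side, because quadratics leave the physical range away from their fit
domain; the domain is recorded with every fitted model.

The pipeline fits curves on the background stratum only: the rare
contaminated-site stratum carries an inorganic profile of its own and
would otherwise occupy the top percentile sections and invert the fitted
trends. Agreement, summary tables and projection use all subjects.

## Projection (interchangeability)

Given a summed reading h, each minor species is estimated as its
curve-predicted share of h, and DMA as the remainder, so the four
estimates sum to h exactly — mass balance holds by construction for every
subject. Negative curve predictions are floored at zero; if the three
minor estimates overshoot h they are rescaled proportionally (flagged) so
the balance survives. Optionally the additive assay shift is applied to h
first, since the offset analysis establishes that the summed assay reads
low. Validation regresses observed on estimated per species, the
orientation in which interchangeability claims are stated. On realistic
cohorts DMA validates well and the minor species poorly; the package makes
no attempt to build a better species estimator — quantifying how little
speciation signal a summed assay contains is the point.

## Synthetic cohort generator

The generator emulates, per subject: DMA drawn log-normally (default GM
70 µg/g-cr, GSD 2.2); the total solved from the curve-implied DMA share by
per-subject fixed-point inversion, which pins the noiseless DMA geometric
mean exactly at its configured value; minor-species proportions from the
configured curves plus Gaussian noise (default SD 3 percentage points)
truncated to [0,100], with DMA as the complement; covariate effects as
additive shifts of the inorganic share (default: males +3 points, split
between AsIII and AsV); a high-exposure stratum (default frequency
14/457) multiplying the inorganic species by 50; the summed assay as
total − offset (default 18 µg/g-cr) times multiplicative noise (default
CV 0.1 — a plausible inter-method analytical CV; replicate variance data
to anchor it are not generally published), floored at zero; uniform
creatinine in 0.4–2.5 g/L mapping µg/g-cr to µg/L; and censor flags where
the µg/L reading falls below the species LOD. Stored values remain the
truth — flags drive substitution downstream — keeping the generator
invertible for round-trip tests.

The default generating curves use the reference AsIII power decay and MMA
quadratic, but an AsV quadratic re-parameterized to stay decreasing
through the realistic range (vertex at h = 350 µg/g-cr): the reference AsV
shape turns upward almost immediately and cannot serve as a generating
truth. Curves are evaluated at min(h, 300 µg/g-cr) inside the generator —
flat extrapolation beyond the trusted range — so rare extreme subjects
cannot acquire unphysical speciation. Covariate categories are sampled
with frequencies shaped after a rural, older, majority-female mine-area
cohort, including explicit "missing" levels for questionnaire items.

What the generator does *not* emulate: correlation between covariates and
exposure magnitude (effects act on speciation only), within-subject
replicate structure, spatial/mine-level clustering, instrument physics, or
seasonal diet effects. Tests passing on this cohort therefore certify the
statistical machinery under the stated structure, not the epidemiology of
any real population.

Truncation of proportion noise at zero is worth flagging: for species
whose true share is below ~2 points, truncated noise raises the observed
mean share (this is realistic — it is why arithmetic means of minor
species far exceed their geometric means) and flattens fitted decay
curves. Curve-recovery guarantees are therefore stated for Gaussian
scatter; data passed through the truncated fixture generator carry an
upward bias at sub-percent shares that no unbiased fitter can remove.

## Numerical and reproducibility choices

Quartile labels use the 25/50/75th percentiles with linear interpolation;
values equal to a cut point go to the lower quartile; fully tied data
degenerate to Q1 with a warning. All randomness flows from
`numpy.random.default_rng` seeds; the pipeline derives per-stage child
seeds from the run seed via `SeedSequence([seed, stage])`, so stages can
be re-run in isolation. Manifests contain no timestamps and are
byte-identical across reruns of the same (config, seed). Concentrations
are kept at full precision throughout; rounding is a rendering concern.
Default problem sizes — cohorts of 457, 100 percentile sections, 200
replicates for Monte-Carlo properties, 5000 subjects for generator-moment
checks — keep every check comfortably small while leaving sampling error
well inside the asserted tolerances.
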