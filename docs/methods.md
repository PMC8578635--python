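# Methods

This note documents the models, conventions, and numerical choices behind
`pharmscreen`, in the spirit of a statistical methods supplement. It covers
what each stage computes, the defaults and why, what the synthetic-data
generators emulate (and what they deliberately do not), and the known
limitations.

## Lineage Selectivity Scores

For one drug screened against N cell lines, lines are ranked ascending by
IC50 (rank 1 = most sensitive). Ties receive the mean of the tied rank
positions — the fractional-rank convention, chosen over ordinal ranks
because it is invariant to the input ordering. The Selectivity Score is

    score = median(target-lineage ranks) / N,

a value in (0, 1]; lower means the target lineage sits near the sensitive
end of the ranking. For an even number of target lines the median is the
mean of the two middle ranks (the standard sample median). Because the
score depends on IC50s only through ranks, it is invariant under any
strictly increasing transform of the concentrations, and the same code
ranks drugs on any sensitivity column (e.g. viability fold changes) without
modification.

`rank_drugs` computes one score per drug using only the lines actually
screened against that drug (N is drug-specific). Drugs with fewer than
`min_target` target-lineage lines (default 3) are skipped rather than
scored — a median over one or two lines is too unstable to rank. An
optional subgroup predicate (e.g. *MYCN*-amplified / *TP53* wild-type)
restricts which target-lineage lines define the median while N still
counts every screened line, so subgroup scores remain on the same scale.

Group comparisons of log10 IC50 use Welch's two-sample two-sided t-test
(unequal variances assumed — the safer default when group sizes differ by
an order of magnitude); rescreen concordance is the Pearson correlation of
paired log10 IC50s with the usual t-approximation p-value.

## Four-parameter log-logistic (4PL) dose–response

All curve fitting uses

    y(d) = lower + (upper − lower) / (1 + (d/ec50)^(−hill)),

with the sign of `hill` encoding direction (positive: response rises with
dose). The 4-parameter form is used throughout; a fifth asymmetry
parameter is deliberately excluded. Fitting is least squares on the
response scale via `scipy.optimize.least_squares`, parameterized in
log(ec50) so the midpoint stays positive. Initialization: asymptotes from
the response extremes, log(ec50) from the dose bracketing the half-range
crossing, and a multi-start over hill magnitudes {1, 2}; the best SSE wins
and exact ties go to the smaller |hill|. Convergence tolerances are 1e-10
on relative SSE change with a cap of 10,000 function evaluations;
`converged=False` is reported (with the best-found parameters) if the
optimizer does not terminate cleanly. After fitting, parameters are
canonicalized so `lower <= upper` (the curve is unchanged by swapping
asymptotes and negating the hill).

ICx values are closed-form inversions on the **absolute** assay scale:
with `f = (effect − lower)/(upper − lower)`,

    d = ec50 · (f/(1−f))^(1/hill).

"IC25" therefore means the dose at which the curve crosses 75% of total
activity remaining — 25% inhibition of the assay total, not 25% of the
fitted dynamic range. A relative-to-asymptote reading can be had by
passing `effect = lower + x·(upper − lower)`.

Confidence intervals come from a case-resampling bootstrap (B = 1000 by
default, percentile 2.5/97.5), warm-started at the full-data fit. Case
resampling was preferred to residual resampling because replicate noise in
plate data is not obviously homoscedastic across the dose range. More than
half of the bootstrap refits failing raises an "unstable fit" error rather
than returning a misleading interval.

Plate-reader IC50s (`ic50_from_viability`) normalize raw luminescence to
the mean vehicle signal, fit a decreasing 4PL, and invert at the 0.5
absolute level; the whole path is invariant to a common rescaling of the
raw signal.

## ZIP synergy surfaces

Combination plates cross two 12-point 1:2 dilution ladders. Raw signal is
mapped to percent cell death per well and replicate with

    %death = 100 · (mean_vehicle − x) / (mean_vehicle − mean_maxkill),

using the plate's own vehicle (0% death) and maximum-kill (100% death)
control wells. Normalized values are **never clipped**: out-of-range
values are real replicate noise and clipping them would bias the
downstream t-tests. The map is invariant to adding a constant to every
signal, controls included.

The zero-interaction-potency expectation for two single-agent percent
death values is `E = y1 + y2 − y1·y2/100`, evaluated on copies clamped to
[0, 100] (probabilities must stay in range inside the expectation; stored
matrices are untouched).

The delta surface follows the two-directional conditional-fit scheme of
the ZIP framework: (i) fit each monotherapy with a 4PL; (ii) for each grid
row (second drug's dose fixed) fit a conditional 4PL in the first drug's
dose with the lower asymptote pinned at the second drug's fitted
single-agent effect at that dose, and symmetrically for columns; (iii) the
fitted combination response at each dose pair is the mean of the row and
column predictions; (iv) delta is that fitted response minus the ZIP
expectation of the two monotherapy-fit predictions. Rows or columns whose
conditional fit fails fall back to the observed values and are flagged. A
simpler "observed minus expectation" mode (`mode="naive"`) is available
for diagnostics. Replicates are averaged **before** surface fitting;
synergy calls go back to the per-replicate values.

Calls extract the maximum- and minimum-delta dose pairs and test the
per-replicate `log2(observed %death / E)` against zero with a one-sample
two-sided t-test. Classification thresholds default to |log2 FC| >= 1.5
and p <= 0.01; the fold-change threshold is interpreted on the log2 scale
(an alternative linear-fold reading is a config switch). A pair whose
expectation — or any replicate's observed death — is non-positive cannot
support a log fold change; such pairs are skipped in favor of the
next-ranked extremum and counted in the output.

## Genomic association

Regressions of log10 IC50 on genotype/expression use ordinary least
squares (statsmodels) with per-coefficient t-tests, the overall F-test and
R². A coefficient c on log10 IC50 is reported as a directional fold
change 10^|c| (increase if c > 0), with the CI transformed monotonically.
Rank-deficient designs raise rather than silently dropping columns.

Genome-wide scans correlate each gene's expression with a sensitivity
vector (reciprocal IC50 by default) using Spearman's rank correlation with
mean ranks for ties and the t-approximation p-value; constant genes are
reported as missing. The scan is vectorized (ranks once, then a matrix
product), which matters at genome scale. Gene-set shift tests compare
in-set vs out-of-set correlations with Welch's t-test by default; a paired
mode exists but requires an explicit pairing, since there is no canonical
pairing between a small gene set and the remaining genome.

Mediation is the regression form: fit `y ~ exposure` and
`y ~ exposure + mediator`, and report both exposure coefficients/p-values
plus the conditional mediator term. Full mediation appears as a marginal
exposure association that vanishes once the mediator is conditioned on
while the mediator stays significant. No product-of-coefficients or
bootstrap indirect-effect machinery is included — the conditional-loss
pattern is the quantity of interest.

ElasticNet minimizes

    (1/2n)·||y − b0 − Xb||² + λ·(α||b||₁ + (1−α)||b||²/2)

on standardized features with an unpenalized intercept; α defaults to 0.5
and λ is chosen as the minimizer of mean 10-fold cross-validated error on
a 50-point geometric grid from the data-derived λ_max down four decades
(the CV-minimum rule, not the 1-SE rule). Folds are seeded and shuffled.
The inner solver is scikit-learn's coordinate descent, whose penalty with
`alpha=λ, l1_ratio=α` is exactly the objective above; coefficients are
mapped back to the original feature scale. Zero-variance features are
dropped with a warning. A KKT-residual helper checks the subgradient
conditions of the returned solution (used in the test suite at 1e-6).

Housekeeping normalization is `log2(TPM+1)` of the gene minus the mean
`log2(TPM+1)` over the housekeeping set (default ACTB, GAPDH); the +1
guards zeros and matches the log2(TPM+1) convention used everywhere else.
`fold_range` is simply max/min of a positive vector.

## Paralog preference

Each decatenation run yields percent-decatenation curves for both
topoisomerase-II paralogs over a shared dose ladder. Per run and enzyme a
decreasing 4PL is fit and inverted at 75% remaining activity (IC25 on the
absolute scale); optional masks drop doses outside a compound's activity
range before fitting, and IC25s outside the tested range are flagged as
extrapolated but still returned. The preference statistic is the
geometric mean over runs of the per-run ratio IC25_A/IC25_B — a fold
ratio was chosen over a percent difference because the quantity of
interest is "how many fold less compound inhibits the B paralog"; a
percent-difference mode is provided. The CI is a t-interval on the per-run
log ratios. Runs where either enzyme's fit fails are dropped (recorded);
fewer than three surviving runs is an error.

Significance uses a simulation test. Per run, a pooled 4PL is fit to the
combined A+B points; null datasets draw both enzymes' responses as the
pooled curve plus residuals resampled with replacement from the pooled
residual pool, followed by a random label swap. Resampled residuals are
inflated by sqrt(n/(n−p)) so the four degrees of freedom absorbed by the
pooled fit do not shrink the null noise level (without this correction the
test rejects ~11% of true nulls at the 5% level; with it, calibration sits
at ~5%). The two-sided p-value is `(1 + #{|sim| >= |obs|})/(1 + n_sim)`,
with the statistic |mean log ratio|.

Inside the simulation loop, both the observed and every null statistic are
computed with the same fast estimator: a fixed-asymptote (0/100)
log-logistic fit by a vectorized SSE grid search over (hill, log ec50)
with quadratic refinement of log ec50. Using one estimator for observed
and null data preserves the exchangeability the test relies on, and the
vectorized path makes 10,000 simulations per dataset (and 500-dataset
calibration studies) cheap. The reported point estimate and CI always use
the full free-asymptote fits.

## Non-compartmental PK

AUC uses the linear trapezoid by default; a linear-up/log-down variant
(log trapezoid on strictly declining positive segments) is available by
flag. The terminal slope is a least-squares regression of ln(concentration)
on time over the final `n_terminal` points (default 3, no automatic
best-fit point selection — simple and auditable), giving `lambda_z` and
`t1/2 = ln2/lambda_z`; non-declining terminal data or zero concentrations
in the window raise. `Cavg = AUC/interval` with an inclusive threshold
check (default 100 µg/L) supports exposure-matched dosing decisions.
Cross-species exposure comparison is by ratios of AUC and Cavg only; no
allometric model is implemented.

## Synthetic data: what it emulates, and what it does not

Every generator is seeded (`numpy.random.default_rng`), returns its ground
truth beside the data, and reproduces byte-identical output for identical
seeds. Noise models are the simplest forms consistent with the
positivity of each quantity: Gaussian on log10 IC50 and on percent-death
points, multiplicative lognormal on concentrations.

- **Screens**: log10 IC50 = lineage/genotype/drug structure + Gaussian
  noise. Defaults mirror a large public screen: 1,001 lines × 265 drugs
  with a 31/1001 target-lineage fraction, and planted genotype effects of
  ×17.45 (TP53 mutant, resistance) and ×10.9 (MYCN amplified,
  sensitization). Tests and the acceptance script use smaller screens
  (50–200 lines) — the statistical structure, not the raw scale, is what
  the pipeline consumes.
- **Plates**: monotherapy 4PL truths anchored to the printed top
  concentrations (e.g. 1.89 µM and 19.93 µM ladders); the true combined
  response is the ZIP expectation plus a configurable interaction
  (zero, block, or smooth bump); raw signal inverts the control
  normalization, with four replicates and noisy control wells.
- **Expression chains**: a latent mediation chain exposure → mediator →
  outcome with configurable path coefficients, emitted as a TPM table
  (with ACTB/GAPDH at fixed levels) plus a 38-column feature matrix with
  3 planted predictors of the mediator among equicorrelated noise
  features. Cohort sizes default to 29 (cell-line mode) with 88 for the
  tumor-cohort mode. Mediation-focused analyses set the planted feature
  effects to zero so the exposure–mediator correlation sits near 0.8.
- **Decatenation**: decreasing 4PL truths with the true IC25 fixing the
  EC50; 9 doses spanning 1.734–400 µM and 5 runs. The printed endpoints
  are not an exact power of 2 apart, so the ladder is geometric with step
  ≈1.97 rather than exactly 1:2.
- **PK**: one-compartment IV kinetics, default t1/2 = 3.7 h, sampled on a
  0.5–24 h grid with 10% lognormal CV.

What passing tests on these generators shows: the estimators recover
planted truths of realistic magnitude at realistic sample sizes, the
tests are calibrated under their own nulls, and every stage is
deterministic under seeding. What they do **not** show: robustness to the
messiness of real screening data — batch effects, heteroscedastic and
non-Gaussian noise, dose-range misspecification, correlated missingness,
or marginal distributions matched to any particular public release. No
attempt is made to match GDSC/PRISM empirically.

## Problem sizes in the test and acceptance runs

Simulation studies in the test suite use the sizes stated in their
docstrings (e.g. 200-seed coverage studies with B = 300 bootstrap
resamples, 500-dataset null calibrations at n_sim = 2,000, 100-seed
support-recovery studies at n = 88 × 38). `scripts/acceptance.py` uses
comparable or slightly smaller replications (25–200 seeds per quantity,
B = 300, n_sim = 1,000–2,000), chosen so each quantity's Monte-Carlo error
is small relative to the tolerance of the claim it supports.

## Known limitations

- The 4PL optimizer is local with a small multi-start; pathological
  biphasic data can settle in poor optima (masking, as in the
  decatenation workflow, is the intended remedy).
- The ZIP conditional-fit scheme is this package's fixed reference
  behavior; numerical agreement with any particular external synergy
  package/version is not guaranteed.
- Mediation is purely regression-based and assumes linearity and no
  unmeasured confounding; it quantifies the conditional-loss pattern, not
  a causal indirect effect.
- The simulation-test null (pooled-curve residual resampling + label
  swap) is one reasonable null among several; it is documented here as
  the reference and is swappable in code.
- PK summaries are non-compartmental; no absorption modelling, so IP/PO
  profiles are summarized on the same terms as IV.
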