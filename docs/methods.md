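# Methods

## The problem being modelled

Psychometric scales score a construct by summing ordinal item responses, so
a single skipped item invalidates a respondent's total score. This package
studies, by simulation, what the common remedies cost: it builds complete
synthetic questionnaire populations, hides a controlled fraction of item
cells under a missing-at-random mechanism, repairs the data with four
strategies, and measures how far summary statistics and downstream analyses
drift from their complete-data values.

## Synthetic population model

Respondent covariates are drawn i.i.d. from declared marginals —
categorical variables from level probabilities, continuous ones from a
normal mean/sd — and are mutually independent. A unidimensional latent
trait links them to the items:

    theta_i = sum_c beta_c * code_c(x_ic) + e_i,   e_i ~ N(0, 1)

where `code_c` is a centred coding (level index minus its expectation for
categoricals; z-score for continuous variables) so that `beta_c` is the
trait shift per coded step, in trait-SD-ish units. Each ordinal item
follows a probit-style graded threshold model:

    z_ij = lambda_j * theta_i + eps_ij,  eps_ij ~ N(0, 1)
    x_ij = response_min + #{t : z_ij > tau_jt}

with strictly increasing thresholds per item. The shared trait produces
positively inter-correlated items and covariate–score associations; with
zero loadings the item marginals reduce to the closed-form normal-CDF cell
probabilities, which is the oracle the generator is unit-tested against.

**Calibration.** Each preset's thresholds were frozen once by
`calibrate_scale_params`: a coarse grid over a threshold spread factor and
the loading, with an inner bisection on a common threshold shift against
the Monte-Carlo total-score mean (common random numbers make the
shift→mean map exactly monotone, n = 60 000 per evaluation). The RSES-like
preset (10 items, 1–4, n = 3513) targets total-score mean 28.22, SD 4.63
and lands within ~0.02 / ~0.08 of them. The SAQ-like (16 items, n = 742,
target 44/7) and ADL-like (14 items, n = 1242, target 20/5.5) presets use
the published instruments' conventional item counts and response ranges;
their score targets are plausible values chosen by us, not measured ones.
Covariate effect sizes were chosen once to reproduce the direction and
rough magnitude of the group differences such surveys report (e.g. a
~0.9-point male–female gap and a ~4.6-point spread across academic-record
levels on the RSES-like scale) and frozen.

## Missingness mechanism

Missingness is imposed per item cell with a respondent-level probability

    p_i = expit(alpha + sum_d gamma_d * code_d(x_id))   (MAR)
    p_i = r                                             (MCAR)

Drivers are always fully observed covariates — never item values — which is
exactly what makes the mechanism MAR. The intercept `alpha` is solved by
bisection so the sample mean of `p_i` equals the target cell rate to 1e-6
(closed form `logit(r)` when all slopes are zero). Replication `k` of a
plan with master seed `s` draws its mask from
`SeedSequence([s, k, stream])`, so the 50 replications are independently
reproducible.

Driver defaults load on score-relevant covariates (academic record and
communication for RSES-like runs; gender and parental education for
SAQ-like runs) with slopes of 0.4–0.8 per coded step. Two deliberate
choices here:

- slopes large enough that complete-case deletion is visibly biased — the
  point of the benchmark is the regime where the mechanism matters, and at
  these slopes the deletion bias of the mean is of the order the motivating
  comparisons report (~0.5 to ~1.8 points at 5–20%);
- the covariate used as the correlation operand (age) is **not** a driver.
  If the driver and the correlation operand coincide, constant-fill
  imputation corrupts the correlation statistic more than deletion does and
  the characteristic near-equivalence of mode/hot-deck/MI on correlations
  disappears. The benchmark's default design keeps the two roles separate;
  both are configurable.

MNAR is intentionally out of scope: it is unverifiable in real data and the
benchmark design needs a mechanism whose assumptions the imputation methods
can in principle satisfy.

## Handling strategies

- **Deletion** keeps exactly the respondents with no missing item.
- **Mode** fills each cell with its column's most frequent observed value;
  ties break to the smallest value, making the method a pure function.
- **Random hot-deck** partitions respondents into donor classes by the
  joint levels of configured covariates (gender × grade by default for
  RSES-like runs) and fills each missing cell with the value of a donor
  drawn uniformly, with replacement, among class members observed on that
  item. A class with no observed donor for an item falls back to the full
  observed pool for that item and logs the event. Note that cell-wise
  donor draws break within-respondent item correlation, so hot-deck
  attenuates the total-score SD noticeably at high rates — visibly less
  than mode, which is the ordering the benchmark asserts.
- **MI** is a chained-equations engine with predictive-mean matching.
  Missing cells start as random observed-value draws; each of `n_iter`
  sweeps regresses every incomplete item on all other items (current
  values) plus the coded covariates by least squares and refills its
  missing cells with the observed value of one of the `k_pmm` donors whose
  predictions are nearest. Because PMM only copies observed values, ordinal
  range preservation needs no rounding rules. `m` independent chains give
  `m` completed datasets. Defaults `m=20`, `n_iter=10`, `k_pmm=5`.
  Descriptive statistics are averaged across the m datasets; model
  coefficients are pooled by Rubin's rules (q̄, ū, B, T = ū + (1+1/m)B,
  df = (m−1)(1 + ū/((1+1/m)B))², df = ∞ when B = 0) with t-based CIs.

Numerical choices inside MI: the conditional fits solve jittered normal
equations (ridge 1e-8 of the mean diagonal) with an SVD fallback — on
near-collinear designs this shrinks the degenerate direction instead of
failing, and at the fit counts a replicated benchmark needs it is much
faster than SVD throughout. PMM donor search is vectorised over cells via
a sorted-prediction window of 2k candidates.

## Evaluation design

One complete dataset is fixed per scale, so `y_i0` is constant across
replications within a run (the data model still records it per replication).
The three summary statistics are the total-score mean, its sample SD
(denominator n−1), and the Pearson correlation between total score and a
configured covariate (age by default; the operands are configurable). For
MI the replication's statistic is the average over the m completed
datasets; for deletion it is computed on the complete-case subset. The
signed average relative error follows the `(y_i0 − y_ij)/y_i0` orientation
exactly; an absolute-value variant is deliberately not the default.

The validation tier mimics routine survey analysis: one amputation per
rate, hot-deck and MI arms only, group t/F tests per categorical covariate,
and a multiple logistic regression of `total ≥ cutoff` on trend-coded
covariates (a single integer score per multi-level variable — this matches
reporting one OR per variable; dummy sets are out of scope). Outcome
orientation: 1 = high score. Significance is α = 0.05, Wald CIs, no
multiplicity correction. For the MI arm, group means, SDs and test
statistics are averaged across imputations (a stacked variant exists
behind a flag but overstates the effective n); logistic coefficients are
Rubin-pooled.

## What the tests do and do not show

The test suite establishes, at the study's own scale (50 replications,
rates 5–20%, MI m=20): deletion has the largest mean-statistic deviation at
every rate; mode has the largest SD-statistic deviation among the
imputation methods; each method's mean-statistic RMSE is nondecreasing in
the rate (up to one MC standard error); and mode/hot-deck/MI are nearly
equivalent on the correlation statistic while deletion is worse. An MI
parameter-recovery experiment (n = 2000, 20% MAR, 100 replications) checks
that the pooled total-score mean and pooled log-ORs sit within three
per-replication simulation SEs of their complete-data values with matching
signs for strong effects. A caveat worth knowing: although MI recovers
group means and SDs almost exactly, the dichotomized-outcome probabilities
shift by ~0.005–0.008 per stratum (imputation noise redistributes mass
across the cutoff), so pooled log-ORs carry a small but systematic
deviation; an independent chained-equations engine (statsmodels MICE)
reproduces the same shift, i.e. it is a property of the method class, not
of this implementation.

The generator emulates ordinal items, inter-item correlation and
covariate–score structure, but not multidimensional traits, item bias
(DIF), response styles, or covariate–covariate dependence. Passing tests
therefore demonstrate correct mechanics and the expected method ranking
under a clean MAR regime — not performance guarantees on any particular
field dataset, where the mechanism is unknown and possibly MNAR.

## Problem sizes and degenerate inputs

Default problem sizes mirror the emulated surveys (n = 742 / 1242 / 3513);
calibration and marginal checks use n = 50 000–100 000 Monte-Carlo draws;
the replicated benchmark in the test suite runs the full 4 × 4 × 50 grid on
the SAQ-like population. Degenerate inputs fail loudly: zero complete
respondents (deletion), fully missing columns (mode, MI), single-class
outcomes, separation or non-convergence in logistic fits, unattainable
amputation rates. Empty donor classes are the one soft failure (documented
fallback, logged).
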