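# Methods

## Model

Each preprocessed feature *y* (one value per subject) is modelled as
multivariate normal over the cohort,

    y ~ MVN(mu * 1,  Sigma),    Sigma = Vg * A + Vc * H + Ve * I,

with `A` the additive relationship matrix (twice the kinship matrix
computed recursively from parent links, founders unrelated and
non-inbred), `H` the household indicator (1 for subjects sharing a
family), and `Vg, Vc, Ve >= 0`.  The model assumes multivariate
normality of residuals, additive polygenic effects, a single shared
household environment per family, and no dominance, gene–environment
interaction or assortative mating.  Heritability summaries are the
variance shares `h2_max = (Vg+Vc)/(Vg+Vc+Ve)`, `h2_g = Vg/(Vg+Vc+Ve)`
and `c2 = Vc/(Vg+Vc+Ve)`; `h2_max = h2_g + c2` holds identically.

The familial effect is the joint likelihood-ratio test of
`Vg = Vc = 0` against the full model.  The default reference
distribution is chi-square with 2 df, which is conservative because both
parameters sit on the boundary under the null; the
`1/4·chi2_0 + 1/2·chi2_1 + 1/4·chi2_2` mixture is available behind a
flag.  The AE alternative model fixes `Vc = 0` and reports
`Vg/(Vg+Ve)`.

The bivariate model stacks two traits; the cross-trait covariance is
`rho_g*sqrt(Vg1*Vg2)*A + rho_c*sqrt(Vc1*Vc2)*H + rho_e*sqrt(Ve1*Ve2)*I`.
`rho_g`, the genetic correlation, is tested against zero by a df=1 LRT.
When a fitted trait carries numerically no genetic variance
(`Vg < 1e-6 * var(y)`), `rho_g` is reported missing with a
machine-readable reason rather than a number, mirroring the fact that
bivariate fits on real family data frequently fail to return a genetic
correlation.

### Unrecorded-parent convention

A family study often phenotypes the mother and children but not the
father.  By default, children of the same recorded mother whose father
is unrecorded are treated as full siblings — the kinship recursion
routes them through one implicit founder father per (family, mother) —
because the design enrolls biological siblings whether or not the father
was sampled.  `share_unrecorded_fathers=False` restores strict
unique-founder semantics (such children become half siblings).  The
gene-dropping oracle used in the tests implements the same convention
independently.

## Estimation

Likelihoods are evaluated blockwise: families are mutually unrelated, so
`Sigma` is block-diagonal and blocks of equal size are batched through a
stacked Cholesky factorization; the mean (two means in the bivariate
case) is profiled out by GLS inside the likelihood.  The public
`loglik` also offers a dense evaluation used to cross-check the
blockwise path against `scipy.stats.multivariate_normal`.

Free variances are optimized by L-BFGS on a softplus scale (in units of
the sample variance, making fits scale-equivariant), with `Ve` floored
at `1e-8 * var(y)` so `Sigma` stays positive definite.  Three
deterministic starts are used (equal split; genetic-heavy;
environment-only) — no random initialization, so scans are
bit-reproducible.  Because a softplus parameterization cannot reach
zero exactly, the boundary submodels (`Vg = 0`, `Vc = 0`, both) are
fitted explicitly and the best log-likelihood wins, with ties within
1e-6 resolved toward the simpler model.  This makes exact-zero
component estimates representable, which matters: under a true null a
large fraction of features is expected to land exactly at
`h2_max = 0`, and real family panels show heavy mass there.
Correlations in the bivariate fit are optimized on a tanh scale with
|rho| pinned at 0.999999 to keep the stacked covariance positive
definite; starts are rho = 0, +0.5, −0.5.

## Preprocessing

* **Detection filter**: keep features detected (detection p <= threshold,
  boundary inclusive) in at least a given fraction of subjects; the
  default 0.05 / 25% reproduces expression-array practice.  The
  direction of "detected" is a parameter (`at_most` / `at_least`)
  because platforms disagree on whether small or large detection
  p-values mean "seen above background"; the convention default is
  `at_most`.
* **Normalization**: `log2(x + 1)` then quantile normalization across
  subjects (rank-wise means; within-subject ties get the mean of the
  reference values at the tied positions).  This is a deliberate
  simplification of array-specific variance-stabilizing pipelines,
  which need raw bead-level inputs; it preserves the pipeline contract
  (identical per-rank distributions, within-subject rank order) without
  claiming to reproduce any particular vendor transform.
* **Residualization**: per-feature OLS on intercept, batch and
  array-position dummies, sex, centered age, age², sex·age, sex·age²,
  and cell-proportion columns (one dropped for the sum-to-one
  constraint).  Age is centered before squaring to tame collinearity;
  remaining collinear columns are rank-pruned with a warning.
  Residuals are exactly orthogonal to the retained design and
  residualization is idempotent.
* **Deconvolution**: per subject, least squares on the reference
  signature with iterative removal of the most-negative coefficient
  until all are nonnegative, then optional renormalization to
  proportions.  Pruning was chosen over quadratic programming for
  transparency; it recovers noiseless mixtures exactly and agrees with
  true NNLS whenever the solution is interior.  Published reference
  signatures are not redistributed; the simulator ships synthetic
  signatures and user signatures are accepted as TSV.  Proportions (not
  counts) enter the residualization design, since counts would require
  an unavailable per-subject total.

## Cross-omic screen

All pairwise Pearson correlations between two residual matrices are
streamed in column chunks; p-values use the Fisher transformation
(`z = atanh(r)`, `z*sqrt(n-3)` standard normal under the null) and the
Bonferroni denominator is the full grid — zero-variance features stay
in the denominator with missing `r`, so the threshold never depends on
data quality.  Only pairs below a report threshold are materialized;
counts are exact for the whole grid.

## The simulator

`simulate` draws features directly from the model above via a symmetric
eigendecomposition square root of `Sigma` (exact in singular limits such
as a pure shared-environment model), so every downstream estimate has a
known truth.  The study-like preset reproduces the motivating design:
48 subjects in 16 nuclear families (16 mothers, 6 fathers, 26 children),
with the per-family composition (three 3-child, four 2-child, nine
1-child families; fathers placed so father–offspring pairs number 11)
reconstructed from the published pair totals — 13 sibling, 26
mother–offspring, 37 parent–offspring and 1078 unrelated-including-
spouse pairs.  Larger cohorts cycle this composition.  Default variance
shares are Vg = 0.156, Vc = 0.050, Ve = 0.794 (the study's mean
decomposition over all probes) and the paired-feature genetic
correlation defaults to 0.97 (its mean significant |rho_g|).  Covariate
effect sizes default to zero, since none are reported; the pipeline
preset switches them on (sex 0.3, age 0.02/yr, batch 0.3 SD) to give
residualization real work.  Parent ages are uniform on 30–55 y,
children 8–18 y per the eligibility window; child sex is Bernoulli(1/2).
One global seed expands into fixed per-stage substreams so stages can
be regenerated independently; reruns are byte-identical.

What the simulator does *not* emulate: probe-level array artifacts
(beads, dye bias, background), bounded beta-value methylation scales
(features are M-value-like and unbounded), genotypes, linkage
disequilibrium, assortative mating, and realistic annotation geometry
(positions are uniform).  Passing tests therefore demonstrate that the
estimators are correct *under the model* and correctly calibrated at
the study's design size — not that any particular real-data estimate is
right.

## Simulation sizes and numerical tolerances

Chosen once for statistical meaning at desk-scale runtimes, and stated
here as the package's own study conditions:

* likelihood oracle: 100 random draws on pedigrees of <= 12 subjects,
  agreement to 1e-8;
* kinship oracle: gene dropping with 1e5 drops, tolerance 0.01;
* (Vg, Vc, Ve) = (0.4, 0.2, 0.4) recovery: 200 study-like families,
  200 features, mean within 0.05;
* rho_g = 0.9 recovery: 300 families, 100 pairs, mean within 0.1;
* familial-LRT null calibration: 1000 features at the 16-family design
  (rate must not exceed 0.05 + 2 binomial SE; the boundary makes the
  default df=2 reference conservative, observed rates are ~0.01);
* rho_g = 0 calibration: 120 pairs at 60 families, where the
  interior-parameter chi-square(1) asymptotics hold (two-sided
  2-binomial-SE band);
* deconvolution: noiseless recovery to 1e-6; MAE < 0.05 at 10% noise
  over 200 subjects.

Degenerate inputs are handled without exceptions mid-optimization:
zero-variance features yield flagged degenerate fits; singular
covariances return `-inf` log-likelihood; negative LRTs within 1e-8 are
clamped to zero; BH ties follow the standard step-up with enforced
monotonicity.

## Known limitations

* ML (not REML) with an explicitly profiled mean: features are
  pre-residualized, so the lost degrees of freedom are few, but
  absolute component estimates at very small family counts are slightly
  shrunken.
* The pair-classification labels target two-generation nuclear
  families; grandparental and half-sib pairs in exotic pedigrees fall
  through to "unrelated" in the summary table (the relationship
  *matrices* remain exact for any pedigree).
* Table-style pair correlations are computed per feature across pairs
  (the reading whose null expectation matches the observed unrelated
  value); the per-pair-across-features reading is implemented and
  switchable.  Spouse pairs are pooled with unrelated pairs for the
  summary (and also reported separately), the convention consistent
  with the published pair counts.
* The screen's Fisher-Z null assumes exchangeable subjects; related
  subjects reduce the effective sample size, so genome-wide p-values on
  family data are mildly anti-conservative — the reason the bivariate
  follow-up, which models the relatedness, is the inferential
  endpoint.
* With |rho| pinned below 1, a perfectly correlated pair fits
  rho_g ≈ 0.999999, not 1 exactly.
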