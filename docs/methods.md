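# Methods

## Model

A yield record of hybrid j in environment i (a location-year) is

    y_ij = Env_i + sum_{k=0..K} (a_kj + be_kj) phi_k(theta_i) + e_ij

* `Env_i` — fixed environment effect (one level per environment, no global
  intercept, so the effects are directly the environment merits in Mg/ha).
* `theta_i` — the environmental gradient: the environment fixed effect of a
  baseline identity-covariance BLUP model, min-max scaled to [-1, 1]. The
  baseline model deliberately uses an identity (not genomic) covariance for
  the hybrid effect because its purpose is an unbiased environment effect,
  not breeding values.
* `phi_k` — normalized Legendre polynomials,
  `phi_k(t) = sqrt((2k+1)/2) P_k(t)`; K = 1 or 2 in the candidate ladder
  (K = 0 yields the plain-GBLUP arm). Normalized rather than raw
  polynomials are used for conditioning and by random-regression
  convention; the two parameterizations span the same model space.
* `a_j ~ N(0, G (x) C_a)` — additive reaction-norm coefficients, with G
  the VanRaden method-1 genomic relationship matrix
  `G = WW' / (2 sum p(1-p))`, optionally blended `(1-eps)G + eps I`
  (default eps = 0.01) for invertibility.
* `be_j ~ N(0, I (x) C_be)` — the broad-environment term, a repeated-record
  (permanent-environment-like) effect over the spatially repeated records
  of a hybrid; on by default.
* `e_ij` — residual, either homogeneous (`sigma^2`) or heterogeneous with
  the exponential link `sigma^2_i = exp(d0 + d1 theta_i)`, which keeps all
  implied variances positive. Internally the homogeneous model is the same
  link with d1 fixed at 0, so the nested-model comparison is structural.

An optional fixed average-curve regression on theta is reported on request:
with a full environment fixed effect any function of theta per environment
is confounded with it, so the fit itself is unchanged and the coefficients
are reported as the projection of the environment effects onto the
polynomial basis.

## Estimation

Variance components are estimated by average-information REML on the dense
mixed model equations. Records are collapsed to (environment, hybrid) cell
sufficient statistics (count, mean, within-cell sum of squares), which is
exact because residual variance is constant within an environment. Per
iteration the MME are assembled and factored (Cholesky); the gradient uses
the standard trace identities (the prediction-error contraction
`Phi_a[k,l] = sum_{ab} Ginv_ab Cuu[(a,k),(b,l)]` and its identity-matrix
analogue for the broad-environment block), and the AI matrix is built from
the `f = dV/dtheta Py` vectors evaluated at cell level. Updates are damped
Newton steps (Levenberg-Marquardt adaptation) with PSD projection of the
coefficient covariances (eigenvalue floor 1e-8); when a damped AI step
cannot improve the likelihood an EM step is taken (monotone, and also the
fallback when the AI matrix is singular). Convergence is declared at a
maximum relative parameter change < 1e-8 or |delta logL| < 1e-9, cap 200
iterations. If the loop exhausts its budget — typically a solution on the
PSD boundary, where projected AI steps degenerate and derivative precision
limits progress — the fit is finished by L-BFGS-B in an unconstrained
log-Cholesky parameterization with the analytic chain-rule gradient
(dl/dL = 2 (dl/dC) L); a non-decreasing refinement that terminates at the
optimizer's own precision is accepted as converged. Boundary solutions
(for example a rank-deficient C_be when the data carry no broad-environment
signal) are therefore reported at numerical precision rather than erroring.

Starting values are data-driven fractions of the phenotypic variance net of
environment means; the model ladder warm-starts each member from the
previous fit's overlapping blocks.

The REML log-likelihood includes the full constant, so
`-2 logL = (n-p) log 2pi + log|R| + log|Sigma_u| + log|C| + y'Py`; AIC is
`-2 logL + 2k` with k the count of free covariance parameters (upper
triangles of C_a and C_be plus 1 or 2 residual parameters), comparable
across the ladder because all members share the same fixed effects.

Unphenotyped hybrids present in G receive coefficient predictions through
the relationship matrix (they are rows of the MME with no data), which is
what the cross-validation schemes rely on for untested hybrids.

The baseline gradient model and the within-environment reference BLUPs are
two-component REML problems solved by Nelder-Mead on the log-variance
scale over the same MME machinery. A single-environment dataset with no
replication cannot separate the two variances; the reference falls back to
centred hybrid means and flags it.

## Genetic parameters and association analysis

`Sigma = T C_a T'` gives per-environment additive variances (rank <= K+1 by
construction), `h2_i = Sigma_ii / (Sigma_ii + sigma^2_ei)` uses the fitted
residual link (the broad-environment variance is excluded from the
denominator, matching the estimand as printed in the reaction-norm
literature), and the genetic correlation is the standardization of Sigma.
GEBV trajectories use the additive coefficients only.

SNP effects per coefficient are the projection `u_j = Z'(ZZ')^-1 a_j` on
the centred coding Z = M - 2p (the GRM's centring); a pseudo-inverse gives
the minimum-norm solution when ZZ' is singular. The reconstruction
identity Z u = a is exact only for an unblended, full-rank G; two
structural facts matter in practice and are encoded in the tests: crosses
sharing a parent are exactly linearly dependent, and centring by the
panel's own allele frequencies puts the all-ones vector in the null space,
so exact-identity checks use disjoint parent pairs and base-panel
frequencies. With the default blend 0.01 the backsolve is a documented
approximation. Effects are reported for the major allele (negative =>
minor allele favourable). Top-k selection per environment visits SNPs by
decreasing |effect| (ties by chromosome, position) and skips any SNP in LD
above the threshold (default r^2 > 0.2) with the running selection, which
spans all environments processed so far (a per-environment-only mode is
available); pairs beyond the LD window count as not in LD. Allele-state
contrasts average replicates to one value per hybrid and environment,
require every genotype class to hold at least 10 hybrids and the
environment to sit above 0 on the gradient, and use one-way ANOVA followed
by Fisher LSD letters at alpha = 0.05. No multiple-testing correction is
applied by default (a Benjamini-Hochberg option exists upstream of the
reported p-values if needed); this mirrors common practice for these
follow-up contrasts.

## Environment-merit prediction

Daily April-October weather is aggregated monthly per variable — totals
for precipitation and photosynthetically active radiation, maxima for
daily-maximum temperature and wind speed, minima for daily-minimum
temperature and dew point, means otherwise — and combined with five soil
variables at depths 0-5, 5-15 and 15-30 cm into 92 features per
environment. A Random Forest regresses theta (not beta: train and test
then share a bounded scale, with the training (beta_min, beta_max) stored
to move between scales) on these features; hyperparameters are tuned by
10-fold cross-validation over candidate-predictors-per-split in
{p/3, sqrt(p), p/2} and tree counts {250, 500, 1000} — the tuning protocol
is standard, the exact grid is this package's reproducibility choice.
Predictions are clipped to [-1, 1] because the polynomial basis is only
defined on the training domain. Missing features are imputed with training
medians; environments missing more than 20% of features are dropped.

## Cross-validation

Leave-one-year-out. Training records are all records of the other years;
CV0 evaluates every phenotyped hybrid of the test year, CV00 only hybrids
without any training record (removal acts on the evaluated set - their
training records do not exist by definition of the scheme). The test-year
gradient is either predicted from covariates or, in known-gradient mode,
taken from an all-years baseline fit re-scaled with the training-year
merit range (clipped). The plain-GBLUP arm is the same machinery
restricted to an intercept-only basis, homogeneous residual, no
broad-environment term. Accuracy is the per-environment Pearson
correlation of predicted GEBVs with the reference (within-environment
identity BLUPs, or the GEBVs of a model fitted on all years); bias is the
per-environment slope of reference-on-prediction minus one, averaged over
environments. Environments with fewer than three evaluable hybrids are
skipped and reported.

## Synthetic data

The generator draws environment merits uniformly on a span of average
yields (default 4.2-13.5 Mg/ha, the spread typical of large public maize
METs), maps them to the true gradient with the same min-max rule used in
estimation (so truth and estimate share one scale), and simulates
phenotypes from the model above: additive coefficients from the matrix
normal with row covariance the *realized* GRM of the simulated hybrids
(the fitted model is correctly specified; an identity-rows flag supports
misspecification experiments), broad-environment coefficients with
identity rows, and residuals from the exponential link. Parents are fully
homozygous with a MAF spectrum massed just above the 1% bound and LD
decaying with bp distance (latent Gaussian AR process); hybrids are
Mendelian sums of two parents. Incidence is year-structured - each hybrid
is active in a 1-3-year window (probabilities 0.5/0.3/0.2) and appears in
each allowed environment with the configured density - which creates the
hybrid turnover across years that makes CV00 non-empty, with guards that
every environment keeps >= 2 hybrids and every hybrid >= 1 environment.
Outliers (4-6 environment SDs, symmetric) can be injected and are flagged
in the truth bundle so the screening filter's recall is testable. Weather
and soil covariates give two weather variables and one soil variable exact
linear loadings on the z-scored merit plus noise; the rest are seasonal
noise, providing both signal and distractors for the merit model.

Defaults are 150 hybrids x 16 environments x 4 years, 1,000 SNPs from 60
parents, 2 replicates, incidence density 0.25, C_a = diag(0.5, 0.2, 0.05),
C_be = diag(0.1, 0.03, 0.01), d0 = -0.7, d1 = 0.5. The genetic
architecture values are the generative counterparts of the fitted
quantities the analysis targets; the scale is roughly a tenth of a large
public MET, chosen so a full study (ladder fits, ten-seed recovery,
leave-one-year-out evaluation) runs on a laptop. The incidence density of
real METs is not well documented; 0.25 is a default exposed in the
configuration. Parameter-recovery studies in the test suite use 300
hybrids x 24 environments at density 0.5.

What the synthetic data does *not* emulate: field spatial autocorrelation
(the screening stage assumes spatially clean data; the spatial-correction
step of real pipelines is out of scope), dominance and epistasis,
multi-trait structure, genotyping-error processes beyond stray
heterozygous calls and missingness, and realistic weather dynamics beyond
a seasonal curve with linear merit loadings. Passing tests therefore
demonstrate correctness of the estimation machinery under the assumed
model, not robustness to these real-data features.

## Numerical choices and edge cases

* Genotype QC order is fixed: heterozygous calls masked, non-biallelic
  SNPs dropped, MAF < 1% dropped (strict inequality; frequency computed on
  non-missing calls), missingness > 5% dropped; then orientation to
  major-allele counts.
* The naive imputer fills a missing inbred call with the nearest
  homozygote to 2p (ties to the major allele); it biases frequencies by at
  most missing_rate x MAF and is not a haplotype-model substitute.
* Repeatability (the screening threshold names a quantity without a
  formula in common usage) is plot-basis
  `sigma_h^2 / (sigma_h^2 + MSW)` from a one-way method-of-moments
  decomposition over hybrids; environments with no replication anywhere
  are retained, since the screen is undefined there.
* The outlier filter uses each environment's unfiltered mean and SD and
  is applied once, not iterated.
* Gradient scaling errors on zero merit range; out-of-sample scaling
  stores (beta_min, beta_max) and can clip.
* LD is squared Pearson correlation of allele counts within a 100-SNP
  sliding window; zero-variance pairs are skipped and counted. Literature
  thresholds quoted as "r = 0.2" are interpreted as r^2 = 0.2 (the PLINK
  convention); both the pruning and decay thresholds are configurable.
* Ties in top-SNP selection break by (chromosome, position) ascending for
  determinism; environment processing order is sorted.
* All simulation and model seeds derive from explicit integer seeds; the
  pipeline manifest hashes every artifact so a re-run is verifiably
  byte-identical.

## Limitations

* AI-REML is dense; the intended regime is up to a few hundred hybrids
  and tens of environments. The real-data scale (thousands of hybrids,
  ~100 environments) needs sparse or preconditioned solvers that are out
  of scope here.
* Heritability and correlation estimates carry no standard errors.
* The backsolve identity is approximate under GRM blending.
* The CV bias definition (slope - 1) is undefined for zero-variance
  predictions; such environments are skipped.
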