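# Methods

This note documents the statistical model behind `shapevar`, the defaults
it ships with, and the design choices made where several implementations
would have been defensible.

## Shape data and alignment

Input is replicated bilateral 2D landmark data: each individual contributes
two sides (left/right forelegs or similar paired structures), each side
digitized twice. Matching symmetry is assumed — the two sides are separate
configurations, and the left side is mirrored (x -> -x) before alignment.
Which side is reflected is configuration-level and has no effect after
superimposition.

All records enter a single generalized Procrustes analysis: center, scale to
unit centroid size, rotate onto the running consensus by the rotation-only
orthogonal Procrustes solution (SVD with determinant forced to +1), iterate
until the consensus root-mean-square change falls below 1e-10 (cap 100
iterations; typical data converge in 3-5). Partial Procrustes is used: every
aligned record keeps exactly unit centroid size. Centroid size is retained
per record as the size measure for allometry adjustment.

GPA leaves the global orientation arbitrary (it is set by the first record).
Quantities relating two estimates from the same alignment are unaffected;
comparisons against an externally defined frame (simulation truth) first
rotate the aligned dataset onto that frame (`align_to_reference`).

## The tangent-space estimation model

Superimposition removes 4 degrees of freedom (translation 2, rotation 1,
scale 1), so aligned coordinates of k landmarks occupy a (2k - 4)-dimensional
subspace, up to second-order curvature terms. All covariance estimation is
done in an orthonormal basis of the tangent space at the consensus shape and
embedded back to the p = 2k shape-variable space for reporting. This makes
the estimation problem well-posed: in the full p-dimensional space an
unstructured covariance minus a full-rank diagonal error term is always
indefinite along the constraint directions, whereas in the tangent basis
moment and REML estimators sit in the interior for well-conditioned data.
One consequence: "one residual variance per shape variable" becomes one
residual variance per tangent coordinate (the two coincide up to an
orthonormal change of basis that mixes the diagonal; the approximation is
the same kind the heteroscedastic-diagonal model already makes).

## Variance components

With z the tangent coordinates, individual i, side s, replicate r:

    z_{isr} = fixed effects + d_{is} + eps_{isr},
    d ~ N(0, D),  eps ~ N(0, diag(sigma^2))

- **Measurement error** comes from replicate differences within each
  (individual, side) cell: sigma_j^2 = within-cell mean square per
  coordinate.
- **D** comes from signed asymmetry contrasts a_i = mean_r z_{i,right,r} -
  mean_r z_{i,left,r}, residualized on an intercept (directional asymmetry),
  mean log centroid size, and cohort where present. Cov(a) = 2D +
  (1/r_L + 1/r_R) diag(sigma^2), so the moment estimator is
  D = (S_a/df_a - c diag(sigma^2))/2. Individuals are pooled across
  populations and treatments; individual-level effects cancel in the
  contrast, which is the well-conditioned equivalent of fitting individual
  identity as a fixed effect with hundreds of levels.
- **P** comes from individual mean shapes residualized on log centroid
  size, temperature (linear two-level contrast), population and cohort; the
  developmental and measurement noise left by averaging (D/2 +
  diag(sigma^2)/(s r)) is subtracted.
- **G** (broad-sense, full-sib) comes from the between/within family
  decomposition of residualized individual means:
  G = (MS_between - MS_within)/n0, with n0 the effective family size.
  Families with one offspring are dropped. Between-family degrees of freedom
  subtract one per population (population is a between-family fixed effect);
  within-family df subtract the within-family covariates.

Each estimator also has a REML path: the likelihood is the product of
independent Wishart-form pieces (asymmetry scatter, within-cell scatter,
between/within family scatters), maximized by L-BFGS-B over
Cholesky-parameterized covariances and log variances with analytic
gradients, multi-start (default 3), convergence at 1e-14 relative
log-likelihood with bounded log-parameters so flat directions cannot drift.
On balanced designs the REML optimum coincides with the moment estimator;
the test suite verifies agreement to 1e-6 relative Frobenius norm.

Moment estimates are projected to the nearest PSD matrix (eigenvalue
clipping at zero) by default, since downstream log-variance comparisons
require nonnegative projected variances.

### Sampling covariances

For REML-MVN resampling each estimate carries the covariance of
vech(estimate): Wishart asymptotics Cov(V_ij, V_kl) = (V_ik V_jl +
V_il V_jk)/df applied to each scatter, combined by the estimator's linear
form. For P, the naive Wishart with the residual df overstates precision
because individual means are clustered in families; the implementation
splits the scatter into within-family and per-family-size between-family
Wishart pieces, which simulation shows calibrates the variances to within
~10% (the naive version is off by a factor of two at the default design).

### Factor-analytic rank selection

Reduced-rank models C = Lambda Lambda' + diag(psi), Lambda lower-triangular
p x m with non-negative diagonal, psi floored at 1e-10 of the trace, fitted
by the same REML engine. AIC = -2 loglik + 2 (pm - m(m-1)/2 + #psi +
#residual parameters). `select_rank` increases m until AIC rises or a fit
fails to converge and returns the AIC minimizer among converged fits.
Reconstruction returns Lambda Lambda' + diag(psi) by default (the full
implied covariance); a flag gives the common part only — both conventions
exist in the field's reduced-rank software and the full matrix is the one
that plays the role of the covariance downstream.

## Comparing covariance matrices

- **Common-subspace (Krzanowski-style) comparison**: project two matrices on
  the first q eigenvectors of a reference matrix (default: P, q = 6 — the
  rank shared by all matrices in the default design) and correlate the log
  variances. The slope b is the OLS regression of log genetic variances on
  log developmental variances — D is the predictor, so b answers "how much
  genetic variance does a unit of developmental variance predict". Eigenvector
  signs are fixed by the largest-magnitude-element-positive rule.
- **Random skewers**: mean absolute response-vector cosine over random unit
  selection gradients (components uniform on [-1, 1] then normalized, to
  match the convention of the standard implementation; Gaussian-sphere
  sampling available). The analytic null uses cos^2 ~ Beta(1/2, (p-1)/2)
  for independent random directions; a Monte-Carlo null is optional.
- **REML-MVN resampling**: vech of the matrix is drawn from a normal
  centered at the estimate with its sampling covariance; non-PSD draws are
  projected to the nearest PSD matrix and counted (a warning fires if more
  than half the draws are clipped — routine for rank-deficient estimates,
  where the clipped fraction carries no information about the top of the
  spectrum). Resampling is on the covariance-parameter scale, not the log
  scale. FactorModel fits resample through the delta-method covariance of
  the implied matrix from the observed information.
- **BCa intervals**: standard bias-corrected and accelerated form; z0 from
  the fraction of resamples below the observed value, acceleration from the
  jackknife skewness (jackknife over families for statistics involving G).
  With z0 = a = 0 the interval reduces to plain percentiles.

### Known limitation: interval coverage of the subspace correlation

Simulation at the default design (true subspace r = 0.76, between-family
df ~ 49, q = 6) shows the REML-MVN + BCa intervals for r reach ~84-87%
coverage at nominal 95% (1000 draws), not the nominal rate. The mechanism
is a sign mismatch the bootstrap cannot see: the plug-in estimator of r is
biased *upward* (the estimated reference basis chases directions where the
noisy P and G estimates look large together), while resampled statistics
are shifted *downward* relative to the observed value (a second layer of
noise attenuates the log-variance correlation), so BCa's bias-correction
term z0 pushes the interval the wrong way. The draw dispersion itself is
accurate (within-replicate draw SD 0.115 vs true sampling SD 0.114), and
the two shifts are each only ~0.2-0.3 SD, but they add. Joint resampling of
all three matrices from shared scatter-matrix draws (`varcomp.resample_dgp`,
which preserves the strong sampling correlation between the P and G
estimates) and the jackknife acceleration constant were both evaluated and
neither closes the gap; holding the reference basis fixed across draws
makes coverage worse at this alignment level. The interval should therefore
be read as mildly anticonservative for this statistic at this design size.

## Alignment of shape-change vectors

Shape-change vectors are multivariate least-squares coefficients:
the latitudinal vector from family mean shapes (averaged across
temperatures) regressed on latitude with log centroid size partialled out;
the thermal vector from individual mean shapes regressed on a two-level
temperature contrast with log centroid size and population partialled out.

The e_beta statistic is the Rayleigh quotient beta' M beta / |beta|^2 of the
trace-scaled matrix: the fraction of M's total variance captured along
beta, bounded by the extreme eigenvalues of the scaled matrix, equal to 1/p
under isotropy. Significance is one-sided (large e_beta = aligned) against
a null of randomized vectors. The default null permutes the elements of
beta — this preserves the vector's norm and marginal distribution while
destroying its landmark structure, and is exact (p uniform) when the true
vector's direction is exchangeable; isotropic random directions are the
alternative scheme. Angle tests work the same way on theta =
arccos |cos(beta, v)| with small angles counted as aligned; 10 000 resamples
by default.

## The synthetic-data generator

`default_paper_design()` encodes the study conditions the package is built
around: 54 full-sib families x 6 offspring reared in a common garden, each
brood split evenly between 19 and 27 deg C, across 5 populations spanning
latitudes 30.5-42.6 deg N, plus 110 unstructured laboratory-reared
individuals (singleton families, one population) — 434 individuals, each
measured on 2 sides with 2 replicate digitizations (1736 records of 16
shape variables from 8 landmarks).

Ground truth lives in the 12-dimensional tangent space of the mean shape:

- D_true has rank 7 (eigenvalue fractions decaying geometrically, ratio
  0.65). G_true has rank 6; each genetic eigenvector is its developmental
  counterpart rotated by 41.5 degrees toward an orthogonal direction, so the
  gmax-dmax vector correlation is 0.75 by construction — a partial
  developmental-genetic alignment at the level the study system shows —
  with genetic log-variances related to the developmental ones with slope 2
  on the paired axes. E_true (individual-environment) is full-rank with an
  independent eigenstructure.
- Scales are set from the design arithmetic: measurement error SD 0.0025
  per coordinate gives an expected within-cell trace m; trace(D) =
  (F - 1) m / 2 with F = 4.71 the target Goodall F of the asymmetry term;
  among-individual variance (genetic + environment + fixed effects) is set
  so the asymmetry term is an expected 11% of total shape variance.
- The thermal and latitudinal effect vectors are constructed orthogonal to
  dmax with e_beta fixed by construction at 0.087 and 0.076 of the
  trace-scaled D — the generator reproduces a system where plasticity and
  clinal change are *not* channeled along the main axes of developmental
  variability, while G is.
- Directional asymmetry, log-centroid-size allometry (per unit log size),
  and a log-normal size distribution are included; every raw record receives
  an independent random rotation, translation and scale, and left sides are
  stored mirrored, so alignment is non-trivial.

What the generator does not emulate: digitizing error that is absolute in
pixels rather than proportional to size; landmark-specific error structure;
non-Gaussian developmental noise; dominance/maternal structure within the
full-sib covariance; unbalanced family sizes within the common garden.
Passing recovery tests therefore demonstrate correctness of the estimators
under the model's assumptions, not robustness to their violation.

`calibration_design()` is a smaller, fully interior variant (all true
matrices full-rank in tangent space, strong signal) used for
moment-vs-REML agreement checks, where boundary effects would otherwise
confound the comparison.

## Problem sizes used in the test suite

The suite exercises the full 434-individual design for single-run checks;
multi-replicate checks use 20 seeds (parameter recovery, rank selection),
100 replicates (interval coverage), 1000 replicates of cheap statistics
(type-I error calibration at 999 resamples), and n of 750-2000 for
law-of-large-numbers convergence of generator moments. These sizes give
Monte-Carlo error comfortably below the tolerances asserted while keeping
the default run practical on one CPU.
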