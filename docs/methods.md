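# Methods

## The evaluation problem

A saliency map assigns every image location a conspicuity value; a good
map should predict where people fixate. Raw agreement between fixations
and salience is confounded twice: observers fixate near the image center
regardless of content (central fixation bias), and photographs tend to
place salient content near the center (photographer bias). gazegrid
implements a regression-based evaluation that separates the two: scenes
are parcellated into an a-priori grid, each cell contributes a binary
fixated/not-fixated observation per subject and scene, and a generalized
linear mixed model (GLMM) estimates the effect of cell salience on
fixation probability *conditional on* an explicit distance-to-center
predictor, with crossed random effects for subjects and scene items.

## Grid parcellation and responses

Cells are half-open axis-aligned rectangles `[x0, x0+cw) x [y0, y0+ch)`
in 0-based pixel coordinates, so the grid is an exact partition and
every fixation belongs to at most one cell. Image dimensions must be
divisible by the cell size unless right/bottom truncation is explicitly
enabled; silent partial cells would bias per-cell means. The default
geometry is an 8 x 6 grid of 100-px cells on 800 x 600 images. Per cell,
the saliency predictor is the mean of the (per-map min-max normalized)
saliency values under the cell mask; the region abstraction is
mask-based so irregular regions (e.g. object outlines) can be added
later without API changes.

The trial-initial fixation continues from the pre-trial fixation cross,
so it is excluded, and the cell it fell on is excluded from that trial
entirely (revisits to it are discarded). Out-of-image fixations are
dropped with a log message rather than an error, since real
fixation-report exports contain them. Refixations and revisits each
increment the count response; the binary response is the indicator of a
positive count. Missing trials simply contribute no rows.

## Central-bias predictors

All measures act on cell-center offsets `(dx, dy)` from the image
center, in units of half the image width. Seven canonical variants:

| measure | formula | variants |
|---|---|---|
| Euclidean | `sqrt(dx^2 + dy^2/nu)` | nu = 1, h/w, 0.45 |
| Gaussian | `-exp(-dx^2/(2 s2) - dy^2/(2 s2 nu))` | nu = 1, h/w, 0.45 |
| taxicab | `|dx| + |dy|` | — |

Defaults `s2 = 0.23` (horizontal Gaussian variance, in half-image-width
units) and `nu = 0.45` (vertical scaling, giving vertical variance
`0.45 * 0.23 ~ 0.10`) follow published fits of the central fixation bias
in scene viewing; users fitting their own data can supply both. The
Gaussian is negated so that larger values always mean "more peripheral",
keeping the sign of the fitted slope comparable across measures. The
aspect-ratio and anisotropic variants coincide whenever `nu` equals the
inverse aspect ratio. The taxicab measure has no anisotropic variant;
requesting one is an error rather than a silent extension.

## The GLMM and its estimation

For cell `g` of image `m` viewed by subject `s`:

    logit P(fixated) = b0 + b_cb CB_z(m,g) + b_sal S_z(m,g)
                       + z' u_s + z' u_m,     z = (1, CB_z, S_z)
    u_s ~ N(0, Sigma_subject),  u_m ~ N(0, Sigma_item)   (crossed)

Counts use a Poisson log-linear model with the same structure.
Predictors are z-standardized (sample SD, n-1 denominator) over the rows
entering the model, so slopes are comparable within and across models.
Random structures: *maximal* (all variances and correlations), *zcp*
(variances only, zero correlations, the `||` formula syntax),
*intercept-only*, or an explicit term subset for parsimonious models.

Estimation maximizes the Laplace approximation to the marginal
likelihood. Covariance matrices are parameterized by their
lower-triangular Cholesky factors (`theta`, diagonal bounded at zero, so
boundary fits are representable). For fixed `theta`, the spherical
random effects and the fixed effects are found jointly by penalized
iteratively reweighted least squares (PIRLS) with step-halving; the
fixed effects are thus profiled out of the outer problem, which matches
the fast (`nAGQ = 0`) variant of the reference mixed-model fitters. The
outer objective

    dev(theta) = deviance(y, mu) + ||u||^2 + log det(L' Z'WZ L + I)

is minimized by L-BFGS-B with forward-difference gradients (step 1e-5)
from fixed starting values: zero slopes, intercept at the empirical
link-scale mean, identity-scaled Cholesky factors. The fit is fully
deterministic. Cross-products with the sparse random-effect design are
accumulated by per-level indicator matrices whose data vector carries
the IRLS weights, so each iteration is a handful of single-pass sparse
products regardless of the number of random terms.

Convergence: relative penalized-deviance change below 1e-11 in PIRLS
(a failed step-halving is treated as numerical convergence, and steps
that saturate the linear predictor beyond |eta| = 100 — the flat,
clipped-likelihood region where binary deviance carries no gradient
information — are rejected like non-improvements, with a fallback to
the deterministic cold start if a warm-started trajectory degenerates),
relative
objective change below 1e-10 in the outer optimizer by default;
simulation harnesses may relax the outer tolerance to 1e-6 and chain
`theta` starting values across replicates (measured effect on estimates
~5e-5, far below Monte-Carlo noise). Against `glmer` at the same
objective (`nAGQ = 0`) the fitter agrees to ~3e-4 on standardized fixed
effects and ~0.01 in log-likelihood on a 6,912-row test problem; with
the random structure pinned near zero it reproduces an independent IRLS
GLM to better than 1e-9.

Standard errors come from the fixed-effects block of the inverse of the
final weighted joint system (the Schur complement of the random-effects
block); Wald `z = b/SE` with two-sided normal p-values. Likelihood-ratio
tests use `chi2 = 2 (l_full - l_nested)` with df equal to the parameter
count difference and no boundary correction — the field's standard
practice for variance components, reproduced here deliberately even
though it is conservative at the boundary. AIC/BIC count fixed effects
plus variance and correlation parameters. Marginal and conditional R^2
use the linear-predictor decomposition with link-scale residual variance
`pi^2/3` (logit) or `ln(1 + 1/mean(mu))` (Poisson log); the
random-effect contribution of a slope structure is the mean over
observations of `z' Sigma z`. Conditional modes carry conditional
variances from the same system (ignoring fixed-effect uncertainty, the
convention of the reference implementation); 95% prediction intervals
are `mode +- 1.96 sqrt(condvar)`. Boundary fits (variance < 1e-8,
|correlation| > 1 - 1e-4) set a singularity flag, and the parsimony
helper proposes dropping exactly the flagged components.

The saliency-map comparison model stacks the observation table long —
one replicate per map, sharing the response — and uses a treatment-coded
map factor: intercept, central-bias and saliency simple effects for the
reference map, plus map x central-bias and map x saliency interactions
(seven fixed effects for three maps). A map main effect is not included:
the response is identical across replicates, so it carries no
information. Per-map coefficients are recovered by summing the simple
effect and the relevant interaction. The stacked-response structure
means replicates of one observation are not independent; we treat the
comparison model, as is conventional, as a device for estimating and
testing *differences* between maps rather than absolute fit.

## Synthetic data generator

The generator emulates the statistical structure of a scene-viewing
corpus so that every pipeline stage is testable against known truth.

*Saliency maps* are sums of isotropic Gaussian blobs (default 12 blobs,
SD 60 px on 800 x 600 images — a handful of object-scale salient
regions). Blob centers are uniform over the image padded by 2 SD — the
padding keeps the expected saliency stationary inside the image, so zero
photographer bias really yields a zero saliency/centrality correlation —
and are then shrunk toward the center by `1/(1 + kappa)`. `kappa` is the
single photographer-bias knob: the Spearman correlation between per-cell
saliency and center distance decreases monotonically in `kappa`, and
`calibrate_kappa` bisects it into any requested band. The default
`kappa = 0.5` was calibrated once to `rho ~ -0.37`, the modest-bias
regime typical of saliency models without a built-in center preference.

*Fixation data* are sampled from the GLMM itself: per-subject and
per-item effect vectors (intercept, central-bias slope, saliency slope)
are drawn from their covariance matrices, per-cell fixation indicators
(or Poisson counts) are sampled from the resulting linear predictor, and
one fixation point is placed uniformly inside each fixated cell (counts:
one point per counted fixation; binary: an extra Poisson(0.5) number of
refixation points to exercise the counting rules). A central initial
fixation is prepended to every trial to exercise the exclusion rule. The
ground truth — parameters, realized random effects, sampled responses,
initial-fixation cells — is returned alongside.

Defaults mirror the corpus conditions the method was demonstrated on:
42 subjects x 150 scenes, 8 x 6 grid, `b0 = -1.2` (overall fixation
log-odds), `b_cb = -0.6`, `b_sal = 0.7` on the standardized scale,
subject covariances (0.031, 0.026, 0.0025; correlations 0.83/0.43/0.39)
an order of magnitude below item covariances (0.103, 0.081, 0.186;
correlations 0.50/0.20/0.35). Simulation studies in the tests and the
acceptance script use 20 subjects x 30 images.

What the generator does *not* emulate: scanpath structure (saccade
amplitudes, temporal order), within-cell salience structure (points are
cell-uniform), real saliency algorithms, or non-GLMM sources of
overdispersion. Passing tests therefore demonstrate that the pipeline
and fitter are correct and calibrated *under the model*, not that the
model is adequate for any particular real corpus.

## Verification strategy and problem sizes

- Degenerate-structure equivalence: 50 random small GLM datasets, random
  variance pinned at ~0, fixed effects and SEs vs `statsmodels` GLM
  (IRLS) within 1e-4.
- Cross-implementation check: one synthetic dataset vs `lme4::glmer`
  (`nAGQ = 0`) within 2e-3 on fixed effects.
- Parameter recovery: 100 replicates at 20 subjects x 30 images x 48
  cells, maximal structure; the mean estimate of each fixed effect must
  lie within 2 Monte-Carlo standard errors of the generating value.
- Wald calibration: 200 null replicates (`b_sal = 0`, random slopes
  retained with uncorrelated components, zcp fit — the correctly
  specified null model; the maximal and zcp structures give near-identical
  fixed-effect inference on such data); empirical type-I rate must lie
  in 0.05 +- 0.03.
- Photographer bias: `kappa = 0` gives |rho| < 0.1; calibration reaches
  a requested band such as [-0.5, -0.25].
- Pipeline inversion: sampled indicators are reproduced exactly after
  fixation-point emission, grid mapping, exclusion and assembly.

`scripts/acceptance.py` recomputes all of the above; its simulation
components run at 30 recovery and 100 null replicates, a size chosen so
the whole script completes in a few minutes while the Monte-Carlo
checks remain meaningful.

## Known limitations

- The fitter implements the Laplace/PIRLS objective with profiled fixed
  effects; for very small clusters (few observations per subject or
  item) both the Laplace approximation and the profiling bias estimates,
  as they do in the reference tools at `nAGQ = 0`.
- Probit and complementary log-log links, bootstrap and Bayesian
  inference, and fixation-duration (linear mixed model) responses are
  out of scope.
- LRT p-values for variance components ignore the boundary problem (by
  convention); they are conservative.
- `correlate_predictors` treats predictor values as stimulus properties
  (one row per image x cell); it is not a subject-level statistic.
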