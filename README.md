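# gazegrid

Grid-based evaluation of saliency maps against human fixation data with
binomial/Poisson generalized linear mixed models (GLMMs).

## The problem

Saliency models predict where people look in scenes, but two spatial
biases confound naive evaluation: observers fixate near the image
center regardless of content (**central fixation bias**), and
photographs tend to concentrate salient content centrally
(**photographer bias**). A saliency map can therefore "predict"
fixations purely by being central. gazegrid is for vision researchers
who want to know whether a map predicts fixation selection *above and
beyond* centrality — and whether one model is significantly better than
another — using the data at the level of individual observations
instead of image-averaged scores.

## The method

1. Scenes and their saliency maps (grayscale rasters, one per model,
   linked by image ID) are parcellated into a regular grid — by default
   8 x 6 cells of 100 px on 800 x 600 images. Per cell, local saliency
   is the mean of the [0,1]-normalized map under the cell mask.
2. Each cell also gets a distance-to-center predictor. Seven canonical
   variants: Euclidean `sqrt(dx² + dy²/ν)` and negated Gaussian
   `−exp(−dx²/2σ² − dy²/2σ²ν)`, each isotropic (ν = 1), aspect-ratio
   (ν = h/w) or anisotropic (ν = 0.45; σ² = 0.23 in half-image-width
   units), plus the taxicab distance `|dx| + |dy|`.
3. Fixation reports (delimited text: subject, image, index, x/y pixels)
   are coded per trial into per-cell fixated indicators and counts. The
   trial-initial fixation — a continuation of the pre-trial fixation
   cross — is excluded, along with its cell for that whole trial.
4. The long observation table (one row per subject x image x cell) is
   fitted with a binomial-logit GLMM with crossed subject and item
   random effects:

   `fixated ~ cb_z + sal_z + (1 + cb_z + sal_z | subject) + (1 + cb_z + sal_z | image)`

   Standardized slopes, Wald z-tests, likelihood-ratio tests, AIC/BIC,
   marginal/conditional R², conditional modes with prediction intervals,
   and a treatment-coded comparison model for testing differences
   between saliency maps are all provided. The fitter is native
   (penalized IRLS + Laplace approximation, deterministic) and is
   validated against `statsmodels` GLM and `lme4::glmer`.

A seed-deterministic synthetic module generates saliency maps with a
tunable photographer bias and fixation data from a known generative
GLMM, so the entire pipeline is testable without an eye-tracking corpus.

## Worked example

```python
import gazegrid as gg
from gazegrid import glmm

# a synthetic corpus: 12 subjects x 20 scenes, known ground truth
params = gg.GenerativeParams(n_subjects=12, n_images=20)
table, truth = gg.simulate_recovery_table(params, seed=7)

print(gg.correlate_predictors(table, "sal_z", "cb_z"))   # -0.406

spec = gg.parse_formula(
    "fixated ~ cb_z + sal_z + (1 + cb_z + sal_z | subject) + (1 + cb_z + sal_z | image)")
fit = glmm.fit(spec, table)
print(glmm.wald_table(fit))
```

```
                b      se        z    p
intercept -1.0751  0.0775 -13.8718  0.0
cb_z      -0.6181  0.0742  -8.3311  0.0
sal_z      0.5793  0.0661   8.7635  0.0
```

The negative `cb_z` slope says fixation probability drops with distance
from center (about −0.62 log-odds per SD of center distance); the
positive `sal_z` slope says salience predicts fixation selection above
and beyond that (truth here: −0.6 and 0.7; the generating correlation
between saliency and centrality was induced by the photographer-bias
knob). `glmm.marginal_conditional_r2(fit)` gives (0.217, 0.267): fixed
effects explain ~22% of latent-scale variance, subject and item
heterogeneity another ~5%.

## Command line

```sh
gazegrid simulate   --config config.yaml   # synthetic maps + fixation report + truth
gazegrid parcellate --config config.yaml   # grid geometry JSON
gazegrid features   --config config.yaml   # per-cell predictor CSV
gazegrid obsmatrix  --config config.yaml   # assembled + standardized observation CSV
gazegrid fit        --config config.yaml --formula "..." --table obsmatrix.csv
gazegrid evaluate   --config config.yaml   # one-/two-predictor + comparison reports
```

All commands read one YAML config (flags override), write only into the
output directory, copy the effective config there, and log the package
version, config hash and seed. Exit codes: 0 success, 1 user error,
2 internal error.

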