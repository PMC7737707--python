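# Methods

## Scope and model overview

`phenoscreen` analyzes 384-well high-content screens in which each cell
is described by a named attribute vector (16 attributes by default:
cell/nucleus morphology, background-subtracted actin and tubulin
intensities, fiber lengths and intensities, texture, nucleus/cytoplasm
ratio). Three fitted models form the core, each following the
model/results pattern (construct from data, `fit()`, inspect a results
object):

1. **ControlModel** — a robust hyper-ellipsoid for the control
   population of a plate.
2. **MedianEffectModel** — the Chou median-effect dose-response of a
   well-score curve.
3. **CombinationModel** — joint Loewe-additivity or Bliss-independence
   fits of binary dose-pair matrices.

Plate layout modelling, synthetic-data generation, image segmentation
and the CLI are functional modules around these three.

## Control hyper-ellipsoid and Mahalanobis scoring

PCA of the control-cell covariance gives principal axes `V` and
variances `λ`; a cell's squared score is `D² = Σ_k y_k²/λ_k` with
`y = Vᵀ(x − μ)` over the retained axes. On full-rank data this equals
the classical inverse-covariance quadratic form (tested to 1e-8
relative); under rank deficiency the pseudo-inverse through the
retained axes takes over.

**Robustness.** The fit iteratively trims cells whose `D²` exceeds the
chi-square(d) quantile at `trim_quantile` (default 0.975) and refits,
allowing readmission; convergence is declared when the inlier set
repeats (including period-2 oscillation of boundary points). Because
truncating a normal population shrinks its covariance, the trimmed
variances are rescaled by the standard consistency factor
`P(χ²_{d+2} ≤ χ²_{d,q}) / q`; without it the squared scores of fresh
control cells measurably exceed their nominal χ²(d) distribution
(Kolmogorov–Smirnov rejects at n = 5000).

**Retained axes.** Axes with variance below `variance_floor` (default
1e-6) times the mean eigenvalue are dropped and the retained dimension
is reported, never silent. Note a practical consequence: the floor is
relative to the *mean* eigenvalue, so on raw-scale attribute data whose
variances span many orders of magnitude, genuinely informative
small-scale attributes (a texture coefficient next to a total intensity
in camera units) can fall below it. This mirrors what PCA on
unstandardized data does generally; pre-scaling attributes is the
user's choice and the model is equivariant to it on retained axes.

**Contributions.** With `g = Σ⁺(x − μ)`, the signed share of attribute
j is `c_j = (x − μ)_j g_j / D²`; the shares sum to 1 exactly and
ranking `|c_j|` identifies the attributes a treatment changed most.
This additive quadratic-form decomposition is one of several possible
conventions; published per-attribute contribution values from other
implementations use an unstated normalization (three published
example values sum to more than 1) and are not comparable number-for-
number.

**Outliers and well aggregation.** Two distinct rejection rules serve
two distinct purposes. `flag_outliers` flags records against the
*control* model (`D²` beyond the χ²(d) quantile, default 0.999) —
useful for screening control wells and for calibration work. Well
scoring, however, must not reject an entire genuinely shifted treated
population, so `score_well` flags artifacts (bubbles, debris, clumps)
against the *well's own* distance distribution: cells whose robust
z-score — |D − median| over the normal-consistent MAD — exceeds the
two-sided normal quantile matching `outlier_quantile`. The well score
is the median distance over the kept cells, with the MAD reported as
dispersion. The median (rather than mean) aggregate is a deliberate
robustness choice. Controls are pooled per plate; cross-plate
normalization is out of scope.

## Median-effect dose-response

The score-dose relation is `score(D) = A·f + B` with
`f = 1/(1 + (Dm/D)^s)`: `B` is the baseline score at zero dose (for a
Mahalanobis score this is the typical null distance, not 0), `A` the
amplitude at saturation, `Dm` the dose of half effect and `s` the Hill
sigmoidicity. Fitting:

1. `A, B` from the curve extremes (max − min, min). A constant curve
   gives `A = 0` and a non-responsive flag.
2. `f = (score − B)/A` clipped to `[δ, 1 − δ]`, δ = 0.01; points at the
   clip bounds carry no information for the linearization and are
   excluded from it (they re-enter the nonlinear step). The
   least-squares line of `log(1/f − 1)` on `log D` has slope `−s` and
   intercept `s·log Dm`.
3. Damped least squares (`scipy.optimize.least_squares`, trf) refines
   all four parameters from that initialization, with `Dm`
   parametrized on the log scale for conditioning. Bounds:
   `A ∈ [0, 10·range]`, `B ∈ [min − range, min + range]`,
   `Dm ∈ [min dose/100, max dose·100]`, `s ∈ [0.1, 10]`. If refinement
   ever ends above the initialization's residual it is discarded in
   favor of the initial iterate and flagged unconverged.

Duplicates at equal dose are averaged before fitting. Fits with fewer
than 4 points or spanning under 2 dose decades are flagged low
confidence. The fit is equivariant to dose-unit rescaling
(`Dm` scales, `s` invariant, tested to 1e-6). Doses are molar
throughout; `MICROMOLAR`/`NANOMOLAR` constants convert at interfaces.
The screening convention mapping a half-effect *column index* to a
concentration, `10·GI50·3^(1−Dm/2)`, is exposed as
`plates.column_to_concentration`; fitted `Dm` is reported as a
continuous concentration, never snapped to a column.

## Combination analysis

Combination matrices hold duplicate-averaged fractional effects on an
`n₁ × n₂` dose-pair grid plus single-agent edges. Per-drug `(Dm, s)`
pairs come from edge fits; since matrix entries are already fractional,
the edge fits pin `(A, B) = (1, 0)` — a free 4-parameter fit on a
5-point fractional curve is under-determined.

* **Loewe additivity**: `f` solves
  `D1/(Dm1·t^{1/s1}) + D2/(Dm2·t^{1/s2}) = 1`, `t = f/(1−f)`. The
  left side is strictly decreasing in `f`, so bisection on
  `(1e-9, 1 − 1e-9)` (tolerance 1e-8, ≤ 200 iterations) finds the
  unique root deterministically. One published form of this condition
  omits the `Dm` factors from the denominators; dimensional analysis
  and the parameter list of the accompanying Bliss step imply the
  standard Chou form implemented here.
* **Bliss independence**: implemented by default as the *product of
  effect fractions* `f1·f2`, matching the source convention, although
  this predicts a combination weaker than either agent alone at
  matched doses; the usual inclusion-exclusion form `f1 + f2 − f1·f2`
  is available via `convention="inclusion-exclusion"`.
* The fitting surface reduces exactly to the present drug's
  single-agent curve whenever a partner dose is 0, for both models, so
  edges constrain the joint fit coherently.

The joint fit minimizes squared deviations over core grid plus edges
in `(log Dm1, s1, log Dm2, s2)` with bounds as in the dose-response
module. Synergy is summarized by per-cell residuals
(observed − null), the combination index `CI = D1/Dx1 + D2/Dx2` at each
observed effect, and a seeded sign-randomization test of the mean
residual (under the additive null, residuals are symmetric about zero;
1000 sign flips by default). A label-permutation of observed values
across cells would leave the mean residual unchanged, so sign
randomization is the appropriate exchangeable null for this statistic.

## Synthetic data

**Feature level.** Controls are multivariate normal with covariance in
factor form `LLᵀ + diag(σ²)` — positive semidefinite by construction,
with two latent factors imitating the correlated families seen in real
per-cell data (cell size with total stain content; fiber content
across channels). Treatment shifts a chosen attribute subset by
`max_shift · f(D)` with the same median-effect law the fitter assumes
(a deliberately well-specified recovery setting), `f(Dm) = 0.5`
exactly. The default spec emulates a tubulin-depolymerizing phenotype:
tubulin fiber length −4 SD at saturation, tubulin intensities −3/−2.5
SD, texture −2 SD, nuclear content +2 SD, with `Dm = 1 µM` and
`s = 1.5` (typical screening AC50 scale and sigmoidicity), and 1000 is
the nominal plated cells per well in the emulated screen (tests use
150–300 for speed; the statistics scale as √n). Optional multiplicative
lognormal well-level noise (sd 0.05) supports robustness tests.
Per-well seeds are CRC32 hashes of (seed, plate, well): stable across
runs and platforms, independent across wells.

What the generator does *not* emulate: non-Gaussian per-cell
heterogeneity (cell-cycle structure, mixtures), density-dependent
morphology, plate-edge and illumination gradients, or segmentation
errors propagating into the feature table. Passing recovery tests
therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to every real-data pathology.

**Image level.** Fields are ellipses (eccentricity ≤ 0.8, so the
long-axis attribute has nontrivial truth) with a concentric nuclear
disk in the nucleus channel, uniform cytoplasmic fill plus brighter
random-chord fibers in actin/tubulin, Gaussian noise on a flat
background. Placement is rejection sampling with a 3-px margin and
bounded retries. Ground truth records exact masks, areas, long axes,
per-channel signal sums and fiber lengths. No point-spread function,
photon statistics or autofluorescence are modelled.

## Imaging

The original analysis software is proprietary and its algorithms
unpublished, so the segmentation stack is this package's own choice,
documented as replaceable: Gaussian smoothing (σ = 2 px) + Otsu + hole
filling + distance-transform watershed for nuclei; seeded watershed on
the averaged cytoplasmic channels restricted to an above-Otsu
foreground for whole cells (nuclei outside the foreground are flagged,
not dropped). Background per channel per field is the median of
non-cell pixels — robust to dim halos. Fibers: multiscale Sato ridge
filter (scales 1–3 px), threshold at mean + 2 SD of the in-cell
response, skeletonization; length counts axial steps as 1 and diagonal
steps as √2. Texture is the within-cell coefficient of variation of
tubulin intensity — an approximation, as the attribute's original
definition is unpublished. Size filters default to 50–5000 px² at the
synthetic scale. All operations are deterministic.

## Numerical choices and degenerate inputs

- Zero-variance attribute sets and too-few controls are rejected with
  diagnostics; rank deficiency reduces the retained dimension instead
  of failing.
- Contributions are undefined at `D = 0` (no direction) and error
  explicitly.
- The median-effect fractional effect is evaluated in logistic form
  `expit(s·(log D − log Dm))`, stable at extreme dose ratios; `f(0)=0`
  by convention.
- Bisection (not Newton) for the Loewe root: monotone, derivative-free,
  deterministic.
- Empty wells produce NaN scores flagged `empty`, never silent drops.

## Problem sizes in the test and acceptance suites

Control-model calibration uses 3000 fitting cells and 5000 fresh
cells; oracle equivalence covers 100 random 8-attribute instances;
Monte-Carlo dose-response recovery runs 100 noise seeds on 10-point
curves; the imaging round trip renders 15-cell 512×512 fields; plate
simulations use 150–300 cells per well. These sizes make every suite
reproducible in seconds to minutes on a single CPU while keeping the
statistical checks (KS calibration, 4·SE mean checks, ≥95% ranking
rates) well-powered.

## Known limitations

- Table-level numeric parity with published per-drug AC50 columns and
  contribution values is out of scope: those derive from the original
  raw images (terabytes, unavailable), and the contribution
  normalization used there is unstated.
- The variance-floor interaction with raw-scale attributes (above) can
  demote small-scale attributes; standardize inputs if that matters
  for your data.
- Per-well artifact rejection is a 1-D robust rule on the distance
  distribution, not a full per-well hyper-ellipsoid refit.
- Single 2-D fields only; no stitching, 3-D, time-lapse tracking or
  illumination correction.
- Combination analysis is binary only and limited to the Loewe/Bliss
  nulls; no ZIP/HSA-style response-surface models.
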