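# Methods

`tmplkit` implements a complete, testable analogue of a population-specific
brain-template study: a synthetic population generator, the preprocessing
chain, diffeomorphic registration, groupwise unbiased template construction,
per-voxel deformation metrics, and region-wise paired statistics comparing
templates. This note records the models, the defaults and why, the numerical
choices, and what the synthetic setting does and does not establish.

## The scientific procedure

Spatial normalization warps an individual scan onto a template so that
homologous structures coincide. The deformation this imposes is the study's
measurand: a template closer to the population's anatomy requires smaller
deformations. Two per-voxel metrics quantify it:

* **displacement magnitude** `‖u(x)·s‖₂` in mm (s = voxel spacing) — how far
  a voxel moves;
* **Jacobian determinant** `J(x) = det(I + ∇u(x))` — the local volume-change
  factor of `φ(x) = x + u(x)`; `log J > 0` is expansion, `< 0` contraction,
  and region summaries use `|log J|` so expansion and contraction do not
  cancel. The natural log is used throughout (column metadata records the
  base).

Templates built from a larger sample, or from the subject's own population,
should yield smaller values of both metrics on held-out subjects. The
package reproduces these two effects directionally on synthetic populations
and provides the statistical machinery (per-region paired t-tests with
Bonferroni control) used to compare templates.

## Deformation model

Deformations are exponentials of stationary velocity fields (SVF): a voxel-
wise velocity `v` generates `φ = exp(v)` by scaling and squaring (`u₀ =
v/2^N` followed by `N` self-compositions, `N` chosen so the initial step
moves ≤ 0.5 voxel). This guarantees the properties the analysis rests on —
`φ` is diffeomorphic, `exp(−v)` is its inverse, `J > 0` — with a mechanism
simple enough to verify against a brute-force Euler flow integration (the
test suite checks < 0.05 voxel max discrepancy vs 1024 Euler steps, and
< 0.1 voxel mean inverse-composition residual).

All displacement fields use the backward (pull-back) convention — the
output-grid voxel `x` samples the input at `x + u(x)` — in voxel units and
index order. The convention is written into each field's on-disk JSON
sidecar. Interpolation clamps to the edge (replicate); Jacobians use central
differences with one-sided stencils at the boundary, and boundary voxels are
excluded from "interior" assertions.

## Pairwise registration

Registration is greedy multiresolution diffeomorphic demons on the SVF:
per iteration, the classic intensity-normalised demons force
`f = Σ_c w_c (M_c∘φ − F_c)·∇(M_c∘φ) / (‖∇‖² + diff² + ε)` is computed from
the currently warped moving channels, smoothed with a Gaussian (fluid-like),
applied with a step size, and the accumulated velocity is smoothed again
(diffusion-like). A candidate step that raises the channel-weighted SSD is
rejected and the step halved, so the reported similarity trace is monotone
non-increasing within each pyramid level; because re-smoothing the
accumulated velocity means a zero step cannot reproduce the current state, a
persistently rejected step is treated as level convergence, and an error is
raised only for genuine divergence (candidate worse than both twice the
current value and the level's start).

Defaults: 3 pyramid levels, iterations (30, 20, 10), update step 1.5,
velocity smoothing 2× the fine voxel spacing, squaring depth automatic.
These converge on 64³ phantoms in seconds. T1 and the three tissue
probability maps are registered jointly with equal channel weights: the
original pipeline registers the channels separately but constrains them to a
common space, which joint multichannel registration enforces by
construction (the weight vector is configurable).

The multiresolution pyramid downsamples by factor-2 with Gaussian
anti-aliasing; velocities are upsampled between levels with their components
rescaled by the grid factor. Warm-starting from a prior velocity is
available (used optionally by the groupwise builder; see below).

## Groupwise template construction

The builder iterates mean-and-register with an `(outer, inner)` schedule,
default (6, 6):

1. **Initial import** — every subject is rigid + isotropic-scale aligned to
   the first subject's grid by moments (centroid, principal axes, head-mask
   volume for the scale), all channels resampled onto one grid.
2. **template⁰** = voxelwise mean of the imported channels.
3. Each outer iteration: register every subject to the current template
   (`inner` demons iterations per pyramid level), warp the subjects into
   template space, average, then **recentre**: warp the average by
   `exp(−v̄)` where `v̄` is the voxelwise mean of the per-subject velocities.
   Averaging in velocity space keeps the recentring map diffeomorphic; the
   source procedure's "inverse mean deformation" update is not fully
   specified, and this is the standard construction with that guarantee.
4. The final template carries the last outer iteration's per-subject
   deformations; intermediate templates can be written via a snapshot
   callback.

The history records, per outer iteration, the **template drift** — the mean
magnitude over a fixed brain mask of the voxelwise-mean subject
displacement, i.e. the component recentring drives toward zero — together
with the mean per-subject displacement, mean similarity and template
sharpness (mean gradient magnitude over the mask). Drift is the convergence
diagnostic: it decreases as the template moves to the population's
geometric centre and its floor is the registration estimation noise of a
mean of n fields. The per-subject displacement instead plateaus at the
population's irreducible anatomical variability. The evaluation mask is
frozen at iteration 0 so history rows are comparable.

Registrations restart cold each outer iteration by default, so each history
row spends identical registration effort and rows are comparable. With
`warm_start=True` each subject's velocity continues across outer iterations;
cumulative convergence then drives both displacement series *upward* toward
the population's full deformation scale — useful for maximal-accuracy
registration, wrong for a like-for-like convergence trace, which is why it
is off by default.

## Synthetic phantom population

The generator emulates the statistical structure of an age/sex-balanced
elderly cohort, not MRI physics:

* **Anatomy**: an ellipsoidal brain (default semi-axes width 66 / length 81
  / height 50 mm → extents 132 × 162 × 100 mm, inside the observed ranges
  of an elderly East-Asian cohort) with a gray-matter shell (outer 15%
  radial fraction), white-matter core, fluid ventricle, and mirrored
  thalamus-, hippocampus- and parahippocampal-like blobs plus a
  cerebellum-like blob. Axis 0 = length (A-P), axis 1 = width (L-R),
  axis 2 = height (I-S).
* **Demographics**: five age strata, each with equal numbers of men and
  women (default 20 + 20, the development-cohort design; tests use smaller
  counts). The sex effect is a single global isotropic scale (default 1.04
  on male anatomy, matching the observed male > female extents with stable
  shape ratios); the age effect is an optional per-stratum linear shrink
  (default 0 — observed extents are stable across strata).
* **Inter-subject variability**: the exponential of a Gaussian-smoothed
  white-noise velocity (correlation length `warp_smoothness_mm` = 12 mm),
  scaled so the mean displacement magnitude is `warp_sd_mm` = 2 mm. No
  quantitative inter-subject deformation scale is available for the cohort;
  2 mm is a free parameter chosen as a plausible elderly-population scale
  and exposed in configuration. Warps with non-positive interior Jacobians
  are redrawn with 0.7× amplitude (at most 5 attempts).
* **Intensity model**: class intensities fluid/gray/white = 0.3/0.6/0.9,
  multiplied by the exponential of a zero-mean random degree-2 polynomial
  (amplitude 0.2 — a realistic ±20% shading) and degraded with additive
  Gaussian noise (σ = 0.03).
* **Ground truth**: each subject records the velocity/warp that generated
  it (`true_warp`, backward convention, mapping its demographic reference
  anatomy to the subject) and its clean rendering, enabling recovery
  oracles. The deterministic sex/stratum scale is metadata, not part of
  `true_warp`, so the warp sampler is centred by construction.
* **Atlas**: a deterministic parcellation of the mean anatomy — one label
  per named structure (left/right separate) plus an octant parcellation of
  remaining brain tissue; 16 regions by default, volumes from exact voxel
  counts.

Subjects are rendered by evaluating the analytic anatomy at warped
coordinates (no interpolation blur), and identical inputs give bit-identical
subjects (`SeedSequence`-derived per-subject seeds).

Default grids: 64³ at 3 mm for tests, 128³ at 1.5 mm for demo runs; 1 mm
resolution is configuration, not default — the method is resolution-
agnostic and desk-scale grids keep the full pipeline in CI minutes.

## Preprocessing

* **Reorientation**: landmark-based canonical orientation is replaced by
  principal-axis alignment (largest moment → length axis, second → width,
  third → height; centroid → grid centre), since phantoms have no
  commissures. Near-degenerate moments (adjacent eigenvalue ratio < 1.05,
  e.g. a sphere) keep the identity rotation with a warning.
* **Isotropic reslicing** to a target spacing preserves world extents
  (linear or nearest interpolation; nearest mandatory for labels).
* **Bias correction** fits a degree-2 polynomial to log-intensities inside
  a mask, *detrended by per-class intensity offsets* (1D k-means levels
  alternating with the fit, 4 rounds): without the detrending, the
  polynomial absorbs the phantom's genuine radial intensity structure. The
  corrected image keeps the original mask mean exactly; `vol = corrected ×
  bias` holds identically. The source pipeline does not name its algorithm;
  this is the package's choice.
* **Segmentation** is a 1D Gaussian-mixture EM inside the mask (k-means++-
  style init, tol 1e-6, ≤ 200 iterations), classes ordered by ascending
  mean, background = 1 − mask — an atlas-prior-free stand-in for prior-based
  tissue segmentation, sufficient for three well-separated phantom classes.
* **Extents** are world-space bounding-box lengths along grid axes
  ((max − min + 1) × spacing) with W/L, H/L, H/W ratios; the default mask
  threshold is 10% of the 99th intensity percentile (robust to the noise
  floor).

## Region statistics and template comparison

Metric maps are computed in each template's space and transported to one
common reference grid (default: template A) through a bridge deformation
obtained by registering the template's T1 channel to the reference's;
averaging across subjects happens only after transport, so all statistics
live in one frame. Regions smaller than 500 mm³ are excluded; region means
ignore missing voxels (non-positive determinants) and report voxel counts.

Per-subject region means are the paired observations: per region and metric
a two-sided paired t-test compares templates, with the Bonferroni threshold
α/m where m is the number of regions actually retained after the volume
filter for that metric family (m is derived from the data rather than
hard-coded, since published thresholds do not always match published region
counts). A region is flagged directional only when significant with a
strict mean inequality; self-comparison is exactly null (identical pairs →
t = 0, p = 1).

## Experiment designs (desk scale)

`tmplkit.experiment` runs three designs at 48³ / 4 mm with a reduced (2, 3)
schedule and 2-level registration pyramids (the coarsest level of a 48³
grid at 3 levels is 12³, too small to help):

* **Population matching**: template A from the validation population,
  template B from a shifted population (length +4%, width −4%,
  parahippocampal blobs ×1.5 — the analogue of documented between-
  population brain-shape differences); 12 + 12 template subjects, 10
  held-out validation subjects.
* **Sample size**: templates from n = 24 vs n = 8 of one population, 10
  held-out subjects, compared on mean brain-mask displacement.
* **Null calibration**: both templates from disjoint same-population
  samples (n = 4 per arm, 6 validation subjects), 20 repetitions; the
  family-wise fraction of repetitions with any Bonferroni-significant
  region is recorded alongside the pooled fraction of significant region
  tests.

  This design is *not* a true null: two templates built from four subjects
  each genuinely differ (mean-shape sampling error ≈ warp_sd/√n ≈ 1 mm),
  and because per-subject region means average thousands of voxels, the
  paired t-test has enough precision to detect those real differences —
  roughly half the repetitions flag at least one region. The calibration
  of the statistical machinery itself is therefore established separately:
  self-comparison of one template is exactly null (0 significant regions,
  deterministic), and a pure-statistics simulation (2000 families of iid
  region data) confirms the family-wise error of paired t + Bonferroni
  stays below α. Making the template-pair design an approximate null would
  require per-arm samples large enough (n ≳ 16–64) that template sampling
  differences fall below detection, which is outside desk-scale runtime.

Problem sizes were chosen so each design runs in minutes on one CPU while
leaving the qualitative contrasts (matched < mismatched, large-n < small-n,
null ≈ nothing significant) clearly resolved.

## What passing tests do and do not show

The phantoms share the generator's smooth-warp model with the registration's
deformation model, have exactly three well-separated tissue classes, crisp
edges, no skull/neck, no cortical folding, and bias fields inside the
correction's model class. Passing tests therefore validate the *machinery*
— geometry, metrics, statistics, convergence behaviour, effect directions —
not performance on real MRI. Real-data effect sizes, segmentation accuracy
and bias-correction adequacy cannot be inferred from these results.

## Known limitations

* SSD similarity only; no mutual information, so no cross-modality use.
* The demons scheme is a stand-in for the original membrane-energy
  flow-field optimisation; bit-compatibility with that pipeline is a
  non-goal.
* The intensity mixture has no spatial priors and will not segment
  realistic brain MRI.
* `region_summary` assumes atlas and maps share one grid; atlas transport
  between spaces is the caller's responsibility (the experiment designs
  use the generator's atlas on the common reference grid, which matches it
  up to template-construction residuals).
* History drift has an estimation-noise floor (≈ 0.1–0.3 mm at desk scale);
  its decrease is meaningful only well above that floor.
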