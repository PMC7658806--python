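# Methods

`layerlearn` re-implements, as a tested and reusable pipeline, a laminar
(cortical-depth-resolved) fMRI analysis of perceptual-learning
plasticity: equi-volume layer assignment, vascular-bias correction,
layer-wise multivoxel decoding, layer-to-layer informational
connectivity between a sensory and a decision region, and
adaptive-staircase behavioral analysis. Because sub-millimeter 7T data
cannot be assumed on a reviewer's desk, every analysis is exercised
end-to-end on a synthetic laminar BOLD generator with known ground
truth. This note documents the models, parameters, and design choices.

## Cortical geometry and equi-volume layers

A cortical patch is modeled per *column*: a straight segment from the
white-matter boundary (depth 0) to the pial surface (depth 1) with local
thickness `T` (mm) and signed curvature `c` (1/mm). The cross-sectional
area of the sheet is taken to vary linearly with depth,
`A(x) = A0 (1 + c x)` — exact for a cylindrically folded sheet with
white-matter radius `1/c`, first-order correct in general. The
cumulative volume `V(x) = A0 (x + c x²/2)` then gives the equi-volume
depth of grid `k` of `n` in closed form from
`V(x_k) = (k/(n−1)) V(T)`:

    x_k = (sqrt(1 + 2 c f_k (T + c T²/2)) − 1) / c,   f_k = k/(n−1),

falling back to `x_k = f_k T` (equidistant) at `c = 0`. Four grids bound
three equal-volume compartments mapped onto *deeper*, *middle*,
*superficial*. Voxels are assigned by Euclidean distance to the grids
along their column: the two nearest grids bound the compartment; a voxel
exactly on an interior grid goes to the deeper compartment (stable,
documented tie-break). The closed form is validated against numeric
volume bisection of a concentric wedge (white radius 10 mm, pial 12 mm)
to 1e-6.

With positive curvature (area growing toward the pial surface) the
interior grids shift *toward the pial surface*: low-area depths near the
white matter need more distance to accumulate each equal volume share.

## Synthetic laminar BOLD

Per gray voxel `v` and TR `t`:

    y_v(t) = B_v + bias_v · [act_v(t) + pat_v(t) + drain_v(t)] + ε_v(t)

- **Baseline** `B_v = 100` (×0.6 for vein voxels).
- **Stimulus response** `act_v`: one boxcar per 12.36-s condition block
  convolved with a double-gamma canonical HRF (gamma peak at 6 s,
  undershoot at 16 s, undershoot ratio 1/6, unit peak). The source
  analyses extracted responses by TR window rather than deconvolution,
  so no HRF is prescribed there; the double-gamma form is the standard
  choice and is used identically by the simulator and the GLM
  (self-consistency). Activation amplitude 2% signal change, times a
  per-voxel location gain (1.5/0.5 for preferred/non-preferred hemifield
  in lateralized regions) — this gives the left-vs-right localizer
  contrast its ground truth.
- **Pattern signal** `pat_v`: per condition (orientation × location), a
  fixed N(0,1) voxel weight map drawn from `pattern_seed`, scaled by the
  pattern amplitude (default 0.04% per voxel), injected at configured
  depths. The session gain (default 4.0 post-training) multiplies the
  target layer's pattern *for the trained orientation only*: learning
  that is not orientation-specific would raise trained and untrained
  decoding equally and could not produce the improvement-index
  separation the pipeline is designed to detect.
- **Superficial bias** `bias_v = 1 + (g_s − 1)·depth_v` with
  `g_s = 2` by default — the linear amplitude increase of gradient-echo
  BOLD toward the pial surface.
- **Drainage** `drain_v`: superficial voxels receive `λ` (default 0.3)
  times the mean clean signal of middle/deeper voxels in the same
  column — ascending-vein mixing. With zero noise this is an exact
  linear mixing equation, which the tests verify in closed form.
- **Veins**: a random fraction (10%) of voxels, mildly biased toward the
  surface, get noise variance ×4 and baseline ×0.6, giving tSNR-based
  exclusion a ground truth.
- **Noise** `ε_v`: voxel-wise AR(1) Gaussian (lag-1 coefficient 0.3), sd
  3% — i.e. tSNR ≈ 33 after averaging, a realistic figure for
  high-resolution protocols after preprocessing.
- **Block-to-block fluctuations**: each layer's pattern amplitude is
  jittered per block by `g_b = max(0, 1 + σ z_b)`, `z` standard normal,
  `σ = 0.6`. For two regions the `z` series of one designated layer pair
  are drawn from a bivariate normal with correlation `ρ` on blocks of
  the coupled (trained) orientation — the ground truth for
  informational connectivity (`ρ` = 0 pre, 0.8 post by default).

**Block design.** TR 2.06 s; blocks of 12.36 s (exactly 6 TR); six
conditions (three orientations: trained / untrained / control, at two
locations) plus fixation; each run opens with fixation and repeats
(six condition blocks + fixation) four times, orientation order
randomized and location alternating between blocks; 8 runs per session
by default; sessions *pre* and *post*.

**Calibration of the regime.** Amplitude, noise and gain were fixed once
so that (a) pre-training decoding sits near the 55–65% range that
block-design orientation decoding typically yields, and (b) the injected
laminar and connectivity effects are recoverable at the study's own
scale (12 subjects, 8 runs, 64 test blocks per task and session), where
the binomial noise floor of a 64-block accuracy estimate is ≈6%. These
are the generator's study conditions; they are not adjusted per test.

## Vascular correction

1. **tSNR screening**: temporal mean / temporal SD per voxel, averaged
   over runs; constant time courses are undefined and excluded.
2. **Joint exclusion**: voxels below the 10th within-ROI tSNR percentile
   (the low-tSNR cut is inspection-based in practice and not numeric;
   the default mirrors the t-rule symmetrically and is configurable) OR
   above the 90th percentile of the stimulation-GLM t distribution are
   removed. Percentiles use linear interpolation; comparisons are
   strict.
3. **Z-scoring**: per run and voxel, population-SD convention
   (`ddof=0`; a two-point series [1, 3] maps to [−1, 1]).
4. **Spatial regression**: each superficial voxel is matched to its
   nearest middle-layer voxel (Euclidean distance in mm; ties to the
   lowest index; many-to-one allowed); the mean time course of the
   matched (unique) middle donors is regressed out of every superficial
   voxel per run (single regressor + intercept), residuals replacing the
   superficial time courses. OLS guarantees residual⊥regressor at
   machine precision.

## Response extraction and decoding

The voxel-ranking GLM regresses the signal on HRF-convolved condition
boxcars, optional nuisance columns, and run-specific intercepts, with
the localizer contrast left-vs-right (visual cortex, lateralized) or
all-stimuli-vs-fixation (IPS, bilateral). Patterns are the per-voxel
mean of the z-scored signal over the **4th–8th TR** (1-based, inclusive)
after block onset — offsets +3..+7, i.e. 6.18–14.42 s at TR 2.06 s; the
1-based ordinal convention is the only one that reproduces those
seconds, and is pinned by test.

Voxels are ranked by the localizer t (orthogonal to orientation labels —
selection can never leak class information) and the top 500 (visual) /
200 (IPS; and 200 for any between-region comparison) retained. A linear
maximum-margin classifier (SVC, C = 1; the regularization constant is
not prescribed by the source analyses and is pinned in config)
discriminates trained-vs-control and untrained-vs-control at the
trained location under leave-one-run-out cross-validation; accuracy is
averaged over folds with equal weight. Decision values `w·x + b` vote
for the first class when ≥ 0. The shuffled-label null permutes training
labels within fold (test labels intact) and uses the add-one rule
`p = (1 + #{null ≥ obs}) / (n_perm + 1)`.

Learning indices: decoding MPI `=(post − pre)/pre × 100`; behavioral MPI
`=(pre − post)/pre × 100` on thresholds (improvement is a *decrease* in
threshold but an *increase* in accuracy). The correlation-based pattern
index is the fold-averaged Fisher-z difference between same-orientation
and different-orientation Spearman correlations of train/test class-mean
patterns across voxels, with |r| capped at 1 − 1e-15 to keep z finite.

## Informational connectivity

For each (ROI, layer, session, task), the held-out test patterns of
every cross-validation fold are projected onto that fold's hyperplane:
`d = (w·x + b)/‖w‖`, signed toward the pattern's true class (positive =
discriminable). Normalized distances are used; rank correlations are
invariant to the monotone rescaling, so the raw decision value would
give identical rhos. Folds are concatenated in run/block order into one
series per layer. Connectivity between region layers is the partial
Spearman correlation: rank-transform (average ranks), residualize each
side's ranks on the ranks of its own region's other two layers
(+intercept), Pearson-correlate the residuals, Fisher-z transform.

Two pathways are contrasted: **feedforward** (sensory superficial →
decision middle, the ascending-projection route) and **feedback**
(deeper ↔ deeper). The sensory-superficial ↔ decision-deeper pair is
deliberately not analyzed: it mixes feedforward and feedback
contributions. Learning-dependent change is `Δz = z_post − z_pre` per
pathway × condition.

## Staircase behavior

3-down-1-up transformed staircase: the level (angle difference, deg)
is divided by the step factor (default 1.2, ≈0.79 dB) after three
consecutive correct responses and multiplied by it after any error;
reversals are direction flips of the level change (the first trial is
never a reversal); termination at 15 reversals; threshold = mean level
of the last 8 reversals; start level 5°, level clipped to
[0.01°, 45°]. The rule converges where `p³ = 1/2`, i.e.
`p = (1/2)^(1/3) ≈ 79.4%`, independent of the observer's psychometric
shape. Step sizes are unreported in the source experiment and are
config parameters; they affect the spread, not the fixed point.

The simulated observer is 2AFC:
`p(x) = 0.5 + (0.5 − lapse) · F(x)` with `F` a cumulative Gaussian
(`Φ((x − θ)/(θ/slope))`, criterion `p(θ) = 0.75 − lapse/2`) or Weibull
(`1 − exp(−(x/θ)^slope)`, criterion `p(θ) = 0.5 + (0.5 − lapse)(1 −
1/e)`). One empirical caveat found while testing: under a fixed
multiplicative step, a steeper slope tightens the *threshold* spread but
widens the *converged-accuracy* spread, because the steeper level→p
mapping amplifies the residual level oscillation; the test suite asserts
the level-domain tightening.

## Within-subject inference

The repeated-measures ANOVA (1–3 fully crossed within factors, one
value per cell per subject) uses the classical partitioning: for every
effect, `F = MS_effect / MS_(effect × subject)`, built from marginal
totals by inclusion–exclusion — hand-verifiable, and cross-checked in
the tests against independent library implementations. Effects with
zero sum of squares report F = 0, p = 1. Greenhouse–Geisser correction
is available per effect but off by default (not used by the source
analyses). Paired t-tests flag zero-variance nonzero differences as
degenerate (infinite t). FDR is Benjamini–Hochberg step-up.

The recovery suites operationalize "effect present in the superficial
layer only" as: paired t on per-subject MPI(trained) − MPI(untrained),
one-sided p < 0.05 in superficial, and two-sided p ≥ 0.01 in middle and
deeper. The stricter α for declaring an (unexpected) deep-layer effect
keeps the joint false-alarm rate of the two null layers near 2%, so a
≥90%-of-cohorts recovery bound is statistically attainable; with α=0.05
everywhere the expected pass rate would be capped near 0.90 by the null
layers alone.

## Problem sizes and what the tests show

The test-bed patch is 15×15 columns × 3 depth voxels (0.8 mm isotropic,
2.4 mm thickness) — one voxel per layer per column, ~150–200 usable
voxels per layer after exclusion; cohorts are 12 subjects; recovery
suites run 20 replicate cohorts. These sizes are the package's choice of
desk-scale study conditions.

The generator emulates block-design laminar BOLD with superficial bias,
drainage mixing, vein voxels, autocorrelated thermal noise, and shared
discriminability fluctuations. It does **not** emulate: spatially
correlated (physiological) noise, MR physics (T2* decay, k-space
sampling, distortion), head motion, between-subject anatomical
variability, or eye movements. Passing recovery tests therefore show
that the analysis correctly inverts this forward model at realistic
SNR — not that real 7T data would yield the same effect sizes.

## Numerical choices

- Onsets are mapped to the TR grid by nearest-TR rounding (12.36 s = 6
  TR exactly at 2.06 s).
- Percentile exclusions: NumPy linear interpolation, strict
  inequalities.
- Fisher z cap |r| ≤ 1 − 1e-15.
- Nearest-neighbor ties: lowest voxel index.
- Constant series (zero variance) are flagged/excluded rather than
  divided through; degenerate statistics are flagged, not silently
  propagated.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical configs and seeds reproduce every table bit-
  identically.

## Known limitations

- The column-based equi-volume solver assumes straight columns and a
  linear area profile; mesh-based solvers handle general geometry.
- The latent-fluctuation coupling is a block-wise multiplicative jitter
  with bivariate-Gaussian structure — the simplest model realizing
  shared discriminability fluctuations; real informational connectivity
  presumably has richer temporal structure.
- The ANOVA requires complete, balanced within-subject tables; missing
  cells are an error by design (no imputation).
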