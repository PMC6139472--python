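# Methods

## The analysis in one pass

Per subject, the pipeline maps a 4D BOLD run plus a trial table to 120
connectivity features, then classifies subjects across the cohort:

1. **Nodes.** Each of the 16 nodes is the 3×3×3-voxel cube centred on
   the voxel nearest a stereotaxic coordinate.  Coordinates given in
   Talairach space are first converted to MNI with the Lacadie best-fit
   affine (the exact matrix inverse is used for the reverse direction;
   the transform is injectable for other conventions).  Conversion
   happens *before* snapping to the voxel grid; snapping rounds each
   fractional voxel coordinate half-away-from-zero.  A cube that would
   be clipped by the grid raises — there is no silent truncation.
   Conventions everywhere: RAS+ millimetres, 0-based voxel indices,
   cube voxels stored in lexicographic order.
2. **Deconvolution.** Voxel series are detrended and then deconvolved
   against the canonical double-gamma HRF: the BOLD model is x = Hn
   with H the causal Toeplitz operator, and n̂ minimises
   ‖x − Hn‖² + λ‖n‖².  λ is chosen per series by generalized
   cross-validation over a log grid spanning 10⁻¹² to 10 times the
   largest squared singular value (a fixed λ can be configured).  The
   initial detrend exists because the model has no intercept: a
   baseline or linear drift would otherwise deconvolve into a
   structured artifact identical in every voxel and inflate all
   pairwise correlations.
3. **PPI.** The psychological factor ψ has +1/−1 sticks at
   Remember-hit/Know-hit onsets, binned to the nearest TR (no
   microtime upsampling), zeros elsewhere; misses, correct rejections
   and false alarms contribute nothing.  Each voxel's detrended n̂ is
   multiplied by ψ, re-convolved with the HRF (causal, truncated to
   the run length), detrended again, and the 27 voxel series are
   averaged last — yielding 16 task-dependent series per subject.
4. **Features.** Zero-lag Pearson correlations over the full run (not
   condition epochs) fill a symmetric 16×16 matrix; the lower triangle
   in row-major (i > j) order gives 120 features.  Raw r values are
   used throughout — no Fisher z — matching how the group means are
   reported.
5. **Classification.** Linear soft-margin SVM, C = 1, raw features
   (standardization available but off by default).  Features are
   ordered once on the whole cohort by descending |t| (pooled-variance
   two-sample statistic; ties break to the lower edge index;
   zero-variance edges get infinite |t|, rank on top and are flagged).
   LOOCV accuracy is computed for every k = 1…120.  The permutation
   null shuffles labels preserving class counts and recomputes the
   *entire* procedure — ranking included — per permutation, so the
   null inherits the same selection optimism as the observed curve.
   The peak is the maximum accuracy, smallest k on ties.  The edge
   report lists the top peak_k edges with plain within-group mean r
   (displayed at 2 decimals) and a direction flag.

## The whole-cohort ranking and its bias

Ordering features on the full cohort before LOOCV leaks the held-out
subject into the selection step.  Two consequences are worth knowing:

* on pure-noise cohorts the accuracy curve is optimistically shifted
  (≈ 0.74 on average at n = 20 instead of 0.5), and
* at very small k the same selection produces strong *anti-learning*
  (accuracy near 0): the chosen feature separates the full-sample
  group means, and removing the held-out subject systematically moves
  its own class boundary away from it.

Both effects appear identically in the permutation null because the
null re-ranks per shuffle — which is exactly why it must.  An unbiased
alternative (`nested_ranking`) recomputes the ranking inside each
training fold.  The all-feature accuracy (k = 120) is free of
selection bias and is the number to compare against chance.

## The linear-SVM backend

LOOCV over 120 feature counts and thousands of permutations needs
~10⁵–10⁶ SVM fits.  The default backend is an SMO solver for the
binary C-SVC dual (box constraints, unregularized bias via the
equality constraint — the same optimisation problem libsvm solves,
stopping tolerance 10⁻³), jit-compiled with numba and driven from a
precomputed Gram matrix updated incrementally as features are added.
`backend="sklearn"` routes every fit through `sklearn.svm.SVC`
instead; a dedicated test asserts the two produce identical LOOCV
predictions across random cohorts.

## The synthetic cohort generator

The generator reproduces the statistical structure the analysis
assumes, not scanner physics:

* **Protocol.** 120 old + 60 new items, back-to-back 4-s trials,
  TR = 2 s, 360 volumes (the defaults exactly fill the run).  Old
  items split into R-hit/K-hit/miss at 45/35/20% by default and new
  items into CR/FA at 90/10% — placeholders for unreported behavioural
  rates, configurable, chosen only to shape epoch counts.
* **Coupling.** Per TR bin, the 16 latent node signals are one draw
  from a zero-mean unit-variance Gaussian whose correlation matrix is
  switched by trial epoch (onset → onset + duration, nearest-TR):
  `base_rho` (default 0.1) everywhere, except that Remember-hit epochs
  of PP subjects carry `base_rho + delta_rho` on the designated effect
  edges.  The group difference in the R-minus-K coupling contrast is
  therefore exactly `delta_rho`; a negative `delta_rho` yields a
  CTRL>PP edge.  Requested matrices that are not positive definite
  raise, naming the effect edges.
* **Rendering.** Latent signals are convolved with the canonical HRF,
  scaled (`signal_scale`, default 1), and added identically to all 27
  voxels of the node's cube, on a background of baseline 100 + linear
  drift (`drift_amplitude`, default 1 peak-to-peak) + white Gaussian
  noise (`noise_sd`, default 0.5; 0.1 is the "low-noise" setting used
  for recovery checks).  The default grid is 64×64×32 at 3-mm
  isotropic voxels with a diagonal RAS+ affine centred on the origin;
  tests and the acceptance script use a compact 24×24×15 grid that
  still holds 16 disjoint cubes.
* **Determinism.** The cohort is a pure function of its config:
  per-subject seeds are derived from the master seed via
  `SeedSequence`, and a fixed config reproduces bit-identical NIfTI
  files and manifests.

What the generator does **not** emulate: motion, physiological noise,
slice timing, spatial smoothness/autocorrelation of real BOLD noise,
haemodynamic variability across regions, or the encoding run.  Passing
tests therefore demonstrate that the implementation measures what the
generative model injects — not that the analysis is robust to real
acquisition artefacts.

## Numerical choices

* HRF kernel sampled at t = 0, TR, …, 32 s and normalised to unit
  maximum; the continuous mode of the default double-gamma sits at
  ≈ 4.97 s, so at TR = 2 the sampled argmax lands on the 6-s sample
  (h(6) > h(4)).
* `deconvolve_bold` defaults to the fully determined inverse of a
  full-mode convolution (output length = input − kernel + 1); the PPI
  chain passes `n_out = n_volumes` to deconvolve runs in place,
  accepting an edge effect confined to the final samples.  λ = 0 on a
  numerically singular operator raises and instructs a positive
  penalty.
* Deconvolution accuracy has an information ceiling: with white-noise
  truth and observation noise at amplitude SNR 10, the best possible
  truth correlation at TR = 2 is ≈ 0.93, and the GCV choice attains it
  (the unit tests pin GCV to within 0.005 of a λ-oracle sweep).
* Detrending is least-squares removal of intercept + linear trend
  (`scipy.signal.detrend`), applied along the last axis.
* Psych sticks: two opposite-sign onsets in one TR bin are ambiguous
  and raise with the trial indices; same-sign duplicates keep the
  stick at ±1.
* Tie-breaks are deterministic everywhere: ranking ties → lower edge
  index (stable sort); peak ties → smallest k; voxel snapping ties →
  half-away-from-zero.
* Constant node series make Pearson r undefined and raise, naming the
  node.

## Null calibration and the permutation envelope

On a delta_rho = 0 cohort the observed labels are exchangeable with
shuffled ones, so the observed accuracy curve is itself one draw from
the permutation ensemble.  The calibration check therefore requires
the observed curve to lie inside the per-k min–max envelope of 200
permutation curves and to track the null mean on average, and
separately requires the unbiased k = 120 accuracy to sit within 3
standard errors of the majority-class proportion.  A mean ± 3·sd test
at every one of 120 correlated k values is *not* used: across that
many comparisons an occasional |z| > 3 excursion is expected under the
null, and treating it as failure would miscalibrate the check.

## Problem sizes used by tests and the acceptance script

Structural counts run at full protocol scale (16 nodes, 360 volumes,
120 features).  Cohort-level checks use the compact grid with
n = 10 + 10 (null calibration, 200 permutations) and n = 20 + 20
(effect recovery at three delta_rho = 0.5 edges over 5 seeds;
direction recovery at ±0.5 over 3 seeds) — sizes chosen so the whole
bench replays in a few minutes while keeping every count the analysis
fixes (features, nodes, volumes) at its true value.

## Known limitations

* The deconvolution is a ridge inverse with GCV, not a parametric
  empirical Bayes scheme; it honours the same intent (neural-level
  signal recovery) with an explicit, testable contract.
* The default feature ordering reproduces the fixed-ordering design
  and is optimistically biased by construction; use `nested_ranking`
  for unbiased curves.
* The Lacadie affine is a published best fit; it disagrees with other
  Talairach↔MNI mappings (e.g. Brett's piecewise transform) by up to
  ~1 cm at extreme coordinates.
* Group labels are limited to two classes, CTRL and PP, with the
  effect convention attached to PP's Remember-hit epochs.
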