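# Methods

This note documents the models, defaults, and numerical choices behind
`walkmap`, and what the synthetic validation experiments do and do not
establish about real recordings.

## Preprocessing

ΔF/F is computed per voxel as (F − B) / max(B, ε) with B a centered
moving average of `baseline_window` frames (default 4000), truncated at
the recording edges. When the recording is shorter than the window the
baseline degenerates to the per-voxel global mean; both a moving and an
explicit global mode are exposed because either reading of "the signal
averaged for 4000 time points" is defensible — moving is the default
since it additionally tolerates slow drift and bleaching on long
recordings. ε (default 1e−6 a.u.) guards the division; with ε = 0 a
non-positive baseline is an error that reports the offending voxel
count.

Denoising is the stationary fixed-gain form of a recursive
predictor–corrector: Ê₁ = x₁, Ê_t = G·Ê_{t−1} + (1−G)·x_t with
G = 0.5. G = 0 is the identity; every output is a convex combination of
the inputs seen so far, so the filter cannot overshoot the running
input range, and for white noise it strictly reduces variance. The
adaptive-variance generalization was considered and dropped: a fixed
gain is fully characterized by one number, and the pipeline's
statistics are insensitive to the difference at the noise levels we
model. The pipeline order (ΔF/F, then denoise) is enforced by a `space`
flag on the movie container. Motion correction is an explicit identity
hook; registration is assumed done upstream.

## Behavior regressors

Discrete channels (walk, groom, flail, walk_onset, walk_offset) are
binarized from per-frame labels; walk scoring thresholds forward speed
at 0.25 mm/s and drops walk runs shorter than 0.2 s (frames at 30 Hz:
6), both overridable — the binarization itself is standard, the
constants are our defaults. Turning channels stay continuous (rad/s,
split into non-negative left/right). Every channel is causally
convolved with the indicator's single-spike response
k(t) = e^{−t/τ_d} − e^{−t/τ_r} (peak normalized to 1, support 5·τ_d)
and then passed through the *same* ΔF/F transform as the fluorescence,
reusing the fluorescence parameters verbatim. An all-zero channel would
hit 0/0 in the ΔF/F stage; regressors therefore fall back to
subtract-only when the baseline magnitude never exceeds ε, which maps
zero to zero.

Kernel time constants per GCaMP variant are configuration defaults
taken from published sensor characterizations (rise/decay seconds):
6f 0.05/0.40, 6m 0.08/1.00, 6s 0.18/1.80, 7f 0.03/0.45, 7s 0.15/1.70.
They are deliberately overridable — kernel estimation from data is out
of scope.

## Regression statistics

Single-unit fits are OLS with intercept (statsmodels); the reported
quantities are the slope (sign = direction of modulation), R², the
slope's two-sided p and 95% CI. The group-level linear model uses
treatment-coded categorical factors; per level it reports
intercept + level coefficient, with the interval formed by **summing
the half-widths** of the intercept CI and the level-coefficient CI.
That construction overstates the joint uncertainty when the two
estimates covary; it is kept as the default for fidelity to the
original analysis convention, and a covariance-correct interval
(variance of the linear combination) is available via
`ci_method="covariance"`. Level-vs-zero tests use the exact t test of
the combination and are BH-adjusted. Rank-deficient designs raise an
error naming the aliased levels (pivoted QR).

Mann–Whitney comparisons are two-sided, exact when both groups have
n ≤ 8 and no cross-group ties, otherwise normal approximation with
midranks and tie correction; Bonferroni multiplies by the number of
pairs. Fly-wise averaging before the test is the intended usage (the
samples are per-fly means). Benjamini–Hochberg adjustment is the
standard step-up with cumulative minimum and cap at 1.

## Functional components

The extraction is a double SVD with spatial ICA:

1. A first SVD (randomized, up to rank 30) estimates per-voxel noise:
   the top-k₀ singular subspace is removed and the residual sd (with k₀
   degrees of freedom subtracted) is the noise estimate. k₀ comes from
   a knee detector on the **log** singular values (point farthest from
   the chord between the scree's endpoints, floored at 1). The log
   scale matters: a single dominant global mode otherwise swamps the
   signal/noise gap, k₀ lands too low, residual "noise" contains real
   sources, and the normalization flattens exactly the voxels carrying
   signal. Voxels are divided by max(sd, floor) with a floor relative
   to the largest sd, so the output is invariant to rescaling the
   movie.
2. A second SVD to rank K on the normalized matrix, then FastICA
   (log-cosh, tol 1e−6, 1000 iterations, seeded) on the K spatial
   singular vectors, voxels as samples. The unmixing is spatial by
   design: blob-like maps are sparse and approximately independent over
   voxels, whereas the time courses of walk-coupled sources are heavily
   correlated and temporal ICA would fail. The temporal side is
   transformed by the inverse of the same matrix, so
   maps × time courses reproduces the rank-K SVD reconstruction to
   machine precision — an invariant the tests assert at 1e−8.

Whitening for the ICA step is done explicitly (symmetric C^{−1/2} of
the centered spatial vectors) rather than inside scikit-learn: the K
orthonormal singular vectors always yield a (K−1)-fold degenerate
covariance spectrum, and scikit-learn's eigenvector sign convention can
zero out a whitening column in that degenerate subspace, silently
discarding a dimension. The fixed-point iteration is restarted from up
to 5 deterministically derived seeds if it fails to converge; extraction
errors out only after all restarts (pipelines may opt into
`strict=False`, which keeps the last rotation with a logged warning —
appropriate when some retained directions are pure noise, where the
iteration provably cycles and the cycling directions carry no
independent structure anyway). K defaults to the scree-elbow count
capped at 100 and should match the expected source count; extracting
fewer components than sources pushes FastICA into the same limit-cycle
regime.

Components are sign-aligned (largest-|weight| voxel positive), ordered
by explained variance, and matched to reference maps by optimal
assignment on |spatial cosine| (Hungarian algorithm), with per-pair
sign reconciliation.

## Walk-onset analysis

Onsets are rest→walk transitions preceded by ≥ `min_rest` seconds of
unbroken rest (default 1 s) and followed by ≥ `min_walk` seconds of
walking (default 1 s). Trials cover [−2, +2] s; each trial is
baseline-subtracted (mean over [−2, −0.5] s) and scaled by its max
|value| (skipped below ε = 1e−12; the un-normalized path is an option).
The pre-onset statistic is the trapezoidal integral over [−0.5, 0] s of
a(t) − a(−0.5 s), in ΔF/F·s; it is zero for any constant trace, linear
in the trace, and converges to the analytic integral at O(Δt²). Each
component's per-trial (or per-fly mean, when ≥ 5 flies contribute)
statistics are tested against zero with a one-sided Wilcoxon
signed-rank test — exact for ≤ 15 tie-free values, otherwise the normal
approximation with continuity correction — and BH-adjusted across
components.

Lateralization is the mean per-fly difference between a mirrored
component pair's ipsilateral and contralateral turning coefficients,
with a t-based 95% CI and BH-adjusted test against zero. In the
synthetic studies the mirror pairing is known by construction; pairing
recovered components on real data (e.g. by midline-reflected spatial
cosine) is left to the user — a known limitation. Condition comparison
reports cosine similarities of the per-unit R² and coefficient vectors,
flags units with disjoint coefficient CIs, and runs per-unit
Mann–Whitney tests on supplied turn-difference samples.

## Synthetic data generator

The generator is the package's study design, not a fixture. Bouts are a
first-order Markov chain over rest/walk with per-frame transition
probabilities α = 0.01 and β = 0.02 at 30 Hz — geometric dwell times of
≈ 3.3 s rest and ≈ 1.7 s walk, a stationary walk fraction of 1/3, and
bout durations in the seconds range typical of tethered walking. Walk
frames draw forward speed from a gamma distribution (cv 1/3) around
5.6 mm/s; rotational flow is a smoothed signed AR(1) process scaled to
a mean magnitude of 0.4 rad/s and split into non-negative left/right
traces. Rest bouts can be relabeled groom or flail (speeds zero) to
exercise behavior contrasts; their kinematics are placeholders, not
calibrated.

Each planted source is an anisotropic Gaussian blob (truncated at 3
scales, peak 1) with time course a_k(t) = Σ_ch c_k,ch · r_ch(t − ℓ_k) +
η_k(t): r_ch is the behavior channel convolved with the indicator
kernel normalized to **unit sum**, so a sustained bout drives the
channel to 1 and a coupling of c = 0.3 means a 30% ΔF/F change during
sustained behavior (with a peak-normalized kernel the drive would
saturate near (τ_d − τ_r)·f_s ≈ 28 at 30 Hz and the rendered
fluorescence would clip at zero). ℓ_k < 0 makes the source lead the
behavior. η_k is AR(1) noise (φ = 0.8, sd 0.05 by default) — the
"intrinsic" variability of a source not explained by behavior. Voxel
fluorescence is F = F₀·(1 + Σ_k M_k a_k) with a positive per-voxel
baseline (100 a.u. ± 20% variation), Gaussian shot noise with sd
0.01·√F, and additive read noise (sd 0.1 a.u.); negatives are clipped
at zero with a logged count. The exported ground truth (maps, time
courses, couplings, leads, baseline) reconstructs the noise-free movie
exactly.

What the generator does *not* emulate: optics (light-field PSFs,
scattering), motion artifacts, bleaching beyond what the moving
baseline absorbs, non-Markovian bout structure, correlated multi-source
dynamics beyond shared behavior drive, and non-Gaussian photon
statistics. Passing the validation experiments therefore shows the
*analysis* is correct and well calibrated under a realistic
signal-plus-noise model; it does not certify performance on artifacts
the generator omits.

## Validation experiment sizes and choices

- **Component recovery**: 10×20×30 voxels × 3000 frames at 30 Hz,
  K_true ∈ {3..6} well-separated blobs including one inhibited
  (c = −0.2) and one turning-coupled source; extraction at K = K_true;
  success is matched |spatial cosine| ≥ 0.8 for every planted source.
  Matching is done on maps scaled back to ΔF/F units (noise
  normalization mildly reweights voxels and is not part of the claim).
- **Regional signs and noise monotonicity**: 16×12×8 × 2000 frames,
  four sources with walk couplings ±0.3/±0.1; regions are the planted
  blob cores (the stand-in for anatomically aligned regions — a generic
  Voronoi atlas dilutes localized couplings toward zero and tests
  nothing). Sign recovery is checked at |c| ≥ 0.1; mean regional R² is
  tracked across intrinsic noise sd ∈ {0.02, 0.05, 0.1, 0.2} with
  common random numbers per seed, so the decreasing trend is exact
  rather than statistical.
- **Pre-onset calibration**: 200 null components (uncoupled, symmetric
  AR(1) noise) over a 20000-frame behavior trace; the raw one-sided
  rejection rate at 0.05 must sit near nominal, and the BH-adjusted
  rate below it. An uncoupled null is used deliberately: a coupled
  source with zero lead has a *negatively* biased pre-onset integral
  (the indicator tail from earlier bouts decays through the window), so
  it cannot serve as a level check.
- **Pre-onset power**: one leading source (ℓ = −0.3 s, c = 0.3,
  50 trials, 30 Hz, default noise). Onset-dynamics experiments use the
  fast 6f kernel: resolving 300 ms timing with a 1 s-decay sensor is
  the wrong instrument for the question — with 6m only ≈ 20% of the
  kernel mass falls in the first 300 ms and power drops to ≈ 54%,
  which is an indicator limitation, not an analysis failure.
- **Condition contrast**: two 16×12×8 × 9000-frame studies sharing all
  couplings, the "spontaneous" one with the 300 ms lead and the
  "forced" one without (9000 frames ≈ 5 min yields ≈ 20–30 qualifying
  onsets per condition). Expected signature: regional map cosines
  > 0.9 across conditions while the pre-onset test fires only in the
  spontaneous condition.
- **Determinism**: the default pipeline study (two conditions × two
  flies, 16×12×8 × 1800 frames, K = 6 matching the six planted default
  sources) is run twice from one config and compared byte for byte; no
  output contains timestamps, CSV floats are written at fixed
  precision, and manifests store relative paths.

## Known limitations

- The summed-CI convention in the group model is conservative by
  construction; use `ci_method="covariance"` for calibrated intervals.
- The noise estimator (elbow + residual sd) is one reasonable choice
  among several and is isolated in `estimate_noise_and_normalize`;
  heavy-tailed noise or strong global artifacts will bias it.
- Spatial ICA assumes approximately independent (sparse, localized)
  maps; large disjoint sources covering sizable volume fractions are
  anti-correlated by construction and recoverable only up to that
  geometric limit.
- Mirror pairing of components and anatomical naming are external to
  the package; the synthetic studies sidestep both by construction.
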