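# Methods

This note documents the models, estimators, and numerical choices behind
`nanopack`, and what the synthetic-data generators do and do not emulate.

## Scope and data model

The package analyses three kinds of measurement produced in membrane
nanoscopy of solvatochromic probes (Nile Red and push–pull substituted
analogs):

1. **Ratiometric two-detector images.** A probe whose emission red-shifts
   with local polarity is imaged in two spectral detectors (det1: far red,
   640–754 nm; det2: red, 580–640 nm). The per-pixel ratio det1/det2 is a
   proxy for water penetration into the bilayer and hence lipid packing:
   tightly packed membranes give low ratios.
2. **FLIM stacks.** Each pixel holds a photon-arrival-time histogram
   sampled on a fixed grid: at a 40 MHz repetition rate (25 ns period) the
   decay is recorded for 19.9 ns in 0.21 ns bins (94 bins), after an
   acquisition offset of 2–3 ns that stands in for IRF avoidance.
3. **Single-molecule tracks.** Time-ordered 2D localizations (nm, ms) with
   a photon count per localization, as produced by iterative
   beam-repositioning tracking with a probing range of size L.

Internal units are fixed: nm and ms for tracking (conveniently,
1 nm/ms = 1 µm/s), ns for FLIM, pixels for filter widths. Images are
row-major with the origin at the top left, x rightward, y downward.
Compartment masks use the label encoding 0 background, 1 vesicle,
2 lipid droplet, 3 tubule, 4 plasma membrane, 5 filopodium.

## Ratiometric analysis

- `mean_brightness` averages pixels strictly above a user-supplied
  background threshold; an image with no qualifying pixel is an error, not
  zero. Background levels are explicit parameters because they are an
  acquisition-specific choice; the pipeline default (60th percentile of
  nonzero pixels) favours reproducibility over per-image manual selection.
- `pearson` is the standard two-pass Pearson coefficient over a foreground
  mask. It is symmetric and invariant to positive affine rescaling of
  either channel; zero variance raises `UndefinedCorrelationError` rather
  than returning a number.
- `ratio_map` Gaussian-filters each detector (default sigma 1.5 px,
  reflective boundary handling to avoid dark-border ratio artifacts) and
  divides the smoothed images. The background threshold is applied to the
  *smoothed* images, matching the order filter → threshold → ratio; pixels
  failing it are invalid rather than NaN-poisoned.
- `normalize_ratio` divides by the global median of valid pixels (default)
  or by the median of a reference region. The reference is configurable
  because "normalized ratio" admits both per-image and per-dataset
  readings; global median is idempotent and scale-free. Every applied
  divisor is accumulated in `normalization_constant`.
- `mad_filter` keeps values within k (default 3) median absolute
  deviations of the median. When MAD = 0 — at least half the sample sits
  exactly at the median — only median values are kept; this is the only
  consistent limit of the rule.
- `classify_droplets` splits vesicular components into vesicles and lipid
  droplets by mean green emission (droplet cores are green-shifted). The
  green threshold is exposed as a parameter; no universal value exists
  because it depends on laser power and labeling density.
- `vesicle_fwhm` detects local maxima and fits each with an elliptical 2D
  Gaussian plus constant offset in a square window of 7× the nominal PSF
  sigma, brightest peak first; peaks falling inside an already-fitted
  window are skipped. FWHM = 2√(2 ln 2)·σ per axis. Fits that fail to
  converge, drift out of the window, or exceed the window size are
  discarded as misdetections.

## Lifetime estimation

A single-exponential decay I(t) = I₀·exp(−t/τ) becomes a line in
log space, so the **linearized estimator** fits ln I against the bin
centers by ordinary least squares and reports τ = −1/slope. OLS (not
variance-weighted) is used deliberately: the point of the linearization is
speed, and the weighting would reintroduce per-pixel work. Bins with
counts ≤ 0 cannot be log-transformed and are excluded pixel-wise; a pixel
needs ≥ 3 usable bins, and non-decaying pixels (slope ≥ 0) are flagged
rather than given negative lifetimes.

The **nonlinear estimator** fits A·exp(−kt) to the raw counts (negative
noise excursions included) with a vectorized two-parameter
Levenberg–Marquardt: per-pixel damped 2×2 normal equations with
accept/reject steps, initialized from the linearized estimate. This runs
~10³ pixels/ms, which is what makes the Monte-Carlo bias study tractable;
a per-pixel call into a generic optimizer would not be. On noiseless data
both estimators are exact to machine precision for any τ > 0, which the
tests verify as a closed-form oracle.

**Why two estimators:** with additive symmetric noise the nonlinear fit is
nearly unbiased, while the log transform is not — negative tail bins are
dropped and the surviving positive noise pulls the slope toward zero, so
the linearized τ̂ is biased upward, increasingly so at low I₀ and high
noise amplitude. The `noise_bias_study` quantifies this on a grid of
patches (default: one 16×16 patch per I₀ in 20…300 step 40; uniform
integer noise amplitudes 0…40; τ = 4 ns), reporting mean and SD of τ̂ per
(I₀, amplitude, method) cell over all pixels and repetitions.

### Quantization rule of the decay simulator

With uniform-integer noise of amplitude A > 0, the clean decay is rounded
to integer counts and integer noise uniform on [−A, +A] is added; counts
may go negative and are kept (downstream fitting decides handling). The
symmetric range is a deliberate reading of "uniformly distributed around
0" noise; an integer RNG with re-centering was used originally. With
Poisson noise the counts are Poisson draws of the clean decay. With zero
amplitude the simulator returns the *exact continuous* decay: the
noise-free path is the closed-form oracle for the estimators, and
quantizing it would destroy the machine-precision contract while modeling
nothing (the noiseless limit is an idealization either way).

## Noise-corrected PCA

Poisson noise makes early (bright) time bins dominate any PCA of raw decay
curves. `poisson_noise_correct` divides each time bin by the square root
of its mean intensity, approximately whitening the shot noise across bins
(variance ≈ mean for Poisson counts). The correction is not idempotent —
applying it twice rescales by the corrected means — and a bin with
non-positive mean intensity is an error naming the bin, since its scale
factor is undefined.

`ncpca` then treats each foreground pixel's corrected decay as an
observation, eigen-decomposes the time-bin second-moment matrix, and
projects every pixel onto the leading orthonormal basis decays to form
score images, s(pixel) = Σᵢ vᵢ·Iᵢ(pixel). **The data is not mean-centered
by default.** With uncentered decomposition, component 1 is the
intensity-weighted mean decay — its score tracks overall brightness and is
expected to be similar between groups imaged identically — while
component 2 captures the leading decay-shape (lifetime) contrast between
pixels, which is the biologically interpretable axis for group
comparisons. A `center=True` mode is provided for conventional covariance
PCA; there the class contrast moves to component 1. Four components are
retained by default; higher components are typically close to the noise
floor.

Numerical conventions: foreground pixels (mean counts above an intensity
threshold, or explicit masks) alone determine the basis, so background
pixels cannot swamp component 1; eigenvector sign is fixed by making each
vector's largest-magnitude element positive (PCA signs are otherwise
arbitrary and group comparisons need a convention); with several stacks
the basis is computed on pooled pixels so scores are comparable across
groups (a per-stack basis would make medians incomparable, and
`compare_scores` refuses results with different bases). `compare_scores`
reports MAD-filtered (k = 3) score distributions and medians per group,
with no hypothesis test attached — distributions, not p-values, are the
deliverable.

## Tracking analytics

- **Durations** are last − first timestamp per track; histograms are
  normalized to percentage of tracks. Track termination is taken as given
  by the track id: unbinding, bleaching, and double occupancy all end a
  track and cannot be distinguished post hoc, so the simulator models a
  single exponential dwell process.
- **Rolling speed** accumulates step lengths inside a centered window
  (default 35 ms) and divides by the window's actual time span. Edge
  positions with partial windows are dropped: a partial window would
  systematically underestimate speed. On a noiseless constant-velocity
  track every interior position returns the exact speed.
- **Photon statistics** are pooled over localizations and fit by
  closed-form log-normal maximum likelihood (mean/SD of ln N); constant
  counts give σ = 0 and a degenerate flag.
- **Localization precision** is L/(2√(2N)) nm for N photons, valid while
  L ≪ fwhm/√(ln 2) (the package warns when L exceeds a quarter of that
  bound; "≪" has no canonical cutoff). L is a user input: it is an
  instrument setting, not derivable from the data. Precision histograms
  can be summarized by a generalized extreme-value ML fit (or Gumbel with
  fixed shape) — a visualization aid, not a physical model.
- **MSD** is the time-averaged estimator with overlapping pairs, pooled
  across tracks with per-lag pair weighting (maximizing statistics for
  short tracks); a per-track equal-weight mode is provided as the
  alternative estimator. Tracks are first resampled onto a time-bin grid
  by averaging localizations per bin. Lag 0 is included as 0 and pair
  counts are recorded per lag.
- **Model fits**: Brownian, msd = 4Dτ by least squares through the origin;
  anomalous, msd = 4Dτ^α by a linear fit in log-log space (stable on the
  short, noisy curves this field produces; agrees with nonlinear fits to
  machine precision on exact inputs). Non-positive MSD values are excluded
  from the log fit and counted. The fit range defaults to the first
  quarter of available lags, never fewer than three.

### Truncation and binning studies

`truncation_study` clips every track to a given length and refits α;
`binning_study` varies the resampling bin over a fixed initial interval
(default 1 s). Both default to a 10 ms analysis bin, emulating the common
practice of binning fast localizations before MSD analysis. Averaging n
positions per bin introduces a motion-blur term — for pure Brownian motion
the binned MSD behaves as 4DΔ(k − 1/3) rather than 4DΔk — which inflates
the log-log slope at the smallest lags. Full-length tracks are fit over
many lags and barely feel it (α ≈ 1.0–1.1); heavily truncated tracks are
fit over the three shortest lags and show apparent superdiffusion
(α ≈ 1.2–1.3) with no change in the underlying motion. This reproduces,
with known ground truth, the observation that shortening trajectories
induces spurious α > 1 while re-binning full-length trajectories hardly
changes the curve; adequate track length, not finer binning, is what makes
α estimates trustworthy.

## Synthetic data: what it does and does not emulate

The generators supply every input the pipeline consumes, with ground truth
and full seed determinism (fixed seed ⇒ bit-identical output):

- **Scenes**: compartments are composed from disks, annuli, line bands
  (tubules), and a border band (plasma membrane) — enough geometry to give
  each of the five compartment classes its own ground-truth ratio.
  Detector expectations are split so det1/det2 equals the configured ratio
  exactly before noise; Poisson noise is applied per pixel and detector;
  background counts land only outside compartments. Overlapping
  compartments of different classes are rejected.
- **FLIM**: the grid defaults (I₀ 20…300 step 40, τ = 4 ns, 16×16 patches,
  0.21 ns × 94 bins, amplitudes 0…40) are the reference simulation design
  and are the conditions under which the bias study's statements hold.
- **Tracks**: Brownian steps have per-axis variance 2·D·dt (D = 1 µm²/s
  default, dt = 1 ms); ballistic motion is 1 µm/s in a random direction;
  confined motion reflects radially at a 100 nm radius (vesicle scale).
  Photons per localization are log-normal (µ = 5, σ = 0.5 in ln-space,
  ≈ 150 photons); localization noise is 3 nm per axis, the few-nm regime
  of photon-limited nanometric tracking. Durations are exponential with a
  500 ms mean; a fixed-duration mode exists for estimator studies that
  need length-controlled ensembles.

Not modeled: optical PSF and depletion physics, probe photochemistry,
detector afterpulsing/IRF shape, 3D motion, membrane curvature, gap
closing in tracking, and autofluorescence. Passing tests therefore
demonstrate correctness of the *estimators* under controlled conditions —
they do not certify performance on real images, where backgrounds are
structured and masks are drawn by hand.

## Problem sizes and tolerances

Monte-Carlo defaults were chosen so every study runs comfortably on a
laptop core: 100 repetitions per bias-study cell (≈ 25 600 pixel fits per
cell), 500-track ensembles of 1 s at 1 ms sampling for diffusion recovery,
20 seeded replicates for the truncation effect. Closed-form checks use
machine-precision tolerances (1e−9 ns on noiseless lifetimes, 1e−12 on
Pearson against an independent oracle); sampling checks use 3-SE bounds
derived from the relevant estimator variance (chi-square for step
variances, cross-seed spread where smoothing correlates pixels).
LM iterations cap at 60 with per-pixel damping in [1e−12, 1e8]; rate
estimates must end positive and finite for a pixel to be flagged ok.

## Known limitations

- The linearized fit's bin-exclusion rule (counts > 0) is itself a source
  of the bias it is meant to reveal; this is faithful to the method under
  study, not a defect to fix here.
- The uniform-noise convention (symmetric integer noise on [−A, A]) is one
  reading of "uniform around zero" noise; other re-centerings of a
  positive-integer RNG would shift the bias curves slightly.
- `ncpca` assumes a shared time grid across stacks and refuses otherwise;
  no resampling is attempted.
- The MSD resampler assumes bins are contiguous per track (true for the
  generator and for burst-style tracking data); sparse gapped tracks are
  handled through NaN bins but lose pairs.
- The extreme-value fit of precision histograms can be slow to converge
  for near-degenerate samples; it exists to summarize histograms, and its
  parameters should not be over-interpreted.
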