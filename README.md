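# nanopack

Analysis of membrane nanoscopy data acquired with solvatochromic probes
(Nile Red and its push–pull substituted analogs): ratiometric two-detector
STED imaging of lipid packing, per-pixel fluorescence-lifetime (FLIM)
fitting with a noise-bias simulation study, noise-corrected PCA of FLIM
stacks, Pearson colocalization, and single-molecule tracking analytics —
plus synthetic-data generators that emulate all of these measurements with
known ground truth, so every stage is testable without microscope data.

**Who it is for.** Microscopists and image analysts comparing membrane
packing and lifetime signatures between conditions (e.g. healthy
fibroblasts vs. lysosomal-storage-disease cells), and method developers who
need a controlled testbed for lifetime estimators and MSD analysis.

## The core models

- **Emission ratio.** A solvatochromic probe red-shifts in polar (watery,
  loosely packed) membranes. With far-red (det1) and red (det2) detectors,
  the smoothed per-pixel ratio det1/det2 maps lipid packing: low ratio =
  tight packing. Compartment statistics use a k·MAD outlier filter (k = 3).
- **Lifetime.** Each pixel's decay I(t) = I₀·e^(−t/τ) is fit either in log
  space (τ = −1/slope of an ordinary least-squares line — fast but biased
  at low signal-to-noise) or by nonlinear least squares. The bias of both
  estimators is quantified on simulated patches over an (I₀, noise) grid.
- **NC-PCA.** FLIM stacks are Poisson-stabilized (each time bin divided by
  √(bin mean)), the time-bin second-moment matrix of foreground pixels is
  eigen-decomposed, and score images s = Σᵢ vᵢ·Iᵢ are compared between
  groups: score 1 tracks the intensity-weighted mean decay, score 2 the
  leading lifetime contrast.
- **Tracking.** Time-averaged MSD with Brownian (msd = 4Dτ) and anomalous
  (msd = 4Dτ^α, log-log fit) models; 35 ms rolling-window speeds;
  log-normal photon statistics; localization precision L/(2√(2N)) for a
  probing range L and N photons, summarized by extreme-value fits.

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

Reproduce the lifetime noise-bias effect and a diffusion-coefficient
recovery in a few lines:

```python
from nanopack import (FLIMSimConfig, SynthTrackConfig, noise_bias_study,
                      simulate_tracks, msd, fit_msd)

cfg = FLIMSimConfig(I0_start=100, I0_stop=100, noise_amplitudes=(0.0, 40.0), seed=1)
study = noise_bias_study(cfg, n_reps=25)
for amp in (0.0, 40.0):
    lin = study.cell(100.0, amp, "linearized")
    nl = study.cell(100.0, amp, "nonlinear")
    print(f"amplitude {amp:4.0f}:  linearized tau = {lin.mean_tau_ns:6.3f} "
          f"+- {lin.sd_tau_ns:5.3f} ns   nonlinear tau = {nl.mean_tau_ns:6.3f} "
          f"+- {nl.sd_tau_ns:5.3f} ns")

sim = simulate_tracks(SynthTrackConfig(n_tracks=500, D=1.0, dt_ms=1.0,
                                       on_time_mean_ms=1000.0,
                                       duration_model="fixed", seed=2))
fit = fit_msd(msd(sim.ensemble, max_lag_ms=250.0), "anomalous")
print(f"anomalous MSD fit: D = {fit.D:.3f} um^2/s, alpha = {fit.alpha:.3f}")
```

Output:

```
amplitude    0:  linearized tau =  4.000 +- 0.000 ns   nonlinear tau =  4.000 +- 0.000 ns
amplitude   40:  linearized tau = 13.073 +- 2.957 ns   nonlinear tau =  4.063 +- 0.629 ns
anomalous MSD fit: D = 0.992 um^2/s, alpha = 0.998
```

Reading it: with no noise both estimators recover the 4 ns ground truth
exactly. At uniform noise amplitude 40 on an I₀ = 100 decay, the
log-linearized fit is biased upward more than threefold (13.1 ns) — the log
transform drops negative bins and amplifies the noise deviation — while the
nonlinear fit stays near truth with much smaller spread. The 500-track
Brownian ensemble (D = 1 µm²/s, 1 s at 1 ms sampling) fits back to
D = 0.992 µm²/s with α = 0.998, i.e. normal diffusion.

## Command line

Every stage is also a CLI verb writing a `report.json` with parameters,
seeds, and input hashes:

```sh
nanopack simulate flim --tau 4 --amplitude 20 --out run/ --seed 1
nanopack flim fit --stack run/flim.tif --method nonlinear --out run/
nanopack simulate tracks --n-tracks 200 --out run/ --seed 1
nanopack track msd --tracks run/tracks.csv --out run/
nanopack ratio --det1 det1.tif --det2 det2.tif --masks masks.tif --sigma 1.5 --background 20
nanopack report config.yaml      # any stage from a YAML config
```

File conventions: images and label masks are TIFF (masks also PNG; labels
0 background, 1 vesicle, 2 lipid droplet, 3 tubule, 4 plasma membrane,
5 filopodium); FLIM stacks are multi-page TIFF with the time grid in the
ImageDescription tag and a YAML sidecar; tracks are CSV with columns
`track_id, t_ms, x_nm, y_nm, photons`, coordinates in nm (origin top-left,
x right, y down).

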