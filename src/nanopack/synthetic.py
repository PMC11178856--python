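"""Synthetic microscopy data with known ground truth.

Three generators emulate the inputs of the imaging pipeline:

* two-detector ratiometric scenes with compartment-dependent emission
  ratios and Poisson photon noise,
* single-exponential FLIM stacks on the acquisition time grid (0.21 ns bins
  over 19.9 ns at a 40 MHz repetition rate) with uniform-integer or Poisson
  noise, arranged as one 16x16 patch per initial intensity I0,
* membrane-style 2D trajectories (Brownian, ballistic, or confined) with
  log-normal photon counts and exponential on-times.

All randomness flows from the config seed; a fixed seed gives bit-identical
output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    COMPARTMENT_LABELS,
    ChannelPair,
    CompartmentMasks,
    FLIMStack,
    Image2D,
    Track,
    TrackEnsemble,
)

# --------------------------------------------------------------------------
# geometry primitives (pixel coordinates, row-major: y down, x right)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Disk:
    cy: float
    cx: float
    radius: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.indices(shape)
        return (yy - self.cy) ** 2 + (xx - self.cx) ** 2 <= self.radius**2


@dataclass(frozen=True)
class Annulus:
    cy: float
    cx: float
    r_inner: float
    r_outer: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.indices(shape)
        r2 = (yy - self.cy) ** 2 + (xx - self.cx) ** 2
        return (r2 >= self.r_inner**2) & (r2 <= self.r_outer**2)


@dataclass(frozen=True)
class LineBand:
    """A straight band (tubule) between two endpoints, of given half-width."""

    y0: float
    x0: float
    y1: float
    x1: float
    half_width: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.indices(shape)
        dy, dx = self.y1 - self.y0, self.x1 - self.x0
        length2 = dy * dy + dx * dx
        if length2 == 0:
            return Disk(self.y0, self.x0, self.half_width).mask(shape)
        t = ((yy - self.y0) * dy + (xx - self.x0) * dx) / length2
        t = np.clip(t, 0.0, 1.0)
        py, px = self.y0 + t * dy, self.x0 + t * dx
        return (yy - py) ** 2 + (xx - px) ** 2 <= self.half_width**2


@dataclass(frozen=True)
class BorderBand:
    """A band along the image border (stands in for the plasma membrane)."""

    width: int

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        w = self.width
        m[:w, :] = m[-w:, :] = True
        m[:, :w] = m[:, -w:] = True
        return m


Geometry = Disk | Annulus | LineBand | BorderBand


@dataclass(frozen=True)
class Compartment:
    """One labelled structure with its ground-truth emission properties."""

    label: int  # per COMPARTMENT_LABELS
    geometry: Geometry
    ratio: float  # det1/det2 before noise
    green_fraction: float = 0.0  # green counts as a fraction of photon_budget


@dataclass
class SynthImageConfig:
    """Scene layout for the ratiometric generator.

    photon_budget is the expected summed det1+det2 counts per in-compartment
    pixel; background_level the expected counts per background pixel in each
    detector.  ``apply_poisson=False`` gives the noise-free expectation
    (the "infinite photon budget" limit).
    """

    image_shape: tuple[int, int] = (64, 64)
    pixel_size: float = 40.0  # nm
    compartments: Sequence[Compartment] = ()
    background_level: float = 2.0
    photon_budget: float = 400.0
    apply_poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_shape) < 1:
            raise ValueError("image_shape must be positive")
        if self.background_level < 0 or self.photon_budget <= 0:
            raise ValueError("background_level >= 0 and photon_budget > 0 required")
        for comp in self.compartments:
            if comp.ratio <= 0:
                raise ValueError("ground-truth ratio must be > 0")
            if comp.label not in COMPARTMENT_LABELS or comp.label == 0:
                raise ValueError(f"unknown compartment label {comp.label}")


class RatiometricScene(NamedTuple):
    pair: ChannelPair
    green: Image2D
    masks: CompartmentMasks
    truth: pd.DataFrame


def generate_ratiometric_scene(config: SynthImageConfig) -> RatiometricScene:
    """Build a two-detector scene whose in-mask expected ratio equals truth.

    Background counts land only on label-0 pixels, so det1/det2 inside each
    compartment equals its configured ratio before noise.  Overlapping
    compartments of different classes are rejected.
    """
    shape = config.image_shape
    labels = np.zeros(shape, dtype=np.int32)
    det1 = np.full(shape, config.background_level, dtype=float)
    det2 = np.full(shape, config.background_level, dtype=float)
    green = np.full(shape, config.background_level, dtype=float)

    rows = []
    for comp in config.compartments:
        m = comp.geometry.mask(shape)
        clash = m & (labels != 0) & (labels != comp.label)
        if clash.any():
            raise ValueError(
                f"compartment label {comp.label} overlaps a different class"
            )
        labels[m] = comp.label
        r, b = comp.ratio, config.photon_budget
        det1[m] = b * r / (1.0 + r)
        det2[m] = b / (1.0 + r)
        green[m] = config.background_level + b * comp.green_fraction
        rows.append(
            {
                "label": comp.label,
                "compartment": COMPARTMENT_LABELS[comp.label],
                "ratio": comp.ratio,
                "green_fraction": comp.green_fraction,
                "n_pixels": int(m.sum()),
            }
        )

    if config.apply_poisson:
        rng = np.random.default_rng(config.seed)
        det1 = rng.poisson(det1).astype(float)
        det2 = rng.poisson(det2).astype(float)
        green = rng.poisson(green).astype(float)

    pair = ChannelPair(
        Image2D(det1, config.pixel_size), Image2D(det2, config.pixel_size)
    )
    return RatiometricScene(
        pair,
        Image2D(green, config.pixel_size),
        CompartmentMasks(labels),
        pd.DataFrame(rows),
    )


# --------------------------------------------------------------------------
# FLIM decay simulation
# --------------------------------------------------------------------------


@dataclass
class FLIMSimConfig:
    """Grid definition for the single-exponential decay simulation.

    One 16x16 patch is generated per I0 on the grid
    I0_start..I0_stop step I0_step (20..300 step 40 gives the 8 patches of
    the reference design); tau is the shared ground-truth lifetime [ns].
    ``noise_amplitudes`` is the amplitude grid swept by the noise-bias study;
    uniform-integer noise of amplitude A is drawn on [-A, +A].
    """

    I0_start: float = 20.0
    I0_stop: float = 300.0
    I0_step: float = 40.0
    tau: float = 4.0
    noise_amplitudes: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0)
    patch_shape: tuple[int, int] = (16, 16)
    bin_width: float = 0.21
    duration: float = 19.9
    offset: float = 0.0
    rep_period: float = 25.0
    noise_model: str = "uniform"  # "uniform" (integer) or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.bin_width <= 0 or self.duration < self.bin_width:
            raise ValueError("need bin_width > 0 and duration >= bin_width")
        if self.I0_step <= 0 or self.I0_stop < self.I0_start:
            raise ValueError("invalid I0 grid")
        if self.noise_model not in ("uniform", "poisson"):
            raise ValueError("noise_model must be 'uniform' or 'poisson'")
        if min(self.patch_shape) < 1:
            raise ValueError("patch_shape must be positive")

    @property
    def I0_grid(self) -> np.ndarray:
        n = int(np.floor((self.I0_stop - self.I0_start) / self.I0_step)) + 1
        return self.I0_start + self.I0_step * np.arange(n)

    @property
    def n_bins(self) -> int:
        return int(np.floor(self.duration / self.bin_width))

    @property
    def bin_centers(self) -> np.ndarray:
        return self.offset + (np.arange(self.n_bins) + 0.5) * self.bin_width


class SimulatedFLIM(NamedTuple):
    stack: FLIMStack
    tau_map: np.ndarray
    i0_map: np.ndarray


def simulate_decay_image(
    i0_map: np.ndarray,
    tau_map: np.ndarray,
    bin_width: float,
    duration: float,
    offset: float = 0.0,
    rep_period: float = 25.0,
    noise_model: str = "uniform",
    amplitude: float = 0.0,
    rng: np.random.Generator | None = None,
) -> FLIMStack:
    """Per-pixel decay I0*exp(-t/tau) sampled at bin centers, plus noise.

    With uniform-integer noise of amplitude A > 0 the clean decay is
    quantized to integers and integer noise on [-A, +A] is added (counts may
    go negative; downstream fitting decides handling).  With Poisson noise
    the counts are Poisson draws of the clean decay.  With zero uniform
    amplitude the exact continuous decay is returned, so that noise-free
    fits are exact to machine precision.
    """
    i0_map = np.asarray(i0_map, dtype=float)
    tau_map = np.asarray(tau_map, dtype=float)
    if i0_map.shape != tau_map.shape:
        raise ValueError("i0_map and tau_map must share a shape")
    if np.any(tau_map <= 0):
        raise ValueError("tau must be > 0 everywhere")
    n_bins = int(np.floor(duration / bin_width))
    if n_bins < 1:
        raise ValueError("duration must cover at least one bin")
    t = offset + (np.arange(n_bins) + 0.5) * bin_width
    clean = i0_map[None] * np.exp(-t[:, None, None] / tau_map[None])

    if noise_model == "poisson":
        if rng is None:
            rng = np.random.default_rng()
        counts = rng.poisson(clean).astype(float)
    elif amplitude > 0:
        if rng is None:
            rng = np.random.default_rng()
        a = int(round(amplitude))
        noise = rng.integers(-a, a + 1, size=clean.shape)
        counts = np.round(clean) + noise
    else:
        counts = clean
    return FLIMStack(counts, bin_width=bin_width, offset=offset, rep_period=rep_period)


def simulate_flim_stack(
    config: FLIMSimConfig,
    amplitude: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SimulatedFLIM:
    """One patch per I0 grid value, tiled side by side into a single stack.

    Returns the stack together with the per-pixel ground-truth tau and I0
    maps.  ``amplitude`` selects the uniform-noise amplitude (ignored for
    the Poisson noise model); pass an explicit ``rng`` to chain draws, else
    one is seeded from ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ph, pw = config.patch_shape
    grid = config.I0_grid
    i0_map = np.repeat(grid, pw)[None, :] * np.ones((ph, 1))
    tau_map = np.full_like(i0_map, config.tau)
    stack = simulate_decay_image(
        i0_map,
        tau_map,
        bin_width=config.bin_width,
        duration=config.duration,
        offset=config.offset,
        rep_period=config.rep_period,
        noise_model=config.noise_model,
        amplitude=amplitude,
        rng=rng,
    )
    return SimulatedFLIM(stack, tau_map, i0_map)


# --------------------------------------------------------------------------
# trajectory simulation
# --------------------------------------------------------------------------


@dataclass
class SynthTrackConfig:
    """Single-molecule trajectory generator settings.

    D is in um^2/s, speeds in um/s, times in ms, lengths in nm.  Track
    durations are exponential with mean ``on_time_mean_ms`` (a single dwell
    process standing for both unbinding and bleaching) unless
    ``duration_model='fixed'``.  Photons per localization are log-normal
    with parameters (photons_mu, photons_sigma) of ln N.
    """

    n_tracks: int = 200
    D: float = 1.0  # um^2/s
    motion_model: str = "brownian"  # brownian | ballistic | confined
    speed: float = 1.0  # um/s, ballistic only
    dt_ms: float = 1.0
    on_time_mean_ms: float = 500.0
    duration_model: str = "exponential"  # exponential | fixed
    photons_mu: float = 5.0  # ln-space mean  (~150 photons)
    photons_sigma: float = 0.5  # ln-space sd
    loc_noise_sd_nm: float = 3.0
    confinement_radius_nm: float = 100.0
    field_size_nm: float = 5000.0  # start positions scattered over this box
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0 or self.dt_ms <= 0 or self.n_tracks < 1:
            raise ValueError("need D >= 0, dt_ms > 0, n_tracks >= 1")
        if self.motion_model not in ("brownian", "ballistic", "confined"):
            raise ValueError(f"unknown motion model {self.motion_model!r}")
        if self.duration_model not in ("exponential", "fixed"):
            raise ValueError(f"unknown duration model {self.duration_model!r}")
        if self.on_time_mean_ms <= 0 or self.confinement_radius_nm <= 0:
            raise ValueError("on_time_mean_ms and confinement_radius_nm must be > 0")
        if self.photons_sigma < 0 or self.loc_noise_sd_nm < 0:
            raise ValueError("photons_sigma and loc_noise_sd_nm must be >= 0")


class SimulatedTracks(NamedTuple):
    ensemble: TrackEnsemble
    truth: dict


def _simulate_positions(
    config: SynthTrackConfig, n: int, start: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """True (noise-free) positions of one track, nm."""
    d_nm2_ms = 1000.0 * config.D  # um^2/s -> nm^2/ms
    if config.motion_model == "ballistic":
        theta = rng.uniform(0.0, 2.0 * np.pi)
        step = config.speed * config.dt_ms  # um/s * ms = nm (1 um/s == 1 nm/ms)
        k = np.arange(n)
        return (
            start[0] + k * step * np.cos(theta),
            start[1] + k * step * np.sin(theta),
        )
    sd = np.sqrt(2.0 * d_nm2_ms * config.dt_ms)
    steps = rng.normal(0.0, sd, size=(n - 1, 2)) if n > 1 else np.zeros((0, 2))
    if config.motion_model == "brownian":
        xy = start[None, :] + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        return xy[:, 0], xy[:, 1]
    # confined: reflect each step at a circular boundary around the start
    r = config.confinement_radius_nm
    pos = np.zeros((n, 2))
    for i in range(1, n):
        cand = pos[i - 1] + steps[i - 1]
        norm = np.hypot(*cand)
        if norm > r:  # radial reflection back inside
            cand *= (2.0 * r - norm) / norm if norm < 2.0 * r else 0.0
        pos[i] = cand
    return start[0] + pos[:, 0], start[1] + pos[:, 1]


def simulate_tracks(config: SynthTrackConfig) -> SimulatedTracks:
    """Generate an ensemble of 2D tracks with known motion ground truth.

    Brownian steps have per-axis variance 2*D*dt; ballistic tracks move at
    constant speed in a random direction; confined tracks are Brownian with
    radial reflection at the confinement radius.  Localization noise is
    added independently per axis; photons per localization are log-normal
    (rounded, floored at 1).
    """
    rng = np.random.default_rng(config.seed)
    tracks = []
    durations = []
    for tid in range(config.n_tracks):
        if config.duration_model == "exponential":
            dur = rng.exponential(config.on_time_mean_ms)
        else:
            dur = config.on_time_mean_ms
        n = max(2, int(np.floor(dur / config.dt_ms)) + 1)
        durations.append((n - 1) * config.dt_ms)
        start = rng.uniform(0.0, config.field_size_nm, size=2)
        x, y = _simulate_positions(config, n, start, rng)
        if config.loc_noise_sd_nm > 0:
            x = x + rng.normal(0.0, config.loc_noise_sd_nm, size=n)
            y = y + rng.normal(0.0, config.loc_noise_sd_nm, size=n)
        photons = np.maximum(
            1, np.round(rng.lognormal(config.photons_mu, config.photons_sigma, size=n))
        ).astype(np.int64)
        t = np.arange(n) * config.dt_ms
        tracks.append(Track(tid, t, x, y, photons))
    truth = {
        "motion_model": config.motion_model,
        "D_um2_s": config.D,
        "speed_um_s": config.speed,
        "alpha": {"brownian": 1.0, "ballistic": 2.0, "confined": 1.0}[
            config.motion_model
        ],
        "mean_duration_ms": float(np.mean(durations)),
    }
    return SimulatedTracks(TrackEnsemble.from_tracks(tracks), truth)
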