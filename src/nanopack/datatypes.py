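"""Core in-memory containers shared across the pipeline stages.

All images are row-major numpy arrays (y down, x right), coordinates are in
nanometres, times in milliseconds (tracking) or nanoseconds (FLIM).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Label convention for compartment masks (documented in the README).
COMPARTMENT_LABELS = {
    0: "background",
    1: "vesicle",
    2: "lipid_droplet",
    3: "tubule",
    4: "plasma_membrane",
    5: "filopodium",
}


@dataclass
class Image2D:
    """A single-detector photon-count image with a physical pixel size [nm]."""

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("Image2D requires a 2D array of shape >= 1x1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Image2D values must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ChannelPair:
    """Registered two-detector image pair.

    det1 collects the far-red emission (640-754 nm), det2 the red emission
    (580-640 nm); det1/det2 rises with local polarity (looser lipid packing).
    """

    det1: Image2D
    det2: Image2D

    def __post_init__(self) -> None:
        if self.det1.shape != self.det2.shape:
            raise ValueError("det1 and det2 must share a shape")
        if self.det1.pixel_size != self.det2.pixel_size:
            raise ValueError("det1 and det2 must share a pixel size")

    @property
    def shape(self) -> tuple[int, int]:
        return self.det1.shape

    @property
    def pixel_size(self) -> float:
        return self.det1.pixel_size


@dataclass
class RatioMap:
    """Per-pixel det1/det2 emission ratio.

    ``ratio`` is NaN outside ``valid_mask``.  ``normalization_constant``
    accumulates every divisor applied by :func:`nanopack.ratiometric.normalize_ratio`
    so the raw ratio can always be recovered.
    """

    ratio: np.ndarray
    valid_mask: np.ndarray
    normalization_constant: float = 1.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.ratio.shape != self.valid_mask.shape:
            raise ValueError("ratio and valid_mask must share a shape")

    @property
    def valid_values(self) -> np.ndarray:
        return self.ratio[self.valid_mask]


@dataclass
class CompartmentMasks:
    """Integer-labelled compartment masks; encoding per COMPARTMENT_LABELS."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D integer array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class FWHMRecord:
    """One elliptical 2D-Gaussian fit to a detected vesicle/blob [nm]."""

    center_x: float
    center_y: float
    fwhm_x: float
    fwhm_y: float
    amplitude: float
    offset: float
    fit_residual: float


@dataclass
class FLIMStack:
    """Time-binned photon counts, shape (time_bins, rows, cols).

    ``bin_width`` and ``offset`` are in ns; bin centers sit at
    offset + (k + 1/2) * bin_width.  ``rep_period`` is the laser repetition
    period (25 ns at 40 MHz).  ``bin_scale`` records the per-bin factors of a
    Poisson noise correction, if one was applied.
    """

    counts: np.ndarray
    bin_width: float
    offset: float = 0.0
    rep_period: float = 25.0
    bin_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("FLIMStack counts must be (time, rows, cols)")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("FLIMStack counts must be finite")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]

    @property
    def bin_centers(self) -> np.ndarray:
        return self.offset + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def same_time_grid(self, other: "FLIMStack") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.isclose(self.bin_width, other.bin_width)
            and np.isclose(self.offset, other.offset)
        )


@dataclass
class LifetimeMap:
    """Per-pixel lifetime estimates [ns]; tau is NaN where fit_ok is False."""

    tau: np.ndarray
    fit_ok: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.fit_ok = np.asarray(self.fit_ok, dtype=bool)
        if self.tau.shape != self.fit_ok.shape:
            raise ValueError("tau and fit_ok must share a shape")


@dataclass
class NCPCAResult:
    """Noise-corrected PCA of a FLIM stack.

    ``eigenvectors`` holds the first ``n_components`` basis decays
    (components x time_bins, orthonormal rows); ``eigenvalues`` the full
    descending spectrum; ``scores`` the per-pixel projections
    (components x rows x cols).  ``total_variance`` is the trace of the
    decomposed matrix so eigenvalue conservation can be verified.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    n_components: int
    foreground: np.ndarray
    centered: bool
    mean_decay: np.ndarray
    total_variance: float

    def score_image(self, component: int) -> np.ndarray:
        if not 0 <= component < self.n_components:
            raise IndexError(
                f"component {component} out of range (0..{self.n_components - 1})"
            )
        return self.scores[component]


@dataclass
class BiasStudyResult:
    """Mean/SD of fitted lifetimes over a (I0, noise amplitude) grid.

    ``table`` columns: I0, amplitude, method, mean_tau_ns, sd_tau_ns, n.
    """

    table: pd.DataFrame
    tau_true: float
    n_reps: int

    def cell(self, I0: float, amplitude: float, method: str) -> pd.Series:
        t = self.table
        sel = (t.I0 == I0) & (t.amplitude == amplitude) & (t.method == method)
        if not sel.any():
            raise KeyError(f"no cell for I0={I0}, amplitude={amplitude}, {method}")
        return t[sel].iloc[0]


TRACK_COLUMNS = ["track_id", "t_ms", "x_nm", "y_nm", "photons"]


@dataclass
class Track:
    """One molecule's time-ordered 2D localizations."""

    track_id: int
    t_ms: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    photons: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        self.photons = np.asarray(self.photons)
        if not (len(self.t_ms) == len(self.x_nm) == len(self.y_nm) == len(self.photons)):
            raise ValueError("track columns must have equal length")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("track times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])

    def clipped(self, length_ms: float) -> "Track":
        """First `length_ms` of the track (measured from its first point)."""
        keep = self.t_ms - self.t_ms[0] <= length_ms + 1e-9
        return Track(
            self.track_id,
            self.t_ms[keep],
            self.x_nm[keep],
            self.y_nm[keep],
            self.photons[keep],
        )


@dataclass
class TrackEnsemble:
    """A set of tracks, stored as a tidy table (TRACK_COLUMNS)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        self.df = self.df[TRACK_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_tracks(cls, tracks: Sequence[Track]) -> "TrackEnsemble":
        frames = [
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "t_ms": tr.t_ms,
                    "x_nm": tr.x_nm,
                    "y_nm": tr.y_nm,
                    "photons": tr.photons,
                }
            )
            for tr in tracks
        ]
        return cls(pd.concat(frames, ignore_index=True))

    def __iter__(self) -> Iterator[Track]:
        for tid, g in self.df.groupby("track_id", sort=True):
            yield Track(
                int(tid),
                g["t_ms"].to_numpy(),
                g["x_nm"].to_numpy(),
                g["y_nm"].to_numpy(),
                g["photons"].to_numpy(),
            )

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    @property
    def photons(self) -> np.ndarray:
        return self.df["photons"].to_numpy()

    def clipped(self, length_ms: float) -> "TrackEnsemble":
        tracks = [tr.clipped(length_ms) for tr in self]
        return TrackEnsemble.from_tracks([tr for tr in tracks if len(tr) >= 2])


@dataclass
class PrecisionModel:
    """MINFLUX probing-range geometry for the localization-precision formula.

    L is the size of the probing range [nm]; fwhm the beam FWHM [nm].  The
    L/(2*sqrt(2N)) approximation requires L << fwhm/sqrt(ln 2).
    """

    L: float
    fwhm: float | None = None

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("probing range L must be positive")

    def is_valid(self, strictness: float = 0.25) -> bool:
        """Whether L is small against fwhm/sqrt(ln 2); '<<' read as < 1/4."""
        if self.fwhm is None:
            return True
        return self.L < strictness * self.fwhm / np.sqrt(np.log(2))


@dataclass
class MSDCurve:
    """Time-averaged mean squared displacement, pooled over tracks."""

    lags_ms: np.ndarray
    msd_nm2: np.ndarray
    n_pairs: np.ndarray
    time_bin_ms: float

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.msd_nm2 = np.asarray(self.msd_nm2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)

    def __len__(self) -> int:
        return len(self.lags_ms)


@dataclass
class DiffusionFit:
    """MSD model fit; D in um^2/s (generalized, um^2/s^alpha, if anomalous)."""

    model: str
    D: float
    alpha: float
    fit_lags_ms: np.ndarray
    n_excluded: int = 0
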