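"""Single-molecule trajectory analytics.

Tracks are time-ordered 2D localizations (nm, ms) with per-localization
photon counts, as emitted by iterative-beam tracking microscopes.  The
module provides duration and photon statistics, a rolling-window speed,
the closed-form localization precision L/(2*sqrt(2N)) with an extreme-value
fit of its distribution, and time-averaged MSD analysis with Brownian and
anomalous model fits plus truncation/binning sensitivity studies.

Internally lengths are nm and times ms; note 1 nm/ms == 1 um/s, so speeds
convert trivially.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    DiffusionFit,
    MSDCurve,
    PrecisionModel,
    Track,
    TrackEnsemble,
)

NM2_PER_MS_TO_UM2_PER_S = 1e-3


@dataclass
class DurationHistogram:
    durations_ms: np.ndarray
    bin_edges_ms: np.ndarray
    percentages: np.ndarray  # per bin, sums to 100


def track_durations(
    ensemble: TrackEnsemble, bins: int | np.ndarray = 10
) -> DurationHistogram:
    """Track durations (last t - first t) and a percentage-normalized histogram."""
    durations = np.array([tr.duration_ms for tr in ensemble])
    if durations.size == 0:
        raise ValueError("empty ensemble")
    counts, edges = np.histogram(durations, bins=bins)
    percentages = 100.0 * counts / counts.sum()
    return DurationHistogram(durations, edges, percentages)


@dataclass
class SpeedSeries:
    t_ms: np.ndarray
    speed_um_s: np.ndarray
    window_ms: float


def rolling_speed(track: Track, window_ms: float = 35.0) -> SpeedSeries:
    """Speed per position from a centered sliding window over the path.

    For each localization, the step lengths inside the centered window are
    accumulated and divided by the window's actual time span.  Positions
    whose window extends beyond the track (partial windows) are dropped to
    avoid systematic edge underestimation; a track shorter than the window
    yields an empty series.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    t, x, y = track.t_ms, track.x_nm, track.y_nm
    if track.duration_ms < window_ms:
        return SpeedSeries(np.array([]), np.array([]), window_ms)
    steps = np.hypot(np.diff(x), np.diff(y))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    half = window_ms / 2.0
    times, speeds = [], []
    for i in range(len(t)):
        lo, hi = t[i] - half, t[i] + half
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            continue
        j0 = int(np.searchsorted(t, lo - 1e-9, side="left"))
        j1 = int(np.searchsorted(t, hi + 1e-9, side="right")) - 1
        span = t[j1] - t[j0]
        if span <= 0:
            continue
        times.append(t[i])
        speeds.append((cum[j1] - cum[j0]) / span)  # nm/ms == um/s
    return SpeedSeries(np.array(times), np.array(speeds), window_ms)


@dataclass
class LogNormalFit:
    mu: float  # mean of ln N
    sigma: float  # sd of ln N
    n: int
    degenerate: bool
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def photon_lognormal_fit(ensemble: TrackEnsemble, bins: int = 30) -> LogNormalFit:
    """Maximum-likelihood log-normal fit of pooled per-localization photons.

    The ML estimates are the mean and (population) SD of ln N.  Constant
    counts give sigma = 0 and are flagged degenerate.  The fit pools all
    localizations, so it is invariant to how they are grouped into tracks.
    """
    photons = ensemble.photons.astype(float)
    if np.any(photons < 1):
        raise ValueError("photon counts must be >= 1")
    logs = np.log(photons)
    mu, sigma = float(logs.mean()), float(logs.std(ddof=0))
    counts, edges = np.histogram(photons, bins=bins)
    return LogNormalFit(mu, sigma, photons.size, sigma == 0.0, counts, edges)


def localization_precision(
    photons: float | np.ndarray, model: PrecisionModel
) -> float | np.ndarray:
    """Localization precision L/(2*sqrt(2N)) in nm.

    Valid only while the probing range L is small against the beam size
    (L << fwhm/sqrt(ln 2)); a warning is emitted when the model violates
    that regime.  Scales linearly in L and as N^(-1/2).
    """
    n = np.asarray(photons, dtype=float)
    if np.any(n < 1):
        raise ValueError("photon count N must be >= 1")
    if not model.is_valid():
        warnings.warn(
            "probing range L is not small against fwhm/sqrt(ln 2); "
            "the precision approximation may not hold",
            stacklevel=2,
        )
    out = model.L / (2.0 * np.sqrt(2.0 * n))
    return float(out) if np.isscalar(photons) else out


@dataclass
class EVDFit:
    family: str
    shape: float  # scipy genextreme c (0 for gumbel)
    loc: float
    scale: float
    n: int
    degenerate: bool
    log_likelihood: float


def precision_evd_fit(precisions: np.ndarray, family: str = "gev") -> EVDFit:
    """ML fit of an extreme-value distribution to precision values.

    ``gev`` fits the full generalized family (scipy's genextreme);
    ``gumbel`` fixes the shape at zero.  Needs at least 10 points;
    zero-spread samples are flagged degenerate instead of being fit.
    """
    x = np.asarray(precisions, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 values for an extreme-value fit")
    if np.ptp(x) == 0.0:
        return EVDFit(family, 0.0, float(x[0]), 0.0, x.size, True, np.nan)
    if family == "gev":
        c, loc, scale = stats.genextreme.fit(x)
        ll = float(stats.genextreme.logpdf(x, c, loc, scale).sum())
    elif family == "gumbel":
        loc, scale = stats.gumbel_r.fit(x)
        c = 0.0
        ll = float(stats.gumbel_r.logpdf(x, loc, scale).sum())
    else:
        raise ValueError(f"unknown family {family!r}")
    return EVDFit(family, float(c), float(loc), float(scale), x.size, False, ll)


def _rebin_track(track: Track, time_bin_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Average localizations onto the bin grid; returns dense x, y (NaN gaps).

    Bin k covers [k, k+1) * time_bin_ms relative to the track start.
    """
    rel = track.t_ms - track.t_ms[0]
    idx = np.floor(rel / time_bin_ms + 1e-9).astype(int)
    nb = idx[-1] + 1
    sums_x = np.bincount(idx, weights=track.x_nm, minlength=nb)
    sums_y = np.bincount(idx, weights=track.y_nm, minlength=nb)
    n = np.bincount(idx, minlength=nb)
    x = np.full(nb, np.nan)
    y = np.full(nb, np.nan)
    filled = n > 0
    x[filled] = sums_x[filled] / n[filled]
    y[filled] = sums_y[filled] / n[filled]
    return x, y


def msd(
    ensemble: TrackEnsemble,
    time_bin_ms: float | None = None,
    max_lag_ms: float | None = None,
    per_track: bool = False,
) -> MSDCurve:
    """Time-averaged MSD with overlapping pairs, pooled over tracks.

    Tracks are first resampled onto the bin grid by averaging localizations
    per bin (``time_bin_ms=None`` uses the native sampling interval).  By
    default all displacement pairs are pooled with per-lag pair weighting;
    ``per_track=True`` instead averages per-track MSD curves with equal
    track weight.  Lag 0 is included with MSD 0; a ``max_lag_ms`` beyond
    every track yields an empty curve.
    """
    tracks = list(ensemble)
    if not tracks:
        raise ValueError("empty ensemble")
    if time_bin_ms is None:
        dts = np.concatenate([np.diff(tr.t_ms) for tr in tracks if len(tr) > 1])
        time_bin_ms = float(np.median(dts))
    if time_bin_ms <= 0:
        raise ValueError("time_bin_ms must be positive")

    binned = [_rebin_track(tr, time_bin_ms) for tr in tracks]
    max_bins = max(len(x) for x, _ in binned)
    if max_lag_ms is None:
        k_max = max_bins - 1
    else:
        k_max = int(np.floor(max_lag_ms / time_bin_ms + 1e-9))
        k_max = min(k_max, max_bins - 1)
    if k_max < 1:
        return MSDCurve(np.array([0.0]), np.array([0.0]),
                        np.array([sum(len(x) for x, _ in binned)]), time_bin_ms)

    sum_sq = np.zeros(k_max + 1)
    n_pairs = np.zeros(k_max + 1, dtype=int)
    per_track_curves = np.full((len(binned), k_max + 1), np.nan)
    per_track_curves[:, 0] = 0.0
    for ti, (x, y) in enumerate(binned):
        nb = len(x)
        for k in range(1, min(k_max, nb - 1) + 1):
            dx = x[k:] - x[:-k]
            dy = y[k:] - y[:-k]
            sq = dx * dx + dy * dy
            good = np.isfinite(sq)
            m = int(good.sum())
            if m == 0:
                continue
            s = float(sq[good].sum())
            sum_sq[k] += s
            n_pairs[k] += m
            per_track_curves[ti, k] = s / m
    n_pairs[0] = sum(int(np.isfinite(x).sum()) for x, _ in binned)

    lags = np.arange(k_max + 1) * time_bin_ms
    if per_track:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            curve = np.nanmean(per_track_curves, axis=0)
        curve[0] = 0.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            curve = np.where(n_pairs > 0, sum_sq / np.maximum(n_pairs, 1), np.nan)
        curve[0] = 0.0
    keep = (n_pairs > 0) | (np.arange(k_max + 1) == 0)
    return MSDCurve(lags[keep], curve[keep], n_pairs[keep], time_bin_ms)


def default_fit_lags(curve: MSDCurve) -> np.ndarray:
    """Default fit range: first quarter of the positive lags, at least 3."""
    positive = curve.lags_ms[curve.lags_ms > 0]
    n = max(3, len(positive) // 4)
    return positive[:n]


def fit_msd(
    curve: MSDCurve, model: str = "brownian", fit_range: np.ndarray | None = None
) -> DiffusionFit:
    """Fit an MSD curve with a Brownian or anomalous diffusion model.

    Brownian: least squares through the origin of msd = 4*D*tau (alpha
    fixed at 1).  Anomalous: msd = 4*D*tau^alpha via a linear fit in
    log-log space; non-positive MSD values cannot enter the log fit and are
    excluded (their count is reported).  The fit range defaults to the
    first quarter of the available lags (at least 3).
    """
    if fit_range is None:
        fit_range = default_fit_lags(curve)
    fit_range = np.asarray(fit_range, dtype=float)
    sel = np.isin(curve.lags_ms, fit_range) & (curve.lags_ms > 0)
    lags_s = curve.lags_ms[sel] * 1e-3
    msd_um2 = curve.msd_nm2[sel] * 1e-6
    if lags_s.size < 3:
        raise ValueError("need at least 3 lags in the fit range")
    if model == "brownian":
        finite = np.isfinite(msd_um2)
        slope = float(msd_um2[finite] @ lags_s[finite]) / float(
            lags_s[finite] @ lags_s[finite]
        )
        return DiffusionFit("brownian", slope / 4.0, 1.0, curve.lags_ms[sel],
                            int((~finite).sum()))
    if model == "anomalous":
        good = np.isfinite(msd_um2) & (msd_um2 > 0)
        n_excl = int((~good).sum())
        if good.sum() < 3:
            raise ValueError("fewer than 3 positive MSD values in the fit range")
        lx, ly = np.log(lags_s[good]), np.log(msd_um2[good])
        alpha, intercept = np.polyfit(lx, ly, 1)
        return DiffusionFit(
            "anomalous", float(np.exp(intercept) / 4.0), float(alpha),
            curve.lags_ms[sel][good], n_excl
        )
    raise ValueError(f"unknown model {model!r}")


def truncation_study(
    ensemble: TrackEnsemble,
    lengths_ms: list[float],
    time_bin_ms: float = 10.0,
    fit_range: np.ndarray | None = None,
) -> pd.DataFrame:
    """Anomalous exponent as a function of trajectory truncation.

    Tracks are clipped to each length (from their first localization), the
    pooled time-averaged MSD recomputed on the binned grid, and the
    anomalous model refit.  Short tracks analysed over few, short lags pick
    up an apparent superdiffusive exponent even for Brownian ground truth.
    Columns: length_ms, alpha, D, n_tracks, n_lags.
    """
    rows = []
    for length in lengths_ms:
        clipped = ensemble.clipped(length)
        curve = msd(clipped, time_bin_ms=time_bin_ms)
        fit = fit_msd(curve, "anomalous", fit_range)
        rows.append(
            {
                "length_ms": float(length),
                "alpha": fit.alpha,
                "D": fit.D,
                "n_tracks": clipped.n_tracks,
                "n_lags": int(len(fit.fit_lags_ms)),
            }
        )
    return pd.DataFrame(rows)


def binning_study(
    ensemble: TrackEnsemble,
    bins_ms: list[float],
    interval_ms: float = 1000.0,
) -> tuple[dict[float, MSDCurve], pd.DataFrame]:
    """MSD of the first ``interval_ms`` of each track at several binnings.

    Returns the curve per binning plus a summary table with the anomalous
    exponent as a curvature measure (bin_ms, alpha, D, n_lags).
    """
    clipped = ensemble.clipped(interval_ms)
    curves: dict[float, MSDCurve] = {}
    rows = []
    for bin_ms in bins_ms:
        curve = msd(clipped, time_bin_ms=bin_ms, max_lag_ms=interval_ms)
        curves[bin_ms] = curve
        fit = fit_msd(curve, "anomalous")
        rows.append(
            {
                "bin_ms": float(bin_ms),
                "alpha": fit.alpha,
                "D": fit.D,
                "n_lags": int(len(fit.fit_lags_ms)),
            }
        )
    return curves, pd.DataFrame(rows)
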