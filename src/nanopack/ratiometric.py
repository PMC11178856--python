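"""Ratiometric emission analysis of two-detector nanoscopy images.

The det1/det2 emission ratio of a solvatochromic probe tracks the
polarity-dependent red shift of its emission: tightly packed (drier)
membranes give low ratios, loosely packed ones high ratios.  This module
computes smoothed ratio maps, normalizes them, summarizes them per
subcellular compartment with MAD outlier filtering, and fits detected
vesicles with elliptical 2D Gaussians to measure their FWHM.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import feature, measure

from .datatypes import (
    COMPARTMENT_LABELS,
    ChannelPair,
    CompartmentMasks,
    FWHMRecord,
    Image2D,
    RatioMap,
)

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class UndefinedCorrelationError(ValueError):
    """Raised when the Pearson coefficient is undefined (zero variance)."""


def mean_brightness(img: Image2D, background: float) -> float:
    """Mean of all pixels strictly above the background threshold.

    Raises ValueError when no pixel qualifies: an image without foreground
    has no defined brightness (never silently 0).
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    fg = img.values[img.values > background]
    if fg.size == 0:
        raise ValueError("no pixel above background; brightness undefined")
    return float(fg.mean())


def pearson(
    ch1: Image2D | np.ndarray,
    ch2: Image2D | np.ndarray,
    foreground: np.ndarray | None = None,
) -> float:
    """Pearson correlation of two channels over a foreground mask.

    p = sum((Ch1_i - Ch1_av)(Ch2_i - Ch2_av))
        / sqrt(sum((Ch1_i - Ch1_av)^2) * sum((Ch2_i - Ch2_av)^2))

    evaluated over the foreground pixels (all pixels if no mask is given).
    """
    a = np.asarray(ch1.values if isinstance(ch1, Image2D) else ch1, dtype=float)
    b = np.asarray(ch2.values if isinstance(ch2, Image2D) else ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if foreground is not None:
        foreground = np.asarray(foreground, dtype=bool)
        if foreground.shape != a.shape:
            raise ValueError("foreground mask shape differs from images")
        a, b = a[foreground], b[foreground]
    a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 foreground pixels")
    da, db = a - a.mean(), b - b.mean()
    ssa, ssb = float(da @ da), float(db @ db)
    if ssa == 0.0 or ssb == 0.0:
        raise UndefinedCorrelationError("zero variance in a channel")
    return float((da @ db) / np.sqrt(ssa * ssb))


def ratio_map(
    pair: ChannelPair,
    sigma: float = 1.5,
    background: float | tuple[float, float] = 0.0,
) -> RatioMap:
    """Smoothed det1/det2 ratio, valid where both detectors exceed background.

    Each detector is Gaussian-filtered (sigma in pixels, reflective edges to
    avoid dark-border artifacts) before the division; the background
    threshold is applied to the smoothed images.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    b1, b2 = background if isinstance(background, tuple) else (background, background)
    s1 = ndimage.gaussian_filter(pair.det1.values.astype(float), sigma, mode="reflect")
    s2 = ndimage.gaussian_filter(pair.det2.values.astype(float), sigma, mode="reflect")
    valid = (s1 > b1) & (s2 > b2) & (s2 > 0)
    ratio = np.full(pair.shape, np.nan)
    np.divide(s1, s2, out=ratio, where=valid)
    return RatioMap(ratio, valid, 1.0, pair.pixel_size)


def normalize_ratio(
    rm: RatioMap,
    mode: str = "global-median",
    reference: np.ndarray | None = None,
) -> RatioMap:
    """Divide the ratio by a reference level and record the constant.

    ``global-median`` divides by the median over all valid pixels (so a
    second application is the identity); ``reference-region`` divides by the
    median over the supplied reference mask, mapping its median to 1.0.
    """
    if not rm.valid_mask.any():
        raise ValueError("no valid pixels to normalize")
    if mode == "global-median":
        const = float(np.median(rm.valid_values))
    elif mode == "reference-region":
        if reference is None:
            raise ValueError("reference-region mode requires a reference mask")
        sel = rm.valid_mask & np.asarray(reference, dtype=bool)
        if not sel.any():
            raise ValueError("reference region holds no valid pixels")
        const = float(np.median(rm.ratio[sel]))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if const <= 0:
        raise ValueError("normalization constant must be positive")
    return RatioMap(
        rm.ratio / const,
        rm.valid_mask.copy(),
        rm.normalization_constant * const,
        rm.pixel_size,
    )


def mad_filter(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Keep values within k median absolute deviations of the median.

    With MAD = 0 (at least half the data at the median) only the median
    values survive.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad_filter needs a nonempty input")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0.0:
        return values[values == med]
    return values[np.abs(values - med) <= k * mad]


@dataclass
class CompartmentStats:
    """MAD-filtered ratio distributions per compartment class."""

    table: pd.DataFrame  # label, compartment, n_pixels, median_ratio, mad
    values: dict[int, np.ndarray]  # label -> filtered pixel ratios


def compartment_stats(
    rm: RatioMap, masks: CompartmentMasks, k: float = 3.0
) -> CompartmentStats:
    """Summarize valid-pixel ratios inside each labelled compartment.

    Classes without valid pixels are reported empty (n=0, NaN median), not
    as errors; pixels outside every mask never influence any summary.
    """
    if masks.labels.shape != rm.ratio.shape:
        raise ValueError("mask shape differs from ratio map")
    rows, values = [], {}
    for label, name in COMPARTMENT_LABELS.items():
        if label == 0:
            continue
        vals = rm.ratio[(masks.labels == label) & rm.valid_mask]
        filtered = mad_filter(vals, k) if vals.size else vals
        values[label] = filtered
        if filtered.size:
            med = float(np.median(filtered))
            mad = float(np.median(np.abs(filtered - med)))
        else:
            med = mad = np.nan
        rows.append(
            {
                "label": label,
                "compartment": name,
                "n_pixels": int(filtered.size),
                "median_ratio": med,
                "mad": mad,
            }
        )
    return CompartmentStats(pd.DataFrame(rows), values)


def classify_droplets(
    vesicle_mask: np.ndarray, green: Image2D, green_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split vesicle components into vesicles and lipid droplets.

    Lipid droplets are identified by the green emission found within
    vesicular structures: connected components whose mean green intensity
    exceeds the threshold are relabelled LD.  The returned masks partition
    the input vesicle pixels exactly.
    """
    if green_threshold < 0:
        raise ValueError("green_threshold must be >= 0")
    vesicle_mask = np.asarray(vesicle_mask, dtype=bool)
    if vesicle_mask.shape != green.shape:
        raise ValueError("vesicle mask shape differs from green image")
    comps = measure.label(vesicle_mask, connectivity=2)
    ld_mask = np.zeros_like(vesicle_mask)
    for region in measure.regionprops(comps, intensity_image=green.values):
        if region.intensity_mean > green_threshold:
            ld_mask[comps == region.label] = True
    return vesicle_mask & ~ld_mask, ld_mask


def _gauss2d(coords, amp, cy, cx, sy, sx, off):
    yy, xx = coords
    return (
        amp * np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2)) + off
    ).ravel()


def vesicle_fwhm(
    img: Image2D,
    detection_threshold: float,
    psf_sigma_px: float = 2.0,
    window_factor: float = 7.0,
) -> list[FWHMRecord]:
    """Detect blob-like maxima and fit each with an elliptical 2D Gaussian.

    Local maxima above the detection threshold are processed brightest
    first; each is fit in a square window of ``window_factor`` x the nominal
    PSF sigma with an amplitude + offset Gaussian.  FWHM = 2*sqrt(2 ln 2) *
    sigma per axis, converted to nm via the image pixel size.  Fits that
    fail to converge, land outside the window, or report an FWHM larger
    than the window are discarded; overlapping windows are resolved in
    favour of the brighter peak.
    """
    vals = img.values.astype(float)
    half = max(3, int(round(window_factor * psf_sigma_px / 2.0)))
    peaks = feature.peak_local_max(
        vals, threshold_abs=detection_threshold, min_distance=2, exclude_border=False
    )
    if peaks.size == 0:
        return []
    order = np.argsort(vals[peaks[:, 0], peaks[:, 1]])[::-1]
    records: list[FWHMRecord] = []
    claimed: list[tuple[int, int]] = []
    for idx in order:
        py, px = int(peaks[idx, 0]), int(peaks[idx, 1])
        if any(abs(py - cy) <= 2 * half and abs(px - cx) <= 2 * half for cy, cx in claimed):
            continue
        y0, y1 = max(0, py - half), min(vals.shape[0], py + half + 1)
        x0, x1 = max(0, px - half), min(vals.shape[1], px + half + 1)
        window = vals[y0:y1, x0:x1]
        if window.size < 9:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        off0 = float(window.min())
        p0 = [float(vals[py, px]) - off0, float(py), float(px), psf_sigma_px, psf_sigma_px, off0]
        try:
            popt, _ = optimize.curve_fit(
                _gauss2d, (yy, xx), window.ravel(), p0=p0, maxfev=4000
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        amp, cy, cx, sy, sx, off = popt
        sy, sx = abs(sy), abs(sx)
        window_nm = (y1 - y0) * img.pixel_size
        fwhm_y = FWHM_PER_SIGMA * sy * img.pixel_size
        fwhm_x = FWHM_PER_SIGMA * sx * img.pixel_size
        if (
            amp <= 0
            or not (y0 <= cy < y1 and x0 <= cx < x1)
            or fwhm_x <= 0
            or fwhm_y <= 0
            or max(fwhm_x, fwhm_y) > window_nm
        ):
            continue
        resid = _gauss2d((yy, xx), *popt) - window.ravel()
        records.append(
            FWHMRecord(
                center_x=cx * img.pixel_size,
                center_y=cy * img.pixel_size,
                fwhm_x=fwhm_x,
                fwhm_y=fwhm_y,
                amplitude=amp,
                offset=off,
                fit_residual=float(np.sqrt(np.mean(resid**2))),
            )
        )
        claimed.append((py, px))
    return records
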