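"""Per-pixel fluorescence-lifetime estimation and noise-corrected PCA.

Two single-exponential estimators are provided: a linearized fit (ordinary
least squares on the log decay, tau = -1/slope — fast, but biased at low
signal-to-noise because only positive bins can be log-transformed) and a
nonlinear least-squares fit of I0*exp(-t/tau) (a vectorized
Levenberg-Marquardt, initialized from the linearized estimate).  The
noise-bias study quantifies both biases over an (I0, noise-amplitude)
grid of simulated patches.

NC-PCA stabilizes the Poisson noise of a FLIM stack by dividing each time
bin by the square root of its mean intensity, decomposes the time-bin
second-moment (or covariance) matrix of the foreground pixels, and projects
every pixel onto the orthonormal basis decays to obtain score images.  By
default the data is not mean-centered: component 1 then carries the
intensity-weighted mean decay, and component 2 the leading lifetime
contrast between pixels, which is the contrast used for group comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BiasStudyResult, FLIMStack, LifetimeMap, NCPCAResult
from .ratiometric import mad_filter
from .synthetic import FLIMSimConfig, simulate_flim_stack

MIN_USABLE_BINS = 3


def linearized_lifetime_fit(stack: FLIMStack, background: float = 0.0) -> LifetimeMap:
    """OLS line fit to ln(counts) vs t per pixel; tau = -1/slope.

    Only bins with counts strictly above max(background, 0) enter the fit
    (the logarithm is undefined otherwise); a pixel needs at least three
    usable bins.  The decay slope is negative, so tau = -1/slope; pixels
    with a non-negative slope are flagged instead of returning a negative
    lifetime.
    """
    counts = stack.counts.astype(float)
    t = stack.bin_centers
    usable = counts > max(background, 0.0)
    n = usable.sum(axis=0).astype(float)

    logc = np.zeros_like(counts)
    np.log(counts, out=logc, where=usable)
    w = usable.astype(float)
    st = np.tensordot(t, w, axes=(0, 0))
    stt = np.tensordot(t * t, w, axes=(0, 0))
    sy = (w * logc).sum(axis=0)
    sty = (w * logc * t[:, None, None]).sum(axis=0)
    denom = n * stt - st * st
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sty - st * sy) / denom
        tau = -1.0 / slope
    fit_ok = (n >= MIN_USABLE_BINS) & np.isfinite(slope) & (slope < 0)
    tau = np.where(fit_ok, tau, np.nan)
    return LifetimeMap(tau, fit_ok, "linearized")


def _lm_exponential(
    y: np.ndarray,
    t: np.ndarray,
    a0: np.ndarray,
    k0: np.ndarray,
    n_iter: int = 60,
    lam0: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Levenberg-Marquardt for y ~ A*exp(-k*t), per row of y.

    Two parameters per pixel, so the damped normal equations solve in
    closed form.  Steps that do not reduce the cost are rejected and the
    damping raised, per pixel.
    """
    a, k = a0.copy(), k0.copy()
    lam = np.full_like(a, lam0)

    def cost(av, kv):
        r = av[:, None] * np.exp(-np.outer(kv, t)) - y
        return (r * r).sum(axis=1), r

    c, r = cost(a, k)
    for _ in range(n_iter):
        e = np.exp(-np.outer(k, t))
        ja = e
        jk = -a[:, None] * t[None, :] * e
        g1 = (ja * r).sum(axis=1)
        g2 = (jk * r).sum(axis=1)
        h11 = (ja * ja).sum(axis=1)
        h12 = (ja * jk).sum(axis=1)
        h22 = (jk * jk).sum(axis=1)
        a11 = h11 * (1.0 + lam)
        a22 = h22 * (1.0 + lam)
        det = a11 * a22 - h12 * h12
        ok = np.abs(det) > 1e-300
        det = np.where(ok, det, 1.0)
        da = np.where(ok, -(a22 * g1 - h12 * g2) / det, 0.0)
        dk = np.where(ok, -(a11 * g2 - h12 * g1) / det, 0.0)
        an, kn = a + da, k + dk
        cn, rn = cost(an, kn)
        better = np.isfinite(cn) & (cn <= c)
        a = np.where(better, an, a)
        k = np.where(better, kn, k)
        c = np.where(better, cn, c)
        r = np.where(better[:, None], rn, r)
        lam = np.clip(np.where(better, lam * 0.3, lam * 5.0), 1e-12, 1e8)
        if np.all(np.abs(np.where(better, dk, 0.0)) <= 1e-13 * (np.abs(k) + 1e-13)):
            break
    return a, k


def nonlinear_lifetime_fit(stack: FLIMStack, background: float = 0.0) -> LifetimeMap:
    """Per-pixel least-squares fit of I0*exp(-t/tau) on the raw counts.

    All bins participate (negative noise excursions included); the fit is
    initialized from the linearized estimate where that succeeded, from a
    crude fallback otherwise.  Pixels ending with a non-positive or
    non-finite rate are flagged.  Pixels without at least three bins above
    background are not fit (an all-background image yields no lifetimes).
    """
    counts = stack.counts.astype(float)
    t = stack.bin_centers
    shape = stack.frame_shape
    usable = (counts > max(background, 0.0)).sum(axis=0)
    candidates = (usable >= MIN_USABLE_BINS).ravel()

    lin = linearized_lifetime_fit(stack, background)
    y = counts.reshape(stack.n_bins, -1).T  # (npix, T)
    tau0 = lin.tau.ravel().copy()
    fallback = ~np.isfinite(tau0) | (tau0 <= 0)
    tau0[fallback] = (t[-1] - t[0]) / 3.0 if t[-1] > t[0] else 1.0
    k0 = 1.0 / tau0
    a0 = np.maximum(y[:, 0], 1.0)

    tau = np.full(y.shape[0], np.nan)
    ok = np.zeros(y.shape[0], dtype=bool)
    if candidates.any():
        a_fit, k_fit = _lm_exponential(
            y[candidates], t, a0[candidates], k0[candidates]
        )
        good = np.isfinite(k_fit) & (k_fit > 0) & np.isfinite(a_fit) & (a_fit > 0)
        tau_c = np.where(good, 1.0 / k_fit, np.nan)
        tau[candidates] = tau_c
        ok[candidates] = good
    return LifetimeMap(tau.reshape(shape), ok.reshape(shape), "nonlinear")


def noise_bias_study(config: FLIMSimConfig, n_reps: int = 100) -> BiasStudyResult:
    """Mean and SD of fitted lifetimes over the (I0, amplitude) grid.

    For every noise amplitude in the config grid, ``n_reps`` stacks (one
    16x16 patch per I0) are simulated and fit with both estimators; the
    mean and standard deviation of tau-hat are taken over all pixels and
    repetitions of a grid cell where the fit succeeded.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    grid = config.I0_grid
    ph, pw = config.patch_shape
    rows = []
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.noise_amplitudes))
    for amp, seed in zip(config.noise_amplitudes, seeds):
        rng = np.random.default_rng(seed)
        samples = {m: [[] for _ in grid] for m in ("linearized", "nonlinear")}
        for _ in range(n_reps):
            sim = simulate_flim_stack(config, amplitude=amp, rng=rng)
            for method, fit in (
                ("linearized", linearized_lifetime_fit(sim.stack)),
                ("nonlinear", nonlinear_lifetime_fit(sim.stack)),
            ):
                for j in range(len(grid)):
                    patch_tau = fit.tau[:, j * pw : (j + 1) * pw]
                    patch_ok = fit.fit_ok[:, j * pw : (j + 1) * pw]
                    samples[method][j].append(patch_tau[patch_ok])
        for method in ("linearized", "nonlinear"):
            for j, i0 in enumerate(grid):
                vals = np.concatenate(samples[method][j]) if samples[method][j] else np.array([])
                rows.append(
                    {
                        "I0": float(i0),
                        "amplitude": float(amp),
                        "method": method,
                        "mean_tau_ns": float(vals.mean()) if vals.size else np.nan,
                        "sd_tau_ns": float(vals.std(ddof=0)) if vals.size else np.nan,
                        "n": int(vals.size),
                    }
                )
    return BiasStudyResult(pd.DataFrame(rows), tau_true=config.tau, n_reps=n_reps)


def poisson_noise_correct(stack: FLIMStack) -> FLIMStack:
    """Scale each time bin by 1/sqrt(of its mean intensity).

    Stabilizes Poisson variance across bins before PCA.  Not idempotent: a
    second application rescales by the corrected bins' means.  A bin with
    non-positive mean makes the correction undefined and raises, naming the
    bin.
    """
    means = stack.counts.reshape(stack.n_bins, -1).mean(axis=1)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(f"time bin {int(bad[0])} has non-positive mean intensity")
    factors = 1.0 / np.sqrt(means)
    return FLIMStack(
        stack.counts * factors[:, None, None],
        bin_width=stack.bin_width,
        offset=stack.offset,
        rep_period=stack.rep_period,
        bin_scale=factors,
    )


def ncpca(
    stacks: FLIMStack | list[FLIMStack],
    n_components: int = 4,
    foreground: np.ndarray | list[np.ndarray] | None = None,
    intensity_threshold: float = 0.0,
    center: bool = False,
) -> NCPCAResult | list[NCPCAResult]:
    """Noise-corrected PCA score images for one or several FLIM stacks.

    Each stack is Poisson-noise corrected; the corrected decay of every
    foreground pixel (mean raw counts per bin above ``intensity_threshold``,
    or explicit masks) is an observation.  The time-bin second-moment
    matrix of the pooled foreground pixels is eigen-decomposed (covariance
    of the mean-centered data when ``center=True``), eigenvector signs are
    fixed by making each one's largest-magnitude element positive, and
    every pixel is projected onto the retained basis to form score images.
    When several stacks are given, the basis is computed on the pooled
    pixels so scores are comparable across groups.
    """
    single = isinstance(stacks, FLIMStack)
    stack_list = [stacks] if single else list(stacks)
    if not stack_list:
        raise ValueError("ncpca needs at least one stack")
    first = stack_list[0]
    for s in stack_list[1:]:
        if not first.same_time_grid(s):
            raise ValueError("stacks must share a time grid")
    n_bins = first.n_bins
    if not 1 <= n_components <= n_bins:
        raise ValueError("n_components must be in 1..n_bins")

    if foreground is None:
        fg_list = [
            s.counts.mean(axis=0) > intensity_threshold for s in stack_list
        ]
    else:
        fg_list = [foreground] if single else list(foreground)
        fg_list = [np.asarray(m, dtype=bool) for m in fg_list]
        for s, m in zip(stack_list, fg_list):
            if m.shape != s.frame_shape:
                raise ValueError("foreground mask shape differs from stack")

    corrected = [poisson_noise_correct(s) for s in stack_list]
    obs = [
        c.counts.reshape(n_bins, -1).T[m.ravel()] for c, m in zip(corrected, fg_list)
    ]
    x = np.concatenate(obs, axis=0)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 foreground pixels")
    mean_decay = x.mean(axis=0) if center else np.zeros(n_bins)
    xc = x - mean_decay
    cov = (xc.T @ xc) / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # sign convention: largest-magnitude element of each eigenvector positive
    flip = evecs[np.abs(evecs).argmax(axis=0), np.arange(n_bins)] < 0
    evecs[:, flip] *= -1.0
    basis = evecs[:, :n_components].T  # (components, time_bins)

    results = []
    for c, m in zip(corrected, fg_list):
        data = c.counts.reshape(n_bins, -1) - mean_decay[:, None]
        scores = (basis @ data).reshape(n_components, *c.frame_shape)
        results.append(
            NCPCAResult(
                eigenvectors=basis,
                eigenvalues=evals,
                scores=scores,
                n_components=n_components,
                foreground=m,
                centered=center,
                mean_decay=mean_decay,
                total_variance=float(np.trace(cov)),
            )
        )
    return results[0] if single else results


@dataclass
class ScoreComparison:
    """MAD-filtered score distributions of two groups on a shared basis."""

    component: int
    values_a: np.ndarray
    values_b: np.ndarray
    median_a: float
    median_b: float


def compare_scores(
    result_a: NCPCAResult,
    result_b: NCPCAResult,
    component: int,
    k: float = 3.0,
) -> ScoreComparison:
    """Compare one score component between two groups.

    Both results must share the eigenvector basis (pooled-basis NC-PCA).
    Foreground score pixels are MAD-filtered (k deviations) per group; the
    distributions and their medians are returned without a hypothesis test.
    """
    if result_a.eigenvectors.shape != result_b.eigenvectors.shape or not np.allclose(
        result_a.eigenvectors, result_b.eigenvectors
    ):
        raise ValueError("score comparison requires a shared NC-PCA basis")
    va = result_a.score_image(component)[result_a.foreground]
    vb = result_b.score_image(component)[result_b.foreground]
    fa, fb = mad_filter(va, k), mad_filter(vb, k)
    return ScoreComparison(
        component, fa, fb, float(np.median(fa)), float(np.median(fb))
    )
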