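"""File formats, run configuration, and the pipeline driver.

Conventions (also in the README): images are TIFF, row-major, origin at the
top-left with x rightward and y downward; FLIM stacks are multi-page TIFF
(one page per time bin) with the time-grid metadata embedded as JSON in the
ImageDescription tag and mirrored in a YAML sidecar; tracks are CSV with
columns track_id, t_ms, x_nm, y_nm, photons; label masks use the encoding
0 background, 1 vesicle, 2 lipid droplet, 3 tubule, 4 plasma membrane,
5 filopodium.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import (
    TRACK_COLUMNS,
    ChannelPair,
    CompartmentMasks,
    FLIMStack,
    Image2D,
    TrackEnsemble,
)

logger = logging.getLogger("nanopack")

FLIM_META_KEYS = ("bin_width_ns", "offset_ns", "rep_period_ns")


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------


def write_image(img: Image2D, path: str | Path) -> None:
    """Write a single image as TIFF; integers kept lossless, floats as 32-bit."""
    values = img.values
    if not np.issubdtype(values.dtype, np.integer):
        values = values.astype(np.float32)
    meta = json.dumps({"pixel_size_nm": img.pixel_size})
    tifffile.imwrite(Path(path), values, description=meta)


def read_image(path: str | Path, pixel_size: float | None = None) -> Image2D:
    """Read a TIFF image; pixel size from the embedded metadata unless given."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        desc = tif.pages[0].description
    if values.ndim != 2:
        raise ValueError(f"{path} is not a single 2D image")
    if pixel_size is None:
        pixel_size = _parse_description(desc).get("pixel_size_nm", 1.0)
    return Image2D(values, pixel_size)


def _parse_description(desc: str | None) -> dict:
    if not desc:
        return {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return {}
    return meta if isinstance(meta, dict) else {}


# --------------------------------------------------------------------------
# FLIM stacks
# --------------------------------------------------------------------------


def write_flim_stack(stack: FLIMStack, path: str | Path) -> None:
    """Write a FLIM stack as multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    meta = {
        "bin_width_ns": float(stack.bin_width),
        "offset_ns": float(stack.offset),
        "rep_period_ns": float(stack.rep_period),
    }
    counts = stack.counts
    if not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(np.float32)
    tifffile.imwrite(
        path, counts, description=json.dumps(meta), photometric="minisblack"
    )
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_flim_stack(path: str | Path) -> FLIMStack:
    """Read a multi-page TIFF FLIM stack; metadata from tag or YAML sidecar.

    Raises a ValueError listing the required keys when the time-grid
    metadata is missing from both sources.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        counts = tif.asarray()
        desc = tif.pages[0].description
    if counts.ndim != 3:
        raise ValueError(f"{path} is not a multi-page stack")
    meta = _parse_description(desc)
    if not all(k in meta for k in FLIM_META_KEYS):
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh) or {}
    missing = [k for k in FLIM_META_KEYS if k not in meta]
    if missing:
        raise ValueError(
            f"{path} lacks FLIM metadata keys {missing}; required: {list(FLIM_META_KEYS)}"
        )
    return FLIMStack(
        counts,
        bin_width=float(meta["bin_width_ns"]),
        offset=float(meta["offset_ns"]),
        rep_period=float(meta["rep_period_ns"]),
    )


# --------------------------------------------------------------------------
# masks and tracks
# --------------------------------------------------------------------------


def write_masks(masks: CompartmentMasks, path: str | Path) -> None:
    path = Path(path)
    labels = masks.labels.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, labels)
    else:
        iio.imwrite(path, labels)


def read_masks(path: str | Path) -> CompartmentMasks:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path)
    else:
        labels = iio.imread(path)
    return CompartmentMasks(np.asarray(labels).astype(np.int32))


def write_tracks(ensemble: TrackEnsemble, path: str | Path) -> None:
    """Write the track table; numeric formatting is repr-exact, so a
    write -> read -> write cycle is byte-identical."""
    ensemble.df.to_csv(Path(path), index=False)


def read_tracks(path: str | Path) -> TrackEnsemble:
    # round_trip parsing keeps write -> read -> write byte-identical
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} missing track columns {missing}")
    return TrackEnsemble(df)


# --------------------------------------------------------------------------
# pipeline driver
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One pipeline stage with its inputs, parameters, and output directory."""

    stage: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    outdir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {"stage", "inputs", "params", "outdir", "seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stage" not in raw:
            raise ValueError("config requires a 'stage' key")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "stage": self.stage,
                    "inputs": self.inputs,
                    "params": self.params,
                    "outdir": self.outdir,
                    "seed": self.seed,
                },
                fh,
            )


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute one stage and write a machine-readable report.

    The report JSON records the stage, parameters, seed, input hashes, and
    the stage's summary statistics; all stochastic stages draw from the
    config seed, so identical configs give identical reports.  Unknown
    stages raise a ValueError (the CLI turns this into a usage error).
    """
    from . import flim, ratiometric, synthetic, tracking  # local to avoid cycles

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("stage %s: params=%s seed=%d", config.stage, config.params, config.seed)
    summary: dict = {}
    outputs: dict = {}
    p = dict(config.params)  # stages may pop keys; the report keeps the original

    if config.stage == "simulate-scene":
        cfg = synthetic.SynthImageConfig(seed=config.seed, **p)
        scene = synthetic.generate_ratiometric_scene(cfg)
        write_image(scene.pair.det1, outdir / "det1.tif")
        write_image(scene.pair.det2, outdir / "det2.tif")
        write_image(scene.green, outdir / "green.tif")
        write_masks(scene.masks, outdir / "masks.tif")
        scene.truth.to_csv(outdir / "truth.csv", index=False)
        outputs = {k: str(outdir / f"{k}.tif") for k in ("det1", "det2", "green", "masks")}
        summary = {"n_compartments": len(scene.truth)}
    elif config.stage == "simulate-flim":
        amp = p.pop("amplitude", 0.0)
        cfg = synthetic.FLIMSimConfig(seed=config.seed, **p)
        sim = synthetic.simulate_flim_stack(cfg, amplitude=amp)
        write_flim_stack(sim.stack, outdir / "flim.tif")
        outputs = {"stack": str(outdir / "flim.tif")}
        summary = {"n_bins": sim.stack.n_bins, "tau_true_ns": cfg.tau,
                   "n_patches": len(cfg.I0_grid)}
    elif config.stage == "simulate-tracks":
        cfg = synthetic.SynthTrackConfig(seed=config.seed, **p)
        sim = synthetic.simulate_tracks(cfg)
        write_tracks(sim.ensemble, outdir / "tracks.csv")
        outputs = {"tracks": str(outdir / "tracks.csv")}
        summary = {"n_tracks": sim.ensemble.n_tracks, **sim.truth}
    elif config.stage == "ratio":
        pair = ChannelPair(read_image(config.inputs["det1"]),
                           read_image(config.inputs["det2"]))
        rm = ratiometric.ratio_map(
            pair, sigma=p.get("sigma", 1.5), background=p.get("background", 0.0)
        )
        rm = ratiometric.normalize_ratio(rm, p.get("normalize", "global-median"))
        out = Image2D(np.nan_to_num(rm.ratio, nan=0.0), rm.pixel_size)
        write_image(out, outdir / "ratio.tif")
        outputs = {"ratio": str(outdir / "ratio.tif")}
        summary = {
            "normalization_constant": rm.normalization_constant,
            "n_valid": int(rm.valid_mask.sum()),
        }
        if "masks" in config.inputs:
            stats = ratiometric.compartment_stats(
                rm, read_masks(config.inputs["masks"]), k=p.get("mad_k", 3.0)
            )
            stats.table.to_csv(outdir / "compartments.csv", index=False)
            outputs["compartments"] = str(outdir / "compartments.csv")
            summary["compartments"] = stats.table.to_dict("records")
    elif config.stage == "coloc":
        ch1 = read_image(config.inputs["ch1"])
        ch2 = read_image(config.inputs["ch2"])
        fg = None
        if "background" in p:
            fg = (ch1.values > p["background"]) | (ch2.values > p["background"])
        summary = {"pearson": ratiometric.pearson(ch1, ch2, fg)}
    elif config.stage == "flim-fit":
        stack = read_flim_stack(config.inputs["stack"])
        method = p.get("method", "linearized")
        fit = (
            flim.linearized_lifetime_fit(stack, p.get("background", 0.0))
            if method == "linearized"
            else flim.nonlinear_lifetime_fit(stack, p.get("background", 0.0))
        )
        write_image(Image2D(np.nan_to_num(fit.tau, nan=0.0)), outdir / "tau.tif")
        ok = fit.tau[fit.fit_ok]
        outputs = {"tau": str(outdir / "tau.tif")}
        summary = {
            "method": method,
            "n_fit": int(fit.fit_ok.sum()),
            "mean_tau_ns": float(ok.mean()) if ok.size else None,
            "sd_tau_ns": float(ok.std()) if ok.size else None,
        }
    elif config.stage == "flim-bias":
        n_reps = p.pop("n_reps", 100)
        cfg = synthetic.FLIMSimConfig(seed=config.seed, **p)
        study = flim.noise_bias_study(cfg, n_reps=n_reps)
        study.table.to_csv(outdir / "bias.csv", index=False)
        outputs = {"bias": str(outdir / "bias.csv")}
        summary = {"tau_true_ns": study.tau_true, "n_reps": study.n_reps,
                   "n_cells": len(study.table)}
    elif config.stage == "ncpca":
        stacks = [read_flim_stack(s) for s in config.inputs["stacks"]]
        results = flim.ncpca(
            stacks,
            n_components=p.get("n_components", 4),
            intensity_threshold=p.get("intensity_threshold", 0.0),
            center=p.get("center", False),
        )
        results = results if isinstance(results, list) else [results]
        for i, res in enumerate(results):
            for c in range(res.n_components):
                write_image(
                    Image2D(res.scores[c].astype(np.float32)),
                    outdir / f"score_stack{i}_pc{c + 1}.tif",
                )
        summary = {
            "eigenvalues": results[0].eigenvalues[: results[0].n_components].tolist(),
            "total_variance": results[0].total_variance,
            "n_stacks": len(results),
        }
    elif config.stage == "track-stats":
        ens = read_tracks(config.inputs["tracks"])
        dur = tracking.track_durations(ens, bins=p.get("bins", 10))
        ph = tracking.photon_lognormal_fit(ens)
        summary = {
            "n_tracks": ens.n_tracks,
            "mean_duration_ms": float(dur.durations_ms.mean()),
            "photons_mu": ph.mu,
            "photons_sigma": ph.sigma,
        }
        if "L_nm" in p:
            from .datatypes import PrecisionModel

            prec = tracking.localization_precision(
                ens.photons, PrecisionModel(p["L_nm"], p.get("fwhm_nm"))
            )
            evd = tracking.precision_evd_fit(prec, p.get("evd_family", "gev"))
            summary["precision_evd"] = {
                "shape": evd.shape, "loc": evd.loc, "scale": evd.scale
            }
        speeds = [
            s
            for tr in ens
            for s in tracking.rolling_speed(tr, p.get("window_ms", 35.0)).speed_um_s
        ]
        if speeds:
            filtered = ratiometric.mad_filter(np.array(speeds), p.get("mad_k", 3.0))
            summary["median_speed_um_s"] = float(np.median(filtered))
    elif config.stage == "msd":
        ens = read_tracks(config.inputs["tracks"])
        curve = tracking.msd(
            ens, time_bin_ms=p.get("time_bin_ms"), max_lag_ms=p.get("max_lag_ms")
        )
        pd.DataFrame(
            {"lag_ms": curve.lags_ms, "msd_nm2": curve.msd_nm2, "n_pairs": curve.n_pairs}
        ).to_csv(outdir / "msd.csv", index=False)
        fit = tracking.fit_msd(curve, p.get("model", "anomalous"))
        outputs = {"msd": str(outdir / "msd.csv")}
        summary = {"model": fit.model, "D_um2_s": fit.D, "alpha": fit.alpha}
    else:
        raise ValueError(f"unknown stage {config.stage!r}")

    report = {
        "stage": config.stage,
        "seed": config.seed,
        "params": config.params,
        "inputs": {
            k: {"path": str(v), "sha256": _hash_file(v)}
            if isinstance(v, (str, Path)) and Path(v).is_file()
            else v
            for k, v in config.inputs.items()
        },
        "outputs": outputs,
        "summary": summary,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
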