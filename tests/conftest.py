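import numpy as np
import pytest

from nanopack import (
    Compartment,
    Disk,
    BorderBand,
    FLIMSimConfig,
    SynthImageConfig,
    SynthTrackConfig,
    generate_ratiometric_scene,
    simulate_flim_stack,
    simulate_tracks,
)


def rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Direction-free AUC via the Mann-Whitney statistic."""
    from scipy.stats import mannwhitneyu

    u = mannwhitneyu(pos, neg).statistic / (len(pos) * len(neg))
    return max(u, 1.0 - u)


@pytest.fixture
def reference_grid_config():
    """The reference FLIM simulation design: I0 20..300 step 40, tau 4 ns,
    0.21 ns bins over 19.9 ns, 16x16 patches."""
    return FLIMSimConfig(seed=42)


@pytest.fixture
def noiseless_patch():
    """A single noise-free 16x16 patch at I0=100, tau=4 ns."""
    cfg = FLIMSimConfig(I0_start=100.0, I0_stop=100.0, seed=0)
    return simulate_flim_stack(cfg)


@pytest.fixture
def two_compartment_scene():
    comps = [
        Compartment(1, Disk(20, 20, 8), ratio=1.2),
        Compartment(4, BorderBand(4), ratio=0.8),
    ]
    cfg = SynthImageConfig(
        image_shape=(64, 64), compartments=comps, photon_budget=400.0,
        background_level=2.0, seed=5,
    )
    return generate_ratiometric_scene(cfg)


@pytest.fixture
def brownian_ensemble():
    cfg = SynthTrackConfig(
        n_tracks=200, D=1.0, dt_ms=1.0, on_time_mean_ms=500.0,
        duration_model="fixed", loc_noise_sd_nm=0.0, seed=21,
    )
    return simulate_tracks(cfg)


@pytest.fixture
def ballistic_ensemble():
    cfg = SynthTrackConfig(
        n_tracks=20, motion_model="ballistic", speed=1.0, dt_ms=1.0,
        on_time_mean_ms=200.0, duration_model="fixed", loc_noise_sd_nm=0.0, seed=2,
    )
    return simulate_tracks(cfg)
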