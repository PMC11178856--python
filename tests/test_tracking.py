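"""Trajectory analytics: durations, speeds, photons, precision, MSD."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanopack import (
    MSDCurve,
    PrecisionModel,
    SynthTrackConfig,
    Track,
    TrackEnsemble,
    binning_study,
    fit_msd,
    localization_precision,
    msd,
    photon_lognormal_fit,
    precision_evd_fit,
    rolling_speed,
    simulate_tracks,
    track_durations,
    truncation_study,
)


def _track(t, x, y, tid=0):
    return Track(tid, np.asarray(t, float), np.asarray(x, float),
                 np.asarray(y, float), np.ones(len(t), dtype=np.int64))


class TestTrackDurations:
    def test_single_track_single_bin(self):
        ens = TrackEnsemble.from_tracks([_track([0, 50, 100], [0, 1, 2], [0, 0, 0])])
        hist = track_durations(ens, bins=1)
        assert hist.durations_ms[0] == 100.0
        assert hist.percentages.tolist() == [100.0]

    def test_exponential_mean_recovered(self):
        cfg = SynthTrackConfig(n_tracks=10000, on_time_mean_ms=50.0, dt_ms=1.0, seed=12)
        sim = simulate_tracks(cfg)
        hist = track_durations(sim.ensemble)
        se = 50.0 / np.sqrt(len(hist.durations_ms))
        assert abs(hist.durations_ms.mean() - 50.0) < 3 * se + cfg.dt_ms

    def test_percentages_sum_to_100(self, brownian_ensemble):
        hist = track_durations(brownian_ensemble.ensemble, bins=7)
        assert hist.percentages.sum() == pytest.approx(100.0, abs=1e-9)


class TestRollingSpeed:
    def test_ballistic_track_exact(self, ballistic_ensemble):
        tr = next(iter(ballistic_ensemble.ensemble))
        series = rolling_speed(tr, 35.0)
        assert len(series.speed_um_s) > 0
        assert np.allclose(series.speed_um_s, 1.0, atol=1e-9)

    def test_immobile_track_zero(self):
        tr = _track(np.arange(100.0), np.zeros(100), np.zeros(100))
        series = rolling_speed(tr, 35.0)
        assert np.allclose(series.speed_um_s, 0.0)

    def test_matches_bruteforce_window_oracle(self):
        rng = np.random.default_rng(8)
        t = np.arange(200.0)
        x, y = np.cumsum(rng.normal(size=200)), np.cumsum(rng.normal(size=200))
        tr = _track(t, x, y)
        series = rolling_speed(tr, 35.0)
        # independent loop implementation
        for ti, si in zip(series.t_ms, series.speed_um_s):
            lo, hi = ti - 17.5, ti + 17.5
            idx = np.where((t >= lo - 1e-9) & (t <= hi + 1e-9))[0]
            path = np.hypot(np.diff(x[idx]), np.diff(y[idx])).sum()
            assert si == pytest.approx(path / (t[idx[-1]] - t[idx[0]]), rel=1e-12)

    def test_short_track_empty_series(self):
        tr = _track([0.0, 10.0], [0, 1], [0, 1])
        assert len(rolling_speed(tr, 35.0).speed_um_s) == 0

    def test_translation_rotation_invariant(self):
        rng = np.random.default_rng(4)
        t = np.arange(100.0)
        x, y = np.cumsum(rng.normal(size=100)), np.cumsum(rng.normal(size=100))
        base = rolling_speed(_track(t, x, y), 35.0).speed_um_s
        th = 0.7
        xr = 50.0 + x * np.cos(th) - y * np.sin(th)
        yr = -3.0 + x * np.sin(th) + y * np.cos(th)
        rotated = rolling_speed(_track(t, xr, yr), 35.0).speed_um_s
        assert np.allclose(base, rotated, atol=1e-9)


class TestPhotonFit:
    def test_constant_counts_degenerate(self):
        tr = Track(0, np.arange(5.0), np.zeros(5), np.zeros(5), np.full(5, 100))
        fit = photon_lognormal_fit(TrackEnsemble.from_tracks([tr]))
        assert fit.mu == pytest.approx(np.log(100.0))
        assert fit.sigma == 0.0 and fit.degenerate

    def test_lognormal_parameters_recovered(self):
        cfg = SynthTrackConfig(
            n_tracks=1000, photons_mu=5.0, photons_sigma=0.5,
            duration_model="fixed", on_time_mean_ms=100.0, seed=1,
        )
        sim = simulate_tracks(cfg)
        fit = photon_lognormal_fit(sim.ensemble)
        n = fit.n
        assert abs(fit.mu - 5.0) < 3 * 0.5 / np.sqrt(n) + 0.01  # rounding slack
        assert abs(fit.sigma - 0.5) < 3 * 0.5 / np.sqrt(2 * n) + 0.01

    def test_invariant_to_track_grouping(self):
        rng = np.random.default_rng(2)
        photons = np.maximum(1, rng.lognormal(5, 0.5, 100).round()).astype(np.int64)
        one = TrackEnsemble.from_tracks(
            [Track(0, np.arange(100.0), np.zeros(100), np.zeros(100), photons)]
        )
        two = TrackEnsemble.from_tracks(
            [
                Track(0, np.arange(50.0), np.zeros(50), np.zeros(50), photons[:50]),
                Track(1, np.arange(50.0), np.zeros(50), np.zeros(50), photons[50:]),
            ]
        )
        fa, fb = photon_lognormal_fit(one), photon_lognormal_fit(two)
        assert fa.mu == pytest.approx(fb.mu) and fa.sigma == pytest.approx(fb.sigma)


class TestLocalizationPrecision:
    @pytest.mark.parametrize(
        "L,N,expected", [(50.0, 200, 1.25), (40.0, 50, 2.0), (100.0, 200, 2.5)]
    )
    def test_closed_form(self, L, N, expected):
        assert localization_precision(N, PrecisionModel(L)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_monotone_decreasing_in_photons(self):
        model = PrecisionModel(50.0)
        prec = localization_precision(np.arange(1, 500), model)
        assert np.all(np.diff(prec) < 0)

    @given(L=st.floats(1.0, 200.0), n=st.integers(1, 10**6), c=st.floats(1.0, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_scaling_laws(self, L, n, c):
        p = localization_precision(n, PrecisionModel(L))
        assert localization_precision(n, PrecisionModel(c * L)) == pytest.approx(c * p)
        # quadrupling the photons halves the precision
        assert localization_precision(4 * n, PrecisionModel(L)) == pytest.approx(p / 2)

    def test_validity_warning(self):
        with pytest.warns(UserWarning, match="probing range"):
            localization_precision(100, PrecisionModel(L=300.0, fwhm=360.0))

    def test_invalid_photons(self):
        with pytest.raises(ValueError):
            localization_precision(0, PrecisionModel(50.0))


class TestEVDFit:
    def test_gumbel_parameters_recovered(self):
        from scipy import stats

        x = stats.gumbel_r.rvs(loc=3.0, scale=0.7, size=100_000,
                               random_state=np.random.default_rng(5))
        fit = precision_evd_fit(x, family="gumbel")
        # asymptotic SEs of Gumbel ML estimates
        se_loc = 0.7 * np.sqrt(1.11 / x.size)
        se_scale = 0.7 * np.sqrt(0.61 / x.size)
        assert abs(fit.loc - 3.0) < 3 * se_loc * 2
        assert abs(fit.scale - 0.7) < 3 * se_scale * 2

    def test_shift_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.gumbel(2.0, 0.5, size=5000)
        f0 = precision_evd_fit(x, family="gumbel")
        f1 = precision_evd_fit(x + 10.0, family="gumbel")
        assert f1.loc == pytest.approx(f0.loc + 10.0, abs=1e-6)
        assert f1.scale == pytest.approx(f0.scale, abs=1e-6)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        x = rng.gumbel(2.0, 0.5, size=5000)
        f0 = precision_evd_fit(x, family="gumbel")
        f2 = precision_evd_fit(3.0 * x, family="gumbel")
        assert f2.loc == pytest.approx(3.0 * f0.loc, rel=1e-5)
        assert f2.scale == pytest.approx(3.0 * f0.scale, rel=1e-5)

    def test_degenerate_flagged(self):
        fit = precision_evd_fit(np.full(20, 2.0))
        assert fit.degenerate

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            precision_evd_fit(np.arange(5.0))


class TestMSD:
    def test_ballistic_closed_form(self, ballistic_ensemble):
        curve = msd(ballistic_ensemble.ensemble)
        v = 1.0  # nm/ms
        assert np.allclose(curve.msd_nm2, (v * curve.lags_ms) ** 2, rtol=1e-9)

    def test_immobile_all_zero(self):
        tr = _track(np.arange(50.0), np.zeros(50), np.zeros(50))
        curve = msd(TrackEnsemble.from_tracks([tr]))
        assert np.allclose(curve.msd_nm2, 0.0)

    def test_lag_zero_and_pair_counts_monotone(self, brownian_ensemble):
        curve = msd(brownian_ensemble.ensemble)
        assert curve.msd_nm2[0] == 0.0
        assert np.all(np.diff(curve.n_pairs[1:]) <= 0)

    def test_brownian_slope_recovers_4d(self, brownian_ensemble):
        curve = msd(brownian_ensemble.ensemble, max_lag_ms=50.0)
        fit = fit_msd(curve, "brownian")
        assert abs(fit.D - 1.0) < 0.1

    def test_single_long_track_converges(self):
        cfg = SynthTrackConfig(
            n_tracks=1, D=1.0, dt_ms=1.0, on_time_mean_ms=100_000.0,
            duration_model="fixed", loc_noise_sd_nm=0.0, seed=5,
        )
        sim = simulate_tracks(cfg)
        curve = msd(sim.ensemble, max_lag_ms=10.0)
        expected = 4.0 * 1000.0 * curve.lags_ms[1:]
        assert np.allclose(curve.msd_nm2[1:], expected, rtol=0.05)

    def test_translation_rotation_invariant(self):
        rng = np.random.default_rng(3)
        t = np.arange(100.0)
        x, y = np.cumsum(rng.normal(size=100)), np.cumsum(rng.normal(size=100))
        base = msd(TrackEnsemble.from_tracks([_track(t, x, y)]))
        th = 1.1
        xr = 9.0 + x * np.cos(th) - y * np.sin(th)
        yr = -4.0 + x * np.sin(th) + y * np.cos(th)
        rot = msd(TrackEnsemble.from_tracks([_track(t, xr, yr)]))
        assert np.allclose(base.msd_nm2, rot.msd_nm2, atol=1e-8)

    def test_max_lag_beyond_tracks_gives_trivial_curve(self):
        tr = _track([0.0, 1.0, 2.0], [0, 1, 2], [0, 0, 0])
        curve = msd(TrackEnsemble.from_tracks([tr]), time_bin_ms=10.0)
        assert len(curve) == 1 and curve.lags_ms[0] == 0.0


class TestFitMSD:
    def test_exact_brownian_input(self):
        lags = np.arange(0.0, 21.0)
        curve = MSDCurve(lags, 4.0 * 2000.0 * lags, np.full(21, 100), 1.0)
        fit = fit_msd(curve, "brownian")
        assert fit.alpha == 1.0
        assert fit.D == pytest.approx(2.0, rel=1e-12)
        anom = fit_msd(curve, "anomalous")
        assert anom.alpha == pytest.approx(1.0, abs=1e-12)

    def test_exact_ballistic_input(self):
        lags = np.arange(0.0, 21.0)
        curve = MSDCurve(lags, (2.0 * lags) ** 2, np.full(21, 100), 1.0)
        fit = fit_msd(curve, "anomalous")
        assert fit.alpha == pytest.approx(2.0, abs=1e-12)

    def test_nonpositive_msd_excluded(self):
        lags = np.arange(0.0, 13.0)
        vals = 4.0 * lags.copy()
        vals[3] = 0.0
        curve = MSDCurve(lags, vals, np.full(13, 10), 1.0)
        fit = fit_msd(curve, "anomalous", fit_range=lags[1:8])
        assert fit.n_excluded == 1

    def test_too_few_lags(self):
        curve = MSDCurve(np.array([0.0, 1.0]), np.array([0.0, 4.0]),
                         np.array([5, 5]), 1.0)
        with pytest.raises(ValueError):
            fit_msd(curve, "brownian", fit_range=np.array([1.0]))


class TestStudies:
    def test_truncation_ballistic_alpha_two_everywhere(self, ballistic_ensemble):
        # partially filled last time bins shift alpha slightly off 2
        table = truncation_study(
            ballistic_ensemble.ensemble, [50.0, 100.0, 200.0], time_bin_ms=5.0
        )
        assert np.allclose(table.alpha, 2.0, atol=0.05)

    def test_truncation_inflates_brownian_alpha(self, brownian_ensemble):
        table = truncation_study(brownian_ensemble.ensemble, [100.0, 500.0])
        short = table.set_index("length_ms").loc[100.0, "alpha"]
        full = table.set_index("length_ms").loc[500.0, "alpha"]
        assert short >= full - 0.05

    def test_binning_identity_at_native_dt(self, ballistic_ensemble):
        curves, table = binning_study(
            ballistic_ensemble.ensemble, [1.0, 5.0], interval_ms=200.0
        )
        # at the native dt the resampling is the identity: msd = (v*tau)^2
        native = curves[1.0]
        assert np.allclose(native.msd_nm2, native.lags_ms**2, rtol=1e-9)
        # coarser bins keep the ballistic curve shape (partial last bins
        # perturb the largest lags only)
        assert np.allclose(table.alpha, 2.0, atol=0.05)

    def test_binning_alpha_stable_for_brownian(self, brownian_ensemble):
        _, table = binning_study(
            brownian_ensemble.ensemble, [2.0, 5.0, 10.0], interval_ms=500.0
        )
        assert table.alpha.max() - table.alpha.min() < 0.15


class TestTrackContainer:
    def test_nonmonotonic_times_rejected(self):
        with pytest.raises(ValueError):
            _track([0.0, 2.0, 1.0], [0, 1, 2], [0, 0, 0])

    def test_clipping_keeps_prefix(self):
        tr = _track(np.arange(10.0), np.arange(10.0), np.zeros(10))
        clipped = tr.clipped(4.0)
        assert len(clipped) == 5
        assert clipped.duration_ms == 4.0
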