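"""Velocity statistics, persistence-time fits, error correction, pooling."""

import numpy as np
import pytest

from bftrack.motility import (
    AcovEstimate,
    MotilityModel,
    MsdEstimate,
    correct_overdispersion,
    ensemble_msd,
    fit_exponential_acov,
    fit_extended_furth,
    furth_msd,
    pool_parameters,
    track_velocities,
    velocity_autocovariance,
)
from bftrack.synthetic import MotilityGroundTruth, add_positional_noise, simulate_ou_tracks
from bftrack.tracking import Track

from conftest import make_track

PX = 1.0  # most tests use pixel_size 1 so px == µm


class TestTrackVelocities:
    def test_stationary(self):
        segs = track_velocities(make_track([(2.0, 3.0)] * 10), dt=2.0, pixel_size=PX)
        assert len(segs) == 1
        np.testing.assert_array_equal(segs[0].velocities, 0.0)

    def test_uniform_motion(self):
        # 1 µm per 2-min frame in x
        t = make_track([(float(i), 0.0) for i in range(20)])
        segs = track_velocities(t, dt=2.0, pixel_size=1.0)
        np.testing.assert_allclose(segs[0].velocities, [[0.5, 0.0]] * 19)

    def test_circular_motion_speed(self):
        R, T, dt = 10.0, 120.0, 2.0
        n = 240
        th = 2 * np.pi * np.arange(n) * dt / T
        t = make_track(np.stack([R * np.cos(th), R * np.sin(th)], axis=1))
        (seg,) = track_velocities(t, dt=dt, pixel_size=1.0)
        speeds = np.hypot(*seg.velocities.T)
        # chord speed: (2R/dt) sin(pi dt / T) -> 2*pi*R/T as dt -> 0
        assert np.allclose(speeds, speeds[0])
        assert speeds[0] == pytest.approx(2 * np.pi * R / T, rel=np.pi * dt / T)

    def test_gap_splits_series(self):
        t = Track(0, frames=[0, 1, 2, 5, 6], positions=np.zeros((5, 2)))
        segs = track_velocities(t, dt=2.0, pixel_size=PX)
        assert [len(s.velocities) for s in segs] == [2, 1]

    def test_flagged_points_excluded(self):
        t = Track(
            0,
            frames=np.arange(6),
            positions=np.zeros((6, 2)),
            flags=[False, False, True, False, False, False],
        )
        segs = track_velocities(t, dt=1.0, pixel_size=PX)
        assert [len(s.velocities) for s in segs] == [1, 2]


class TestVelocityAutocovariance:
    def test_constant_velocity_gives_flat_acov(self):
        s = 1.5  # µm/min in x
        t = make_track([(s * 2.0 * i, 0.0) for i in range(50)])
        acov = velocity_autocovariance([t], max_lag=20.0, dt=2.0, pixel_size=1.0)
        np.testing.assert_allclose(acov.values, s**2, rtol=1e-12)

    def test_zero_lag_is_mean_squared_velocity(self, rng):
        tracks = [make_track(np.cumsum(rng.normal(0, 1, (40, 2)), axis=0)) for _ in range(5)]
        acov = velocity_autocovariance(tracks, max_lag=10.0, dt=2.0, pixel_size=1.0)
        v2 = []
        for t in tracks:
            for seg in track_velocities(t, 2.0, 1.0):
                v2.extend((seg.velocities**2).sum(axis=1))
        assert acov.values[0] == pytest.approx(np.mean(v2), rel=1e-12)

    def test_iid_velocities_decorrelate(self, rng):
        tracks = [
            make_track(np.cumsum(rng.normal(0, 2, (500, 2)), axis=0)) for _ in range(4)
        ]
        acov = velocity_autocovariance(tracks, max_lag=20.0, dt=2.0, pixel_size=1.0)
        nonzero = acov.lags > 0
        assert np.all(np.abs(acov.values[nonzero]) < 4 * acov.stderrs[nonzero])

    def test_ou_ensemble_matches_closed_form(self):
        """Ensemble acov tracks phi0*exp(-tau/P). Because products overlap in
        time, the honest error bar comes from between-cell scatter (cells are
        the independent unit), not the naive per-pair stderr."""
        gt = MotilityGroundTruth(P_true=35, phi0_true=0.18, n_cells=15, n_frames=360, seed=11)
        tracks = simulate_ou_tracks(gt)
        per_cell = np.stack(
            [
                velocity_autocovariance([t], max_lag=60.0, dt=2.0, pixel_size=0.977).values
                for t in tracks
            ]
        )
        mean = per_cell.mean(axis=0)
        sem = per_cell.std(axis=0, ddof=1) / np.sqrt(len(tracks))
        lags = np.arange(per_cell.shape[1]) * 2.0
        expected = 0.18 * np.exp(-lags / 35.0)
        assert np.all(np.abs(mean - expected) <= 3 * sem)

    def test_naive_stderr_underestimates_for_long_tracks(self):
        """The per-pair stderr is an underestimate for redundant data: the
        between-cell error bar exceeds it at long lags."""
        gt = MotilityGroundTruth(P_true=35, phi0_true=0.18, n_cells=15, n_frames=360, seed=11)
        tracks = simulate_ou_tracks(gt)
        acov = velocity_autocovariance(tracks, max_lag=60.0, dt=2.0, pixel_size=0.977)
        per_cell = np.stack(
            [
                velocity_autocovariance([t], max_lag=60.0, dt=2.0, pixel_size=0.977).values
                for t in tracks
            ]
        )
        sem = per_cell.std(axis=0, ddof=1) / np.sqrt(len(tracks))
        assert np.median(sem / acov.stderrs) > 1.5

    def test_n_pairs_non_increasing(self):
        t = make_track(np.arange(60, dtype=float).reshape(30, 2))
        acov = velocity_autocovariance([t], max_lag=20.0, dt=2.0, pixel_size=1.0)
        assert np.all(np.diff(acov.n_pairs) <= 0)


class TestExponentialFit:
    def _exact(self, phi0=0.2, P=30.0):
        lags = np.arange(0.0, 90.0, 2.0)
        return AcovEstimate(
            lags=lags,
            values=phi0 * np.exp(-lags / P),
            stderrs=np.full(lags.size, 1e-3),
            n_pairs=np.full(lags.size, 100),
        )

    def test_exact_data_recovered_to_six_digits(self):
        fit = fit_exponential_acov(self._exact())
        assert fit.P == pytest.approx(30.0, rel=1e-6)
        assert fit.phi0 == pytest.approx(0.2, rel=1e-6)
        assert fit.valid

    def test_downweighted_outlier_barely_moves_fit(self):
        clean = self._exact()
        base = fit_exponential_acov(clean, fit_range=(2.0, 88.0))
        dirty = self._exact()
        dirty.values[10] *= 3.0
        dirty.stderrs[10] = 10.0  # huge error bar: weight ~0
        refit = fit_exponential_acov(dirty, fit_range=(2.0, 88.0))
        assert abs(refit.P - base.P) < base.raw_errors["P"]
        assert abs(refit.phi0 - base.phi0) < base.raw_errors["phi0"]

    def test_too_few_lags_rejected(self):
        est = self._exact()
        with pytest.raises(ValueError):
            fit_exponential_acov(est, fit_range=(0.0, 3.0))


class TestEnsembleMsd:
    def test_stationary_zero(self):
        msd = ensemble_msd([make_track([(1.0, 2.0)] * 30)], 20.0, 2.0, 1.0)
        np.testing.assert_array_equal(msd.values, 0.0)

    def test_ballistic_quadratic(self):
        s = 0.7  # µm/min
        t = make_track([(s * 2.0 * i, 0.0) for i in range(100)])
        msd = ensemble_msd([t], max_lag=40.0, dt=2.0, pixel_size=1.0)
        np.testing.assert_allclose(msd.values, s**2 * msd.lags**2, rtol=1e-10)

    def test_pure_positional_noise_plateau(self):
        """Static cells + white centroid noise: MSD(tau>0) = 4 sigma_pos^2."""
        sigma = 1.4
        base = [make_track([(0.0, 0.0)] * 2000, track_id=i) for i in range(8)]
        noisy = add_positional_noise(base, sigma, seed=3, pixel_size=1.0)
        msd = ensemble_msd(noisy, max_lag=10.0, dt=2.0, pixel_size=1.0)
        plateau = msd.values[msd.lags > 0]
        np.testing.assert_allclose(plateau, 4 * sigma**2, rtol=0.05)


class TestFurthFit:
    def test_exact_curve_recovered(self):
        P, phi0, sig = 35.0, 0.18, 1.40
        lags = np.arange(2.0, 122.0, 2.0)
        msd = MsdEstimate(
            lags=lags,
            values=furth_msd(lags, P, phi0, 4 * sig**2),
            stderrs=np.full(lags.size, 1e-3),
            n_pairs=np.full(lags.size, 100),
        )
        fit = fit_extended_furth(msd)
        assert fit.P == pytest.approx(P, rel=1e-4)
        assert fit.phi0 == pytest.approx(phi0, rel=1e-4)
        assert fit.sigma_pos == pytest.approx(sig, rel=1e-4)

    def test_short_lag_ballistic_limit(self):
        """For tau << P the curve reduces to phi0 tau^2 + 4 sigma^2; a fit on
        short lags only must agree with a plain quadratic fit."""
        P, phi0, sig = 200.0, 0.18, 1.0
        lags = np.arange(1.0, 9.0, 1.0)  # tau <= 8 << P = 200
        vals = furth_msd(lags, P, phi0, 4 * sig**2)
        quad = np.polyfit(lags**2, vals, 1)
        assert quad[0] == pytest.approx(phi0, rel=0.03)
        assert quad[1] == pytest.approx(4 * sig**2, rel=0.05)

    def test_sigma_pos_recovery_from_noisy_ou(self):
        gt = MotilityGroundTruth(P_true=35, phi0_true=0.18, n_cells=15, n_frames=360, seed=21)
        tracks = add_positional_noise(simulate_ou_tracks(gt), 1.4, seed=22)
        msd = ensemble_msd(tracks, max_lag=240.0, dt=2.0, pixel_size=0.977)
        fit = fit_extended_furth(msd)
        assert fit.sigma_pos == pytest.approx(1.4, abs=0.3)

    def test_negative_offset_clamped_and_flagged(self):
        P, phi0 = 35.0, 0.18
        lags = np.arange(2.0, 82.0, 2.0)
        vals = furth_msd(lags, P, phi0, 0.0) - 0.5  # push offset negative
        msd = MsdEstimate(lags, vals, np.full(lags.size, 1e-2), np.full(lags.size, 100))
        fit = fit_extended_furth(msd)
        assert fit.sigma_pos == 0.0
        assert any("clamped" in f for f in fit.flags)


@pytest.fixture(scope="module")
def ou_setup():
    gt = MotilityGroundTruth(P_true=35, phi0_true=0.18, n_cells=12, n_frames=360, seed=31)
    tracks = simulate_ou_tracks(gt)
    acov = velocity_autocovariance(tracks, 105.0, 2.0, 0.977)
    fit = fit_exponential_acov(acov)
    return tracks, fit


class TestOverdispersionCorrection:

    def test_fixed_seed_is_bit_identical(self, ou_setup):
        tracks, fit = ou_setup
        a = correct_overdispersion(fit, tracks, 100, seed=5, dt=2.0, pixel_size=0.977)
        b = correct_overdispersion(fit, tracks, 100, seed=5, dt=2.0, pixel_size=0.977)
        assert a.corrected_errors == b.corrected_errors

    def test_redundant_data_inflates_errors(self, ou_setup):
        """Long overlapping tracks make acov points redundant; the bootstrap
        must report larger errors than the naive fit covariance."""
        tracks, fit = ou_setup
        corr = correct_overdispersion(fit, tracks, 200, seed=5, dt=2.0, pixel_size=0.977)
        assert corr.corrected_errors["P"] > fit.raw_errors["P"]
        assert corr.corrected_errors["phi0"] > fit.raw_errors["phi0"]

    def test_corrected_never_below_raw(self, ou_setup):
        tracks, fit = ou_setup
        corr = correct_overdispersion(fit, tracks, 100, seed=9, dt=2.0, pixel_size=0.977)
        for k in fit.raw_errors:
            assert corr.corrected_errors[k] >= fit.raw_errors[k]

    def test_independent_cells_short_tracks_no_inflation(self):
        """Many short tracks contribute nearly independent products, so the
        bootstrap error matches the naive one to ~20%."""
        gt = MotilityGroundTruth(P_true=10.0, phi0_true=0.2, dt=2.0,
                                 n_cells=400, n_frames=6, seed=41)
        tracks = simulate_ou_tracks(gt, min_spacing_um=5.0)
        acov = velocity_autocovariance(tracks, 8.0, 2.0, 0.977)
        fit = fit_exponential_acov(acov, fit_range=(2.0, 8.0))
        corr = correct_overdispersion(fit, tracks, 200, seed=7, dt=2.0,
                                      pixel_size=0.977, max_lag=8.0)
        for k in ("P", "phi0"):
            assert corr.corrected_errors[k] <= 1.2 * fit.raw_errors[k]

    def test_too_few_tracks_refused(self, ou_setup):
        tracks, fit = ou_setup
        with pytest.raises(ValueError, match="3 tracks"):
            correct_overdispersion(fit, tracks[:2], 100, 1, 2.0, 0.977)
        with pytest.raises(ValueError, match="n_boot"):
            correct_overdispersion(fit, tracks, 50, 1, 2.0, 0.977)


def test_corrected_interval_coverage_is_near_nominal():
    """Over 50 independent simulated movies (15 cells, 12 h, 2-min frames)
    the corrected 1σ intervals should cover the true (P, phi0) at roughly
    the nominal 68% rate — well above the naive-error coverage, but not
    overly conservative."""
    R, cov_P, cov_phi = 50, 0, 0
    for rep in range(R):
        gt = MotilityGroundTruth(P_true=35.0, phi0_true=0.18, n_cells=15,
                                 n_frames=360, seed=rep)
        model = MotilityModel(simulate_ou_tracks(gt), dt=2.0, pixel_size=0.977)
        fit = model.fit(method="acov", n_boot=100, seed=rep).fit
        cov_P += abs(fit.P - 35.0) <= fit.corrected_errors["P"]
        cov_phi += abs(fit.phi0 - 0.18) <= fit.corrected_errors["phi0"]
    assert 0.5 <= cov_P / R <= 0.85
    assert 0.5 <= cov_phi / R <= 0.85


def _fit_with_errors(P, phi0, errP, errphi):
    from bftrack.motility import MotilityFit

    return MotilityFit(
        P=P, phi0=phi0, sigma_pos=float("nan"),
        raw_errors={"P": errP, "phi0": errphi},
        covariance=np.diag([errphi**2, errP**2]),
        method="acov",
        corrected_errors={"P": errP, "phi0": errphi},
    )


class TestPooling:
    def test_identical_fits(self):
        fits = [_fit_with_errors(35.0, 0.18, 4.0, 0.02)] * 5
        pooled = pool_parameters(fits)
        assert pooled.P == pytest.approx(35.0)
        assert pooled.corrected_errors["P"] == pytest.approx(4.0 / np.sqrt(5))

    def test_hand_computed_weighted_mean(self):
        fits = [_fit_with_errors(30.0, 0.1, 3.0, 0.01), _fit_with_errors(42.0, 0.1, 6.0, 0.01)]
        pooled = pool_parameters(fits)
        assert pooled.P == pytest.approx(32.4, abs=0.05)
        assert pooled.corrected_errors["P"] == pytest.approx(2.683, abs=0.005)

    def test_permutation_invariance(self):
        fits = [
            _fit_with_errors(30.0, 0.15, 3.0, 0.02),
            _fit_with_errors(42.0, 0.21, 6.0, 0.03),
            _fit_with_errors(35.0, 0.18, 4.0, 0.01),
        ]
        a = pool_parameters(fits)
        b = pool_parameters(fits[::-1])
        assert (a.P, a.phi0) == pytest.approx((b.P, b.phi0))

    def test_zero_variance_rejected(self):
        fits = [_fit_with_errors(30.0, 0.1, 0.0, 0.01), _fit_with_errors(42.0, 0.1, 6.0, 0.01)]
        with pytest.raises(ValueError):
            pool_parameters(fits)


class TestModelFrontEnd:
    def test_fit_and_summary(self):
        gt = MotilityGroundTruth(n_cells=8, n_frames=240, seed=51)
        model = MotilityModel(simulate_ou_tracks(gt), dt=2.0, pixel_size=0.977)
        res = model.fit(method="acov", n_boot=100, seed=1)
        assert res.params["P"] > 0 and res.params["phi0"] > 0
        assert res.corrected_bse is not None
        text = res.summary()
        assert "P" in text and "phi0" in text and "µm²/min²" in text
        ci = res.conf_int()
        assert (ci["upper"] > ci["lower"]).all()

    def test_from_dataframe_roundtrip(self):
        from bftrack.io import tracks_to_dataframe

        gt = MotilityGroundTruth(n_cells=5, n_frames=100, seed=52)
        tracks = simulate_ou_tracks(gt)
        df = tracks_to_dataframe(tracks, dt=2.0, pixel_size=0.977)
        model = MotilityModel.from_dataframe(df, dt=2.0, pixel_size=0.977)
        direct = MotilityModel(tracks, dt=2.0, pixel_size=0.977)
        np.testing.assert_allclose(model.acov().values, direct.acov().values)

    def test_simulation_hangs_off_results(self):
        gt = MotilityGroundTruth(n_cells=6, n_frames=200, seed=53)
        model = MotilityModel(simulate_ou_tracks(gt), dt=2.0, pixel_size=0.977)
        res = model.fit(method="acov")
        sim = res.simulate(n_cells=4, n_frames=50, seed=2)
        assert len(sim) == 4 and all(len(t) == 50 for t in sim)
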