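"""Trajectory linking, MSD correction, power-law fits, velocity ACF."""

import numpy as np
import pandas as pd
import pytest

from livefish import (MSDCurve, Trajectory, compute_msd, ensemble_alpha,
                      ensemble_velocity_acf, estimate_msd_loc_error,
                      fbm_normalized_acf, fit_power_law, link_trajectories,
                      simulate_fbm_trajectory, velocity_acf)

DT = 1 / 3


def make_traj(xy, frames=None, locus_id=0):
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return Trajectory(locus_id=locus_id, frames=frames, xy_nm=xy,
                      frame_interval_s=DT)


def noisy_fbm_traj(alpha, d_app, n, rng, sigma=0.0, locus_id=0):
    gt = simulate_fbm_trajectory(alpha, d_app, n, DT, rng=rng)
    xy = gt.positions_nm
    if sigma > 0:
        xy = xy + rng.normal(0, sigma, xy.shape)
    return make_traj(xy, locus_id=locus_id)


class TestLinking:
    def loc_df(self, frames, xy):
        xy = np.asarray(xy, float)
        return pd.DataFrame({"frame": frames, "x_nm": xy[:, 0],
                             "y_nm": xy[:, 1]})

    def test_single_spot_full_length(self):
        xy = np.cumsum(np.full((20, 2), 50.0), axis=0)
        trajs = link_trajectories(self.loc_df(range(20), xy),
                                  max_disp_nm=800, frame_interval_s=DT)
        assert len(trajs) == 1
        assert len(trajs[0]) == 20

    def test_two_distant_loci_stay_separate(self, rng):
        n = 30
        a = rng.normal(0, 50, (n, 2))
        b = a + 10_000.0  # always > 2 * max_disp apart
        frames = np.repeat(np.arange(n), 2)
        xy = np.empty((2 * n, 2))
        xy[0::2], xy[1::2] = a, b
        trajs = link_trajectories(self.loc_df(frames, xy), max_disp_nm=800,
                                  frame_interval_s=DT)
        assert len(trajs) == 2
        assert all(len(t) == n for t in trajs)
        # each trajectory stays on one side
        spans = sorted(t.xy_nm.mean() for t in trajs)
        assert spans[1] - spans[0] > 5000

    def test_gap_longer_than_max_gap_splits(self):
        frames = [0, 1, 2, 6, 7, 8]  # 3 missing frames, max_gap=2
        xy = np.zeros((6, 2))
        trajs = link_trajectories(self.loc_df(frames, xy), max_disp_nm=800,
                                  max_gap_frames=2, frame_interval_s=DT)
        assert len(trajs) == 2

    def test_gap_within_max_gap_bridged(self):
        frames = [0, 1, 2, 5, 6, 7]  # 2 missing frames
        xy = np.zeros((6, 2))
        trajs = link_trajectories(self.loc_df(frames, xy), max_disp_nm=800,
                                  max_gap_frames=2, frame_interval_s=DT)
        assert len(trajs) == 1


class TestMSD:
    def test_ballistic_closed_form(self):
        """Straight-line motion x = v t gives MSD(tau) = v^2 tau^2 exactly."""
        v = 120.0  # nm/s
        t = np.arange(40) * DT
        traj = make_traj(np.column_stack([v * t, np.zeros_like(t)]))
        msd = compute_msd(traj, max_lag_fraction=0.5)
        assert np.allclose(msd.msd_raw_nm2, (v * msd.lags_s) ** 2, rtol=1e-12)

    def test_static_locus_with_noise(self, rng):
        """A static locus localized with per-axis noise sigma has
        MSD ~ 4 sigma^2 at every lag."""
        sigma = 27.0
        trajs = [make_traj(rng.normal(0, sigma, (100, 2)), locus_id=i)
                 for i in range(40)]
        msd = np.mean([compute_msd(t).msd_raw_nm2[:10] for t in trajs], axis=0)
        assert np.all(np.abs(msd / (4 * sigma ** 2) - 1) < 0.1)

    def test_brownian_slope_unity(self, rng):
        fits = []
        for i in range(100):
            traj = noisy_fbm_traj(1.0, 1e4, 100, rng)
            fits.append(fit_power_law(compute_msd(traj), (DT, 8 * DT),
                                      use_corrected=False))
        mean_a, _ = ensemble_alpha(fits)
        assert abs(mean_a - 1.0) < 0.05

    def test_correction_exactness(self, rng):
        traj = noisy_fbm_traj(0.5, 1e4, 60, rng, sigma=27)
        msd = compute_msd(traj).with_correction(2916.0)
        assert np.allclose(msd.msd_corrected_nm2 + 2916.0, msd.msd_raw_nm2)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(make_traj(np.zeros((3, 2))))


class TestLocErrorEstimate:
    def test_noiseless_identical_tracks_zero(self, rng):
        gt = simulate_fbm_trajectory(0.5, 1e4, 60, DT, rng=rng)
        t = make_traj(gt.positions_nm)
        assert estimate_msd_loc_error(t, t) == pytest.approx(0.0, abs=1e-9)

    def test_equal_noise_returns_4_sigma_sq(self, rng):
        """Both channels with sigma = 27 nm/axis: the returned per-channel
        constant is 4 sigma^2 = 2916 nm^2, whether the locus moves or not."""
        sigma = 27.0
        for d_app in (0.0, 1e4):
            vals = []
            for _ in range(30):
                gt = simulate_fbm_trajectory(0.5, d_app, 120, DT, rng=rng)
                t1 = make_traj(gt.positions_nm + rng.normal(0, sigma, (120, 2)))
                t2 = make_traj(gt.positions_nm + rng.normal(0, sigma, (120, 2)))
                vals.append(estimate_msd_loc_error(t1, t2))
            assert abs(np.mean(vals) / (4 * sigma ** 2) - 1) < 0.1

    def test_one_sided_noise_biased_by_factor_two(self, rng):
        """If only one channel is noisy the equal-error assumption halves
        the true constant: returned value is 2 sigma^2 instead of 4 sigma^2
        (documented behavior)."""
        sigma = 27.0
        vals = []
        for _ in range(30):
            gt = simulate_fbm_trajectory(0.5, 0.0, 120, DT, rng=rng)
            t1 = make_traj(gt.positions_nm + rng.normal(0, sigma, (120, 2)))
            t2 = make_traj(gt.positions_nm)
            vals.append(estimate_msd_loc_error(t1, t2))
        assert abs(np.mean(vals) / (2 * sigma ** 2) - 1) < 0.1

    def test_too_few_aligned_frames(self):
        a = make_traj(np.zeros((5, 2)))
        b = make_traj(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            estimate_msd_loc_error(a, b)


class TestPowerLawFit:
    def test_exact_power_law_table(self):
        lags = np.arange(1, 31) * DT
        msd = MSDCurve(lags_s=lags, msd_raw_nm2=4 * 250 * lags ** 0.5,
                       counts=np.full(30, 100))
        fit = fit_power_law(msd, (DT, 10.0), use_corrected=False)
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)
        assert fit.d_app == pytest.approx(1000.0, rel=1e-6)
        assert fit.r_squared > 1 - 1e-12

    def test_too_few_lags_rejected(self):
        lags = np.array([1.0, 2.0])
        msd = MSDCurve(lags_s=lags, msd_raw_nm2=lags, counts=[1, 1])
        with pytest.raises(ValueError):
            fit_power_law(msd, (0.5, 3.0), use_corrected=False)

    def test_nonpositive_corrected_lags_excluded(self):
        lags = np.arange(1, 11) * DT
        raw = 4 * 250 * lags ** 0.5
        msd = MSDCurve(lags_s=lags, msd_raw_nm2=raw,
                       counts=np.full(10, 10)).with_correction(raw[2] + 1)
        fit = fit_power_law(msd, (DT, 10.0))
        assert fit.n_lags == 7

    @pytest.mark.parametrize("alpha", [0.35, 0.5, 0.75, 1.0])
    def test_exponent_recovery_with_correction(self, alpha, rng):
        """30 noisy trajectories x 200 frames: corrected ensemble exponent
        within +-0.05 of truth. Without correction the constant noise floor
        flattens the log-log curve at small lags, biasing alpha downward."""
        sigma = 27.0
        fits_corr, fits_raw = [], []
        for i in range(30):
            traj = noisy_fbm_traj(alpha, 1e4, 200, rng, sigma=sigma)
            msd = compute_msd(traj).with_correction(4 * sigma ** 2)
            fits_corr.append(fit_power_law(msd, (0.33, 10.0)))
            fits_raw.append(fit_power_law(msd, (0.33, 10.0),
                                          use_corrected=False))
        mean_corr, _ = ensemble_alpha(fits_corr)
        mean_raw, _ = ensemble_alpha(fits_raw)
        assert abs(mean_corr - alpha) < 0.05
        if alpha < 1.0:
            assert mean_raw < mean_corr  # directional bias of raw fits


class TestVelocityACF:
    def test_constant_velocity_acf_is_one(self):
        t = np.arange(60) * DT
        traj = make_traj(np.column_stack([100 * t, 50 * t]))
        acf = velocity_acf(traj, delta_frames=2)
        assert np.allclose(acf.cv_normalized, 1.0)
        assert np.allclose(acf.tau_over_delta * acf.delta_s, acf.lags_s)

    def test_brownian_acf_zero_at_delta(self, rng):
        trajs = [noisy_fbm_traj(1.0, 1e4, 100, rng, locus_id=i)
                 for i in range(300)]
        acf = ensemble_velocity_acf(trajs, delta_frames=1)
        norm = acf.cv_normalized
        assert abs(norm[1]) < 0.03  # independent increments

    def test_fbm_negative_dip_matches_closed_form(self, rng):
        """alpha=0.5 ensemble: normalized ACF at tau=delta equals
        2^(alpha-1) - 1 = -0.2929 within 3 SE, and lags tau/delta in
        {0,1,2,3} match the fBm increment autocovariance."""
        alpha, n_traj = 0.5, 600
        per_traj = []
        for i in range(n_traj):
            traj = noisy_fbm_traj(alpha, 1e4, 64, rng, locus_id=i)
            a = velocity_acf(traj, delta_frames=1, max_lag_frames=3)
            per_traj.append(a.cv / a.cv[0])
        per_traj = np.array(per_traj)
        mean = per_traj.mean(axis=0)
        se = per_traj.std(axis=0, ddof=1) / np.sqrt(n_traj)
        theory = fbm_normalized_acf(alpha, np.arange(4))
        assert theory[1] == pytest.approx(2 ** (alpha - 1) - 1, abs=1e-12)
        for k in range(4):
            assert abs(mean[k] - theory[k]) < 3 * se[k] + 0.01, f"lag {k}"

    def test_self_similar_collapse_across_delta(self, rng):
        """Normalized ACF curves for delta and 2*delta agree on the common
        rescaled tau/delta grid within pooled sampling error."""
        alpha = 0.5
        trajs = [noisy_fbm_traj(alpha, 1e4, 128, rng, locus_id=i)
                 for i in range(200)]
        curves = {}
        for delta in (1, 2, 4):
            acf = ensemble_velocity_acf(trajs, delta, max_lag_frames=4 * delta)
            curves[delta] = dict(zip(np.round(acf.tau_over_delta, 9),
                                     acf.cv_normalized))
        for d1, d2 in ((1, 2), (2, 4)):
            common = sorted(set(curves[d1]) & set(curves[d2]))
            assert len(common) >= 3
            gaps = [abs(curves[d1][u] - curves[d2][u]) for u in common]
            assert max(gaps) < 0.08

    def test_delta_validation(self):
        traj = make_traj(np.zeros((30, 2)) + np.arange(30)[:, None])
        with pytest.raises(ValueError):
            velocity_acf(traj, delta_frames=0)
        with pytest.raises(ValueError):
            velocity_acf(traj, delta_frames=11)  # length < 3 * delta
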