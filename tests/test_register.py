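"""Two-color registration: fiducial matching, warp fitting, QC."""

import numpy as np
import pytest

from livefish import (QuadraticWarp, SimConfig, apply_warp, fit_warp,
                      match_fiducials, rms_2d, simulate_bead_field)
from livefish.register import WarpModel2


def grid_points(n_side=8, lo=0.0, hi=127.0):
    g = np.linspace(lo, hi, n_side)
    return np.array([[x, y] for x in g for y in g])


class TestMatchFiducials:
    def test_identical_sets_match_self(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        pairs = match_fiducials(pts, pts, max_dist=2)
        assert len(pairs) == 30
        assert np.array_equal(pairs.ref_idx, pairs.mov_idx)

    def test_uniform_offset_keeps_correspondence(self, rng):
        pts = rng.uniform(0, 100, (40, 2))
        pairs = match_fiducials(pts, pts + 0.5, max_dist=2)
        assert len(pairs) == 40
        assert np.array_equal(pairs.ref_idx, pairs.mov_idx)

    def test_order_invariance(self, rng):
        pts = rng.uniform(0, 100, (25, 2))
        mov = pts + rng.normal(0, 0.1, pts.shape)
        perm = rng.permutation(25)
        a = match_fiducials(pts, mov, max_dist=2)
        b = match_fiducials(pts, mov[perm], max_dist=2)
        # same geometric pairs regardless of input order
        got_a = {(i, tuple(np.round(xy, 9))) for i, xy in
                 zip(a.ref_idx, a.mov_xy)}
        got_b = {(i, tuple(np.round(xy, 9))) for i, xy in
                 zip(b.ref_idx, b.mov_xy)}
        assert got_a == got_b

    def test_too_few_pairs_is_error(self, rng):
        pts = rng.uniform(0, 100, (4, 2))
        with pytest.raises(ValueError):
            match_fiducials(pts, pts, max_dist=2)


class TestFitWarp:
    def test_known_quadratic_warp_recovered_exactly(self, rng):
        """Noiseless beads under a known quadratic distortion: raw
        coefficients recovered to 1e-9 relative, residual rms ~ 0."""
        warp = QuadraticWarp.random(rng)
        src = grid_points()
        model, qc = fit_warp(src, warp(src), src_label="reference",
                             dst_label="moving")
        rel = np.abs(model.as_raw_warp().coeffs - warp.coeffs) / \
            np.maximum(np.abs(warp.coeffs), 1e-9)
        assert np.max(rel) < 1e-9
        assert qc.rms_2d < 1e-9

    def test_identity_correspondence_gives_identity(self, rng):
        pts = rng.uniform(0, 127, (30, 2))
        model, qc = fit_warp(pts, pts)
        assert model.as_raw_warp().is_identity(atol=1e-9)
        assert qc.rms_2d < 1e-9

    def test_qc_quadrature_consistency(self, rng):
        warp = QuadraticWarp.random(rng)
        src = grid_points()
        dst = warp(src) + rng.normal(0, 0.1, src.shape)
        _, qc = fit_warp(src, dst)
        assert qc.rms_2d == pytest.approx(
            np.hypot(qc.rms_x, qc.rms_y), rel=1e-12)
        assert qc.loo_rms_2d == pytest.approx(
            np.hypot(qc.loo_rms_x, qc.loo_rms_y), rel=1e-12)

    def test_rank_deficient_geometry_raises(self):
        x = np.linspace(0, 100, 20)
        collinear = np.column_stack([x, 2 * x + 1])
        with pytest.raises(ValueError, match="degenerate|rank"):
            fit_warp(collinear, collinear)

    def test_loo_rms_matches_least_squares_theory(self):
        """100 beads, 15 nm one-sided noise: mean LOO rms per axis ~
        15 * sqrt(1 + 6/100) nm over Monte-Carlo repeats."""
        sigma, n_beads, reps = 15.0, 100, 60
        cfg = SimConfig()
        vals = []
        for s in range(reps):
            bf = simulate_bead_field(n_beads, QuadraticWarp.identity(),
                                     sigma, cfg, seed=500 + s)
            pairs = match_fiducials(bf.ref_xy_px, bf.mov_xy_px, max_dist=2)
            _, qc = fit_warp(pairs)
            vals.append([qc.loo_rms_x, qc.loo_rms_y])
        got = np.mean(vals) * cfg.pixel_size_nm
        expect = sigma * np.sqrt(1 + 6 / n_beads)
        assert abs(got / expect - 1) < 0.05

    def test_noise_floor_two_noisy_channels(self):
        """Cross-validated per-axis error approaches sigma * sqrt(2) from
        above as the bead count grows (noise in both channels)."""
        sigma = 15.0
        cfg = SimConfig()
        means = []
        for n_beads in (10, 30, 100, 300):
            vals = []
            for s in range(12):
                bf = simulate_bead_field(n_beads, QuadraticWarp.identity(),
                                         sigma, cfg, seed=7000 + s,
                                         noise_ref_nm=sigma)
                _, qc = fit_warp(match_fiducials(bf.ref_xy_px, bf.mov_xy_px,
                                                 max_dist=3))
                vals.append(0.5 * (qc.loo_rms_x + qc.loo_rms_y))
            means.append(np.mean(vals) * cfg.pixel_size_nm)
        floor = sigma * np.sqrt(2)
        assert means[0] > means[-1]                 # decreasing toward floor
        assert abs(means[-1] / floor - 1) < 0.10    # near sigma*sqrt(2) at n=300


class TestApplyWarp:
    def test_identity_model_returns_input(self):
        model = WarpModel2(coeffs=QuadraticWarp.identity().coeffs,
                           center=np.zeros(2), scale=np.ones(2))
        pts = np.array([[3.0, 4.0], [10.0, -2.0]])
        assert np.allclose(apply_warp(model, pts), pts)

    def test_hand_computed_polynomial_value(self):
        coeffs = np.array([[1.0, 2.0, 0.0, 0.5, 0.0, 0.0],   # 1 + 2x + x^2/2
                           [0.0, 0.0, 1.0, 0.0, 1.0, 0.0]])  # y + xy
        model = WarpModel2(coeffs=coeffs, center=np.zeros(2),
                           scale=np.ones(2))
        out = model.transform([[2.0, 3.0]])
        assert np.allclose(out, [[1 + 4 + 2.0, 3 + 6.0]])

    def test_unit_mismatch_rejected(self):
        model = WarpModel2(coeffs=QuadraticWarp.identity().coeffs,
                           center=np.zeros(2), scale=np.ones(2), units="px")
        with pytest.raises(ValueError):
            model.transform([[1.0, 1.0]], units="nm")

    def test_held_out_residual_at_noise_level(self, rng):
        warp = QuadraticWarp.random(rng)
        cfg = SimConfig()
        bf = simulate_bead_field(200, warp, 15.0, cfg, seed=42)
        pairs = match_fiducials(bf.ref_xy_px, bf.mov_xy_px, max_dist=3)
        model, _ = fit_warp(pairs)
        held = simulate_bead_field(200, warp, 15.0, cfg, seed=43)
        resid = (model.transform(held.mov_xy_px) - held.ref_xy_px)
        rms_nm = np.sqrt(np.mean(resid ** 2)) * cfg.pixel_size_nm
        assert abs(rms_nm - 15.0) < 3.0

    def test_roundtrip_json(self, tmp_path, rng):
        warp = QuadraticWarp.random(rng)
        src = grid_points()
        model, qc = fit_warp(src, warp(src))
        p = tmp_path / "warp.json"
        model.to_json(p, qc=qc)
        back = WarpModel2.from_json(p)
        pts = rng.uniform(0, 127, (10, 2))
        assert np.allclose(back.transform(pts), model.transform(pts))


@pytest.mark.parametrize("x, y, expect", [
    (21.0, 25.0, 32.649655434629018),
    (0.0, 0.0, 0.0),
    (21.0, 0.0, 21.0),
])
def test_rms_2d_quadrature(x, y, expect):
    assert rms_2d(x, y) == pytest.approx(expect, abs=1e-9)


def test_rms_2d_rejects_negative():
    with pytest.raises(ValueError):
        rms_2d(-1.0, 1.0)
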