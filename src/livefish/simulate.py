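"""Forward model: render locus trajectories into camera movies.

The renderer reproduces the statistical structure of the real acquisitions
the analysis chain was designed for: diffraction-limited puncta on a noisy
nuclear background, imaged on an EM-CCD through a quad-view device so that
the second color channel sees the field through a small chromatic
distortion (a quadratic coordinate warp).

Physics implemented per pixel:

    counts = offset + gain * Poisson(signal + background) + N(0, read_noise)

clipped to the unsigned 16-bit range.  ``signal`` is the *integrated*
2D Gaussian PSF over the pixel area (error-function quadrature), not a point
sample — at 160 nm/px the PSF sigma is ~1.3 px and pixel integration
matters.  The EM gain is a plain multiplier (no excess-noise factor), a
documented simplification.

Coordinate conventions: 0-based pixel indices; a spot "at pixel (i, j)" is
centered at the center of that pixel; x runs along columns, y along rows;
nm = px * pixel_size_nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

from .config import SimConfig
from .fbm import LocusGroundTruth
from .warp import QuadraticWarp


@dataclass
class FrameStack:
    """A single-channel movie with physical calibration."""

    data: np.ndarray  # (T, H, W)
    pixel_size_nm: float
    frame_interval_s: float
    channel: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (T, H, W)")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def save_tiff(self, path) -> None:
        tifffile.imwrite(path, self.data, photometric="minisblack")

    @classmethod
    def load_tiff(cls, path, pixel_size_nm: float, frame_interval_s: float,
                  channel: int = 1) -> "FrameStack":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        return cls(data=data, pixel_size_nm=pixel_size_nm,
                   frame_interval_s=frame_interval_s, channel=channel)


def integrated_gaussian_spot(
    shape: tuple[int, int],
    x0_px: float,
    y0_px: float,
    sigma_px: float,
    photons: float,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Add one PSF to an expectation image (photon units).

    The flux in pixel (r, c), which covers [c-0.5, c+0.5] x [r-0.5, r+0.5],
    is the product of the two 1D Gaussian integrals over that square.  Only
    a +-(6 sigma + 2) px window around the center is touched.
    """
    h, w = shape
    if out is None:
        out = np.zeros(shape)
    half = int(math.ceil(6.0 * sigma_px + 2.0))
    c0 = max(0, int(math.floor(x0_px)) - half)
    c1 = min(w, int(math.ceil(x0_px)) + half + 1)
    r0 = max(0, int(math.floor(y0_px)) - half)
    r1 = min(h, int(math.ceil(y0_px)) + half + 1)
    if c0 >= c1 or r0 >= r1:
        return out
    s = sigma_px * math.sqrt(2.0)
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    fx = 0.5 * (erf((cols + 0.5 - x0_px) / s) - erf((cols - 0.5 - x0_px) / s))
    fy = 0.5 * (erf((rows + 0.5 - y0_px) / s) - erf((rows - 0.5 - y0_px) / s))
    out[r0:r1, c0:c1] += photons * np.outer(fy, fx)
    return out


def _camera(expected_photons: np.ndarray, config: SimConfig,
            rng: np.random.Generator | None) -> np.ndarray:
    if config.deterministic or rng is None:
        return config.camera_offset + config.camera_gain * expected_photons
    counts = config.camera_gain * rng.poisson(expected_photons).astype(float)
    counts += config.camera_offset
    if config.read_noise_counts > 0:
        counts += rng.normal(0.0, config.read_noise_counts, counts.shape)
    return np.clip(np.rint(counts), 0, 65535).astype(np.uint16)


def render_movie(
    loci: list[LocusGroundTruth],
    warp: QuadraticWarp | None,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[dict[int, FrameStack], pd.DataFrame]:
    """Render per-channel movies plus a ground-truth table.

    Channel 1 is the reference channel; channel-2 rendering positions are the
    true reference-frame positions passed through ``warp`` (the physical
    reference -> moving chromatic distortion, pixel units).  A dual-tagged
    locus (channels=(1, 2)) is therefore rendered in both movies at the same
    true reference position.

    Loci drifting out of the field of view are not rendered in the affected
    frames and flagged ``in_fov=False`` in the truth table.

    Returns
    -------
    movies : dict channel -> FrameStack
    truth : DataFrame with columns (frame, locus_id, channel, x_px, y_px,
        x_nm, y_nm, photons, in_fov); x/y_px are the rendered per-channel
        pixel coordinates, x/y_nm the reference-frame positions.
    """
    if warp is None:
        warp = QuadraticWarp.identity()
    if seed is None:
        seed = config.seed
    h, w = config.image_shape
    n_frames = config.n_frames
    channels = sorted({c for locus in loci for c in locus.channels}) or [1]

    rows = []
    spots: dict[int, list[list[tuple[float, float, float]]]] = {
        c: [[] for _ in range(n_frames)] for c in channels
    }
    for locus in loci:
        ref_px = locus.positions_nm / config.pixel_size_nm
        n = min(n_frames, locus.n_frames)
        for c in locus.channels:
            pos_px = ref_px if c == 1 else warp(ref_px)
            for t in range(n):
                x, y = pos_px[t]
                in_fov = (0.0 <= x <= w - 1.0) and (0.0 <= y <= h - 1.0)
                if in_fov:
                    spots[c][t].append((x, y, config.photons_per_spot))
                rows.append(
                    dict(frame=t, locus_id=locus.locus_id, channel=c,
                         x_px=x, y_px=y,
                         x_nm=locus.positions_nm[t, 0],
                         y_nm=locus.positions_nm[t, 1],
                         photons=config.photons_per_spot, in_fov=in_fov)
                )
    truth = pd.DataFrame(
        rows, columns=["frame", "locus_id", "channel", "x_px", "y_px",
                       "x_nm", "y_nm", "photons", "in_fov"]
    ).sort_values(["channel", "frame", "locus_id"]).reset_index(drop=True)

    # independent, reproducible noise stream per channel
    streams = np.random.SeedSequence(seed).spawn(len(channels))
    movies: dict[int, FrameStack] = {}
    for ss, c in zip(streams, channels):
        rng = None if config.deterministic else np.random.default_rng(ss)
        dtype = float if config.deterministic else np.uint16
        data = np.empty((n_frames, h, w), dtype=dtype)
        for t in range(n_frames):
            expected = np.full((h, w), float(config.background_photons))
            for x, y, photons in spots[c][t]:
                integrated_gaussian_spot((h, w), x, y, config.psf_sigma_px,
                                         photons, out=expected)
            data[t] = _camera(expected, config, rng)
        movies[c] = FrameStack(data=data, pixel_size_nm=config.pixel_size_nm,
                               frame_interval_s=config.frame_interval_s,
                               channel=c)
    return movies, truth


@dataclass
class BeadField:
    """Matched fiducial point sets in the two channels (pixel units)."""

    ref_xy_px: np.ndarray  # (N, 2), reference channel
    mov_xy_px: np.ndarray  # (N, 2), moving channel
    warp: QuadraticWarp    # the ground-truth reference -> moving distortion

    def __post_init__(self) -> None:
        self.ref_xy_px = np.asarray(self.ref_xy_px, dtype=float)
        self.mov_xy_px = np.asarray(self.mov_xy_px, dtype=float)
        if self.ref_xy_px.shape != self.mov_xy_px.shape:
            raise ValueError("point sets must have matching shapes")


def simulate_bead_field(
    n_beads: int,
    warp: QuadraticWarp,
    loc_noise_nm: float,
    config: SimConfig,
    seed: int | None = None,
    noise_ref_nm: float = 0.0,
) -> BeadField:
    """Simulate a multicolor fiducial-bead calibration field.

    Reference positions are uniform over the field of view; moving-channel
    positions are warp(reference) plus independent Gaussian localization
    noise of ``loc_noise_nm`` per axis.  ``noise_ref_nm`` optionally adds
    noise to the reference channel too (both channels of a real bead stack
    are localized with finite precision).

    At least 6 beads are required to determine the 12 quadratic warp
    coefficients downstream.
    """
    if n_beads < 6:
        raise ValueError("n_beads must be >= 6 (warp is under-determined)")
    if loc_noise_nm < 0 or noise_ref_nm < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.image_shape
    ref = np.column_stack([
        rng.uniform(0.0, w - 1.0, n_beads),
        rng.uniform(0.0, h - 1.0, n_beads),
    ])
    mov = warp(ref)
    noise_px = loc_noise_nm / config.pixel_size_nm
    if noise_px > 0:
        mov = mov + rng.normal(0.0, noise_px, mov.shape)
    if noise_ref_nm > 0:
        ref = ref + rng.normal(0.0, noise_ref_nm / config.pixel_size_nm, ref.shape)
    return BeadField(ref_xy_px=ref, mov_xy_px=mov, warp=warp)
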