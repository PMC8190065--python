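import numpy as np
import pytest

from livefish import SimConfig, LocusGroundTruth, render_movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def static_locus(x_px, y_px, locus_id=0, pixel_size_nm=160.0, n_frames=1,
                 channels=(1,)):
    """A motionless ground-truth locus at the given pixel position."""
    pos = np.tile([[x_px * pixel_size_nm, y_px * pixel_size_nm]], (n_frames, 1))
    return LocusGroundTruth(locus_id=locus_id, positions_nm=pos, alpha=0.5,
                            d_app=0.0, frame_interval_s=1 / 3,
                            channels=channels)


def render_single_spot(x_px, y_px, seed=0, deterministic=False,
                       shape=(32, 32), **cfg_kwargs):
    """One-frame movie containing a single spot; returns (image, config)."""
    cfg = SimConfig(image_shape=shape, n_frames=1, seed=seed,
                    deterministic=deterministic, **cfg_kwargs)
    movies, _ = render_movie([static_locus(x_px, y_px)], None, cfg)
    return movies[1].data[0], cfg
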