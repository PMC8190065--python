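"""Imaging / simulation configuration.

The defaults encode the acquisition geometry of the study system this
package targets: an EM-CCD at 160 nm/pixel final magnification, movies at
3 frames per second, diffraction-limited puncta with a PSF standard
deviation of ~1.3 px, and a photon budget chosen so that single-frame
localization precision lands near 27 nm per axis (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field


@dataclass
class SimConfig:
    """Physical and camera parameters of a simulated acquisition.

    Attributes
    ----------
    pixel_size_nm : float
        Object-space length of one camera pixel (nm).
    frame_interval_s : float
        Time between consecutive frames (s).
    image_shape : tuple[int, int]
        (H, W) of each frame, in pixels.
    n_frames : int
        Number of frames per movie.
    psf_sigma_px : float
        Gaussian PSF standard deviation per axis, in pixels.
    photons_per_spot : float
        Expected signal photons collected per spot per frame.
    background_photons : float
        Expected background photons per pixel per frame.
    camera_gain : float
        Camera counts per detected photon.
    camera_offset : float
        Camera baseline, in counts.
    read_noise_counts : float
        Gaussian read-noise standard deviation, in counts.
    deterministic : bool
        If True the renderer emits the noise-free expectation image
        (float64, no Poisson/read noise, no quantization).
    seed : int | None
        Seed for all randomness derived from this config.
    """

    pixel_size_nm: float = 160.0
    frame_interval_s: float = 1.0 / 3.0
    image_shape: tuple[int, int] = (128, 128)
    n_frames: int = 50
    psf_sigma_px: float = 1.3
    photons_per_spot: float = 330.0
    background_photons: float = 20.0
    camera_gain: float = 2.0
    camera_offset: float = 100.0
    read_noise_counts: float = 2.0
    deterministic: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        h, w = self.image_shape
        if h < 1 or w < 1:
            raise ValueError("image_shape must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        for name in ("photons_per_spot", "background_photons", "camera_gain",
                     "read_noise_counts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.image_shape = tuple(int(v) for v in self.image_shape)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)
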