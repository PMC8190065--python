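"""Exact fractional Brownian motion sampling for chromatin-locus trajectories.

Genomic loci in interphase nuclei move sub-diffusively, MSD_2D(t) = D_app *
t**alpha with alpha <= 1.  Fractional Brownian motion (fBm) is the standard
Gaussian, self-similar model for this behaviour: per-axis increments over
one frame are stationary Gaussians with autocovariance

    gamma(k) = (sigma2/2) * (|k+1|**alpha - 2|k|**alpha + |k-1|**alpha)

where sigma2 is the one-step variance and k the lag in steps.  This module
samples increments *exactly* by Cholesky factorization of that Toeplitz
covariance, so it can serve as its own oracle in tests: the sampled process
has the target covariance to machine precision, not asymptotically.

Conventions (shared with :mod:`livefish.dynamics`):

* MSD_2D(t) = D_app * t**alpha, the two axes contributing equally, so the
  per-axis one-step variance is (D_app / 2) * dt**alpha.
* D_app carries units nm^2 / s**alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, toeplitz

#: Cholesky factorization is O(n^3) / O(n^2) memory; beyond this length the
#: exactness guarantee is not worth the cost and the request is rejected.
MAX_EXACT_STEPS = 2048


def increment_autocovariance(alpha: float, lags, step_var: float = 1.0) -> np.ndarray:
    """Closed-form autocovariance of unit-time fBm increments.

    gamma(0) equals ``step_var``; for alpha == 1 (Brownian motion) all
    nonzero lags give exactly 0.
    """
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * step_var * (
        (k + 1.0) ** alpha - 2.0 * k ** alpha + np.abs(k - 1.0) ** alpha
    )


def _check_params(alpha: float, dt: float) -> None:
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")


def sample_fbm_increments(
    alpha: float,
    n_increments: int,
    step_var: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw ``size`` independent exact fBm increment series of given length.

    Returns an array of shape (size, n_increments).
    """
    if n_increments < 1:
        raise ValueError("n_increments must be >= 1")
    if n_increments > MAX_EXACT_STEPS:
        raise ValueError(
            f"exact sampling limited to {MAX_EXACT_STEPS} steps, "
            f"got {n_increments}"
        )
    gamma = increment_autocovariance(alpha, np.arange(n_increments), step_var)
    if step_var == 0.0:
        return np.zeros((size, n_increments))
    L = cholesky(toeplitz(gamma), lower=True)
    z = rng.standard_normal((size, n_increments))
    return z @ L.T


@dataclass
class LocusGroundTruth:
    """True motion of one simulated genomic locus.

    positions_nm holds the per-frame true (x, y) in the reference channel's
    coordinate frame; a dual-tagged locus (channels=(1, 2)) has, by
    construction, identical true positions in both channels at every frame.
    """

    locus_id: int
    positions_nm: np.ndarray  # (T, 2)
    alpha: float
    d_app: float  # nm^2 / s^alpha
    frame_interval_s: float
    channels: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        if self.positions_nm.ndim != 2 or self.positions_nm.shape[1] != 2:
            raise ValueError("positions_nm must be (T, 2)")
        if not np.all(np.isfinite(self.positions_nm)):
            raise ValueError("positions must be finite")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.d_app < 0:
            raise ValueError("d_app must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.positions_nm.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def simulate_fbm_trajectory(
    alpha: float,
    d_app: float,
    n_steps: int,
    dt: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    locus_id: int = 0,
    origin=(0.0, 0.0),
    channels: tuple[int, ...] = (1,),
) -> LocusGroundTruth:
    """Simulate one 2D fBm locus trajectory of ``n_steps`` positions.

    Parameters
    ----------
    alpha : float in (0, 1]
        Anomalous exponent; 1 is Brownian, 0.5 is Rouse-like monomer motion.
    d_app : float
        Generalized diffusion coefficient, nm^2 / s**alpha, in the 2D
        convention MSD_2D(t) = d_app * t**alpha.
    n_steps : int >= 2
        Number of positions (so n_steps - 1 increments).
    dt : float
        Frame interval in seconds.

    The x and y axes are independent fBm processes, each with one-step
    variance (d_app / 2) * dt**alpha.
    """
    _check_params(alpha, dt)
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if d_app < 0:
        raise ValueError("d_app must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    step_var = 0.5 * d_app * dt ** alpha
    inc = sample_fbm_increments(alpha, n_steps - 1, step_var, rng, size=2)
    pos = np.empty((n_steps, 2))
    pos[0] = origin
    pos[1:] = np.asarray(origin) + np.cumsum(inc.T, axis=0)
    return LocusGroundTruth(
        locus_id=locus_id,
        positions_nm=pos,
        alpha=alpha,
        d_app=d_app,
        frame_interval_s=dt,
        channels=channels,
    )
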