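"""Chromatin-locus dynamics: linking, MSD, power-law fits, velocity ACF.

The motion statistics follow the standard single-particle-tracking recipe
for genomic loci:

* per-frame localizations are linked into trajectories (greedy mutual
  nearest neighbor with bounded gap closing);
* the time-averaged MSD of each trajectory is corrected for localization
  error by subtracting a constant, MSD_loc_error, estimated from the
  relative motion of one locus tagged simultaneously in two colors;
* log(MSD) vs log(tau) is fitted per locus, MSD_2D(t) = D_app * t**alpha,
  and the ensemble exponent reported as mean +- SE over loci;
* the velocity autocorrelation C_v(tau) of finite-difference velocities
  v(t) = (r(t + delta) - r(t)) / delta exhibits a negative dip at tau =
  delta for anti-persistent (viscoelastic) motion — for fBm the normalized
  dip is 2**(alpha - 1) - 1 — and curves for different delta collapse on
  the rescaled axis tau / delta when the motion is self-similar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fbm import increment_autocovariance

logger = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Time-ordered localizations of one locus in one channel."""

    locus_id: int
    frames: np.ndarray        # (T,) strictly increasing ints
    xy_nm: np.ndarray         # (T, 2)
    frame_interval_s: float
    channel: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy_nm = np.asarray(self.xy_nm, dtype=float)
        if self.frames.ndim != 1 or self.xy_nm.shape != (self.frames.size, 2):
            raise ValueError("frames (T,) and xy_nm (T, 2) must align")
        if self.frames.size < 2:
            raise ValueError("a trajectory needs >= 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    def __len__(self) -> int:
        return self.frames.size

    @property
    def times_s(self) -> np.ndarray:
        return self.frames * self.frame_interval_s

    def dense_positions(self) -> np.ndarray:
        """Positions on the full frame grid, NaN where the locus was missed."""
        span = self.frames[-1] - self.frames[0] + 1
        dense = np.full((span, 2), np.nan)
        dense[self.frames - self.frames[0]] = self.xy_nm
        return dense


def link_trajectories(
    locs: pd.DataFrame,
    max_disp_nm: float = 800.0,
    max_gap_frames: int = 2,
    frame_interval_s: float = 1.0 / 3.0,
    channel: int | None = None,
) -> list[Trajectory]:
    """Greedy nearest-neighbor linking of a localization table.

    locs needs columns (frame, x_nm, y_nm); rows with converged == False
    are dropped if the column exists.  Links are formed per frame, closest
    pair first (ties broken by lowest track id, then input order), with a
    displacement cap of max_disp_nm and gap bridging up to max_gap_frames
    missed frames.  Each spot joins at most one trajectory; trajectories
    shorter than 2 points are discarded.  The procedure is deterministic.
    """
    df = locs
    if "converged" in df.columns:
        df = df[df["converged"].astype(bool)]
    if channel is None and "channel" in df.columns:
        chans = df["channel"].unique()
        if len(chans) > 1:
            raise ValueError("multiple channels present; pass channel=...")
        channel = int(chans[0]) if len(chans) else 1
    elif channel is not None and "channel" in df.columns:
        df = df[df["channel"] == channel]
    if channel is None:
        channel = 1
    df = df.sort_values("frame")

    active: list[dict] = []   # open tracks
    done: list[dict] = []
    next_id = 0
    for f, group in df.groupby("frame", sort=True):
        pts = group[["x_nm", "y_nm"]].to_numpy(dtype=float)
        # retire tracks whose gap can no longer be closed
        still = []
        for tr in active:
            if f - tr["frames"][-1] > max_gap_frames + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        # candidate links, smallest distance first then lowest track id
        cands = []
        for ti, tr in enumerate(active):
            d = np.hypot(*(pts - tr["xy"][-1]).T)
            for pi in np.flatnonzero(d <= max_disp_nm):
                cands.append((float(d[pi]), tr["id"], ti, int(pi)))
        cands.sort()
        used_tracks: set[int] = set()
        used_pts: set[int] = set()
        for _, _, ti, pi in cands:
            if ti in used_tracks or pi in used_pts:
                continue
            active[ti]["frames"].append(int(f))
            active[ti]["xy"].append(pts[pi])
            used_tracks.add(ti)
            used_pts.add(pi)
        for pi in range(len(pts)):
            if pi not in used_pts:
                active.append(dict(id=next_id, frames=[int(f)], xy=[pts[pi]]))
                next_id += 1
    done.extend(active)
    out = [
        Trajectory(locus_id=tr["id"], frames=np.array(tr["frames"]),
                   xy_nm=np.array(tr["xy"]),
                   frame_interval_s=frame_interval_s, channel=channel)
        for tr in sorted(done, key=lambda t: t["id"])
        if len(tr["frames"]) >= 2
    ]
    return out


def trajectory_from_truth(truth: pd.DataFrame, locus_id: int, channel: int,
                          frame_interval_s: float) -> Trajectory:
    """Build a Trajectory from a simulator ground-truth table (nm columns)."""
    sub = truth[(truth["locus_id"] == locus_id) & (truth["channel"] == channel)]
    sub = sub.sort_values("frame")
    return Trajectory(locus_id=locus_id, frames=sub["frame"].to_numpy(),
                      xy_nm=sub[["x_nm", "y_nm"]].to_numpy(dtype=float),
                      frame_interval_s=frame_interval_s, channel=channel)


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

@dataclass
class MSDCurve:
    """Lag-indexed time-averaged MSD, raw and localization-error-corrected."""

    lags_s: np.ndarray
    msd_raw_nm2: np.ndarray
    counts: np.ndarray
    msd_loc_error_nm2: float = 0.0
    loc_error_source: str = "none"

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_raw_nm2 = np.asarray(self.msd_raw_nm2, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.lags_s <= 0) or np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be positive and strictly increasing")

    @property
    def msd_corrected_nm2(self) -> np.ndarray:
        return self.msd_raw_nm2 - self.msd_loc_error_nm2

    def with_correction(self, msd_loc_error_nm2: float,
                        source: str = "dual-tag") -> "MSDCurve":
        return replace(self, msd_loc_error_nm2=float(msd_loc_error_nm2),
                       loc_error_source=source)


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.5) -> MSDCurve:
    """Time-averaged 2D MSD over all ordered frame pairs at each lag.

    MSD(k * dt) = mean over t of |r(t + k dt) - r(t)|^2, gaps excluded
    pairwise; lags run from 1 frame up to max_lag_fraction of the
    trajectory's frame span.  Trajectories shorter than 4 points are
    rejected (too few pairs for a meaningful time average).
    """
    if len(traj) < 4:
        raise ValueError("trajectory too short for MSD (need >= 4 points)")
    if not (0 < max_lag_fraction <= 1):
        raise ValueError("max_lag_fraction must be in (0, 1]")
    dense = traj.dense_positions()
    span = dense.shape[0] - 1
    max_lag = max(1, int(np.floor(max_lag_fraction * span)))
    lags, msd, counts = [], [], []
    for k in range(1, max_lag + 1):
        disp = dense[k:] - dense[:-k]
        sq = np.sum(disp ** 2, axis=1)
        good = np.isfinite(sq)
        if not np.any(good):
            continue
        lags.append(k * traj.frame_interval_s)
        msd.append(float(np.mean(sq[good])))
        counts.append(int(np.sum(good)))
    return MSDCurve(lags_s=np.array(lags), msd_raw_nm2=np.array(msd),
                    counts=np.array(counts))


def ensemble_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Unweighted across-locus average of per-trajectory MSD curves.

    Averaged on the intersection-free union of lags: each lag uses the
    curves that reach it, with equal locus weights (the averaging scheme
    used for the ensemble exponent).
    """
    if not curves:
        raise ValueError("no curves")
    all_lags = np.unique(np.concatenate([c.lags_s for c in curves]))
    msd = np.full(all_lags.size, np.nan)
    counts = np.zeros(all_lags.size, dtype=int)
    for i, lag in enumerate(all_lags):
        vals = []
        for c in curves:
            j = np.flatnonzero(np.isclose(c.lags_s, lag))
            if j.size:
                vals.append(c.msd_raw_nm2[j[0]])
        msd[i] = np.mean(vals)
        counts[i] = len(vals)
    corr = curves[0].msd_loc_error_nm2
    if any(not np.isclose(c.msd_loc_error_nm2, corr) for c in curves):
        logger.warning("ensemble_msd: mixed loc-error constants; using first")
    return MSDCurve(lags_s=all_lags, msd_raw_nm2=msd, counts=counts,
                    msd_loc_error_nm2=corr,
                    loc_error_source=curves[0].loc_error_source)


def estimate_msd_loc_error(
    traj_ch1: Trajectory,
    traj_ch2: Trajectory,
    lag_window_frames: tuple[int, int] = (1, 10),
) -> float:
    """Per-channel MSD localization-error constant from a dual-tag control.

    The same locus imaged in two registered colors moves identically, so
    the difference coordinate r1(t) - r2(t) contains only localization
    noise of both channels: its MSD plateaus at 2 * (MSD_err_ch1 +
    MSD_err_ch2).  Assuming equal channel errors (documented; a one-sided
    noise budget biases the result by a factor of 2), half the plateau —
    averaged over the configured lag window — is returned as the constant
    to subtract from each channel's observed MSD.  For per-axis noise
    sigma in both channels the returned value is 4 * sigma**2 (nm^2).
    """
    common, i1, i2 = np.intersect1d(traj_ch1.frames, traj_ch2.frames,
                                    return_indices=True)
    if common.size < 10:
        raise ValueError(
            f"only {common.size} time-aligned frames; >= 10 required"
        )
    diff = Trajectory(
        locus_id=traj_ch1.locus_id,
        frames=common,
        xy_nm=traj_ch1.xy_nm[i1] - traj_ch2.xy_nm[i2],
        frame_interval_s=traj_ch1.frame_interval_s,
    )
    msd = compute_msd(diff, max_lag_fraction=1.0)
    lo, hi = lag_window_frames
    lag_frames = np.rint(msd.lags_s / diff.frame_interval_s).astype(int)
    sel = (lag_frames >= lo) & (lag_frames <= hi)
    if not np.any(sel):
        raise ValueError("lag window contains no usable lags")
    return float(np.mean(msd.msd_raw_nm2[sel]) / 2.0)


# ---------------------------------------------------------------------------
# Power-law fit
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    """MSD_2D(t) = d_app * t**alpha fitted on log-log axes."""

    d_app: float          # nm^2 / s^alpha
    alpha: float
    alpha_se: float
    log_d_se: float
    r_squared: float
    lag_range_s: tuple[float, float]
    n_lags: int


def fit_power_law(
    msd: MSDCurve,
    lag_range_s: tuple[float, float] = (0.33, 10.0),
    use_corrected: bool = True,
) -> PowerLawFit:
    """Ordinary least squares of log(MSD) on log(tau) over a lag range.

    Non-positive corrected MSD values (possible at small lags after
    subtracting the localization-error constant) are excluded and logged;
    at least 3 usable lags are required.
    """
    values = msd.msd_corrected_nm2 if use_corrected else msd.msd_raw_nm2
    lo, hi = lag_range_s
    sel = (msd.lags_s >= lo * (1 - 1e-9)) & (msd.lags_s <= hi * (1 + 1e-9))
    n_nonpos = int(np.sum(sel & (values <= 0)))
    if n_nonpos:
        logger.info("fit_power_law: %d non-positive MSD lags excluded",
                    n_nonpos)
    sel &= values > 0
    if np.sum(sel) < 3:
        raise ValueError(
            f"only {int(np.sum(sel))} usable lags in range {lag_range_s}; "
            "need >= 3"
        )
    x = np.log(msd.lags_s[sel])
    y = np.log(values[sel])
    res = stats.linregress(x, y)
    ss_res = np.sum((y - (res.intercept + res.slope * x)) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        d_app=float(np.exp(res.intercept)),
        alpha=float(res.slope),
        alpha_se=float(res.stderr),
        log_d_se=float(res.intercept_stderr),
        r_squared=float(r2),
        lag_range_s=(float(msd.lags_s[sel].min()), float(msd.lags_s[sel].max())),
        n_lags=int(np.sum(sel)),
    )


def ensemble_alpha(fits: list[PowerLawFit]) -> tuple[float, float]:
    """Mean anomalous exponent and its SE across loci (equal weights)."""
    if not fits:
        raise ValueError("no fits")
    a = np.array([f.alpha for f in fits])
    se = a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else 0.0
    return float(a.mean()), float(se)


# ---------------------------------------------------------------------------
# Velocity autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class VelocityACF:
    """delta-parameterized velocity autocorrelation of one ensemble/track."""

    delta_s: float
    lags_s: np.ndarray
    cv: np.ndarray            # nm^2 / s^2
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def cv_normalized(self) -> np.ndarray:
        if self.cv[0] <= 0:
            raise ValueError("C_v(0) must be positive to normalize")
        return self.cv / self.cv[0]

    @property
    def tau_over_delta(self) -> np.ndarray:
        return self.lags_s / self.delta_s


def velocity_acf(traj: Trajectory, delta_frames: int,
                 max_lag_frames: int | None = None) -> VelocityACF:
    """Autocorrelation of finite-difference velocities of one trajectory.

    v(t) = (r(t + delta) - r(t)) / delta; C_v(tau) is the time average of
    the 2D dot product v(t + tau) . v(t) over all valid t (gaps excluded
    pairwise).  Lags run from 0 to max_lag_frames (default: half the
    number of velocity samples).
    """
    if delta_frames < 1:
        raise ValueError("delta_frames must be >= 1")
    if len(traj) < 3 * delta_frames:
        raise ValueError("trajectory length must be >= 3 * delta_frames")
    dt = traj.frame_interval_s
    dense = traj.dense_positions()
    delta_s = delta_frames * dt
    v = (dense[delta_frames:] - dense[:-delta_frames]) / delta_s  # (n, 2)
    n = v.shape[0]
    if max_lag_frames is None:
        max_lag_frames = n // 2
    lags, cv, counts = [], [], []
    for k in range(0, max_lag_frames + 1):
        if k >= n:
            break
        dots = np.sum(v[k:] * v[:n - k], axis=1)
        good = np.isfinite(dots)
        if not np.any(good):
            continue
        lags.append(k * dt)
        cv.append(float(np.mean(dots[good])))
        counts.append(int(np.sum(good)))
    return VelocityACF(delta_s=delta_s, lags_s=np.array(lags),
                       cv=np.array(cv), counts=np.array(counts))


def ensemble_velocity_acf(trajs: list[Trajectory], delta_frames: int,
                          max_lag_frames: int | None = None) -> VelocityACF:
    """Equal-weight across-locus average of per-trajectory velocity ACFs.

    Averaged raw, then normalized by the ensemble's own C_v(0) (via the
    cv_normalized property), matching the per-ensemble normalization used
    for collapse plots.
    """
    acfs = [velocity_acf(t, delta_frames, max_lag_frames) for t in trajs]
    n_lags = min(a.lags_s.size for a in acfs)
    lags = acfs[0].lags_s[:n_lags]
    cv = np.mean([a.cv[:n_lags] for a in acfs], axis=0)
    counts = np.sum([a.counts[:n_lags] for a in acfs], axis=0)
    return VelocityACF(delta_s=acfs[0].delta_s, lags_s=lags, cv=cv,
                       counts=counts)


def fbm_normalized_acf(alpha: float, tau_over_delta) -> np.ndarray:
    """Closed-form normalized velocity ACF of fBm on the rescaled axis.

    C_v(tau)/C_v(0) = (|u+1|^a - 2|u|^a + |u-1|^a) / 2 with u = tau/delta;
    at u = 1 this is 2**(alpha - 1) - 1, the depth of the negative dip.
    """
    u = np.asarray(tau_over_delta, dtype=float)
    return increment_autocovariance(alpha, u, step_var=1.0)
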