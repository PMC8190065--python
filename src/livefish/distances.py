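"""Two-color locus-pair distances after registration.

Once the moving-channel localizations have been warped into the reference
frame, apparent locus pairs are formed per frame by mutual nearest
neighbor and their separation vectors summarized.  For truly coincident
loci the measured 2D distance follows a Rayleigh distribution whose scale
is set by the per-axis localization errors of the two colors plus the
registration error, so the mean distance of a dual-tag control directly
reports the combined measurement precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["frame", "pair_id", "id_ch1", "id_ch2",
                "dx_nm", "dy_nm", "d2d_nm"]


def pair_loci(locs_ch1: pd.DataFrame, locs_ch2_warped: pd.DataFrame,
              max_pair_nm: float = 1500.0) -> pd.DataFrame:
    """Pair localizations across channels, frame by frame.

    Both tables must be in the common reference frame (channel 2 already
    warped) with columns (frame, x_nm, y_nm) and optionally an id column
    ("locus_id" or index).  Pairs are mutual nearest neighbors with
    separation <= max_pair_nm; unpaired spots are counted and logged.

    Returns the PAIR_COLUMNS table, dx/dy being channel-2 minus channel-1
    components in nm.
    """
    def ids(df):
        if "locus_id" in df.columns:
            return df["locus_id"].to_numpy()
        return df.index.to_numpy()

    rows = []
    n_unpaired = 0
    frames = sorted(set(locs_ch1["frame"]).union(set(locs_ch2_warped["frame"])))
    pair_id = 0
    for f in frames:
        a = locs_ch1[locs_ch1["frame"] == f]
        b = locs_ch2_warped[locs_ch2_warped["frame"] == f]
        if len(a) == 0 or len(b) == 0:
            n_unpaired += len(a) + len(b)
            continue
        pa = a[["x_nm", "y_nm"]].to_numpy(dtype=float)
        pb = b[["x_nm", "y_nm"]].to_numpy(dtype=float)
        ta, tb = cKDTree(pa), cKDTree(pb)
        d_ab, j_ab = tb.query(pa)
        _, j_ba = ta.query(pb)
        matched_b = set()
        for i, (d, j) in enumerate(zip(d_ab, j_ab)):
            if d <= max_pair_nm and j_ba[j] == i:
                dx = pb[j, 0] - pa[i, 0]
                dy = pb[j, 1] - pa[i, 1]
                rows.append(dict(frame=f, pair_id=pair_id,
                                 id_ch1=ids(a)[i], id_ch2=ids(b)[j],
                                 dx_nm=dx, dy_nm=dy,
                                 d2d_nm=float(np.hypot(dx, dy))))
                matched_b.add(j)
                pair_id += 1
        n_unpaired += (len(a) + len(b) - 2 * len(matched_b))
    if n_unpaired:
        logger.info("pair_loci: %d spots left unpaired", n_unpaired)
    if len(locs_ch1) == 0 or len(locs_ch2_warped) == 0:
        logger.warning("pair_loci: one channel is empty; no pairs formed")
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


@dataclass
class DistanceSummary:
    """Pooled statistics of 2D pair distances (mean ± SD, fractions, histogram)."""

    n: int
    n_loci: int
    mean_nm: float
    sd_nm: float
    median_nm: float
    fraction_within: dict[float, float]
    hist_edges_nm: np.ndarray
    hist_counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_loci": self.n_loci,
            "mean_nm": self.mean_nm,
            "sd_nm": self.sd_nm,
            "median_nm": self.median_nm,
            "fraction_within": {str(k): v for k, v in self.fraction_within.items()},
            "hist_edges_nm": self.hist_edges_nm.tolist(),
            "hist_counts": self.hist_counts.tolist(),
        }


def summarize_distances(
    pairs: pd.DataFrame,
    thresholds_nm=(200.0, 300.0),
    bin_edges_nm: np.ndarray | None = None,
) -> DistanceSummary:
    """Pooled mean/SD/median, threshold fractions and histogram of d2d_nm.

    Measurements are pooled over frames and loci; per-locus statistics can
    be obtained by grouping the pairs table on id columns first.  The
    histogram defaults to 50-nm bins from 0 to 1200 nm (distances beyond
    the last edge are clipped into the final bin so counts always sum to n).
    Empty input is an error rather than a silent NaN summary.
    """
    if len(pairs) == 0:
        raise ValueError("no distance pairs to summarize")
    d = pairs["d2d_nm"].to_numpy(dtype=float)
    if bin_edges_nm is None:
        bin_edges_nm = np.arange(0.0, 1250.0, 50.0)
    bin_edges_nm = np.asarray(bin_edges_nm, dtype=float)
    counts, _ = np.histogram(np.clip(d, bin_edges_nm[0], bin_edges_nm[-1] - 1e-9),
                             bins=bin_edges_nm)
    id_cols = [c for c in ("id_ch1", "id_ch2") if c in pairs.columns]
    if id_cols:
        n_loci = len(pairs[id_cols].drop_duplicates())
    else:
        n_loci = len(pairs)
    return DistanceSummary(
        n=int(d.size),
        n_loci=int(n_loci),
        mean_nm=float(d.mean()),
        sd_nm=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        median_nm=float(np.median(d)),
        fraction_within={float(t): float(np.mean(d <= t)) for t in thresholds_nm},
        hist_edges_nm=bin_edges_nm,
        hist_counts=counts,
    )


def rayleigh_mean_2d(sigma_axis_nm: float) -> float:
    """Expected 2D distance for coincident loci with isotropic per-axis error.

    If the effective per-axis error of the separation vector is sigma
    (localization of both colors plus registration, in quadrature), the 2D
    distance is Rayleigh(sigma) with mean sigma * sqrt(pi / 2).
    """
    if sigma_axis_nm < 0:
        raise ValueError("sigma must be >= 0")
    return float(sigma_axis_nm * np.sqrt(np.pi / 2.0))
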