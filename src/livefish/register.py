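"""Two-color chromatic registration via a second-order polynomial warp.

A multicolor fiducial-bead field imaged in both channels calibrates the
coordinate mapping between them.  The map is a quadratic polynomial per
output axis, fitted by linear least squares on coordinates pre-centered and
scaled to [-1, 1] (raw second-order monomials on a 512-px field are badly
conditioned).  Quality control reports in-sample residual r.m.s. per axis
and in 2D (quadrature), plus the leave-one-out cross-validated r.m.s.,
which is the honest estimate of registration accuracy on new points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .warp import MONOMIALS, QuadraticWarp, design_matrix


def rms_2d(rms_x_nm: float, rms_y_nm: float) -> float:
    """2D r.m.s. from per-axis r.m.s. values, combined in quadrature."""
    if rms_x_nm < 0 or rms_y_nm < 0:
        raise ValueError("r.m.s. values must be >= 0")
    return float(np.hypot(rms_x_nm, rms_y_nm))


@dataclass
class MatchedPairs:
    """Corresponding fiducial coordinates in the two channels."""

    ref_xy: np.ndarray  # (N, 2)
    mov_xy: np.ndarray  # (N, 2)
    ref_idx: np.ndarray | None = None
    mov_idx: np.ndarray | None = None
    units: str = "px"

    def __post_init__(self) -> None:
        self.ref_xy = np.atleast_2d(np.asarray(self.ref_xy, dtype=float))
        self.mov_xy = np.atleast_2d(np.asarray(self.mov_xy, dtype=float))
        if self.ref_xy.shape != self.mov_xy.shape:
            raise ValueError("ref and mov point sets must match in shape")

    def __len__(self) -> int:
        return self.ref_xy.shape[0]


def _as_xy(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        for xcol, ycol in (("x_px", "y_px"), ("x_nm", "y_nm"), ("x", "y")):
            if xcol in points.columns and ycol in points.columns:
                return points[[xcol, ycol]].to_numpy(dtype=float)
        raise ValueError("DataFrame lacks recognizable x/y columns")
    return np.atleast_2d(np.asarray(points, dtype=float))


def match_fiducials(ref_points, mov_points, max_dist: float = 2.0,
                    units: str = "px", pre_align: bool = True) -> MatchedPairs:
    """Pair beads across channels by mutual nearest neighbor.

    The chromatic offset between channels can be a sizable fraction of the
    bead spacing, which makes naive nearest-neighbor matching cross-capture
    close bead pairs; with ``pre_align`` (default) the median displacement
    between the sets is removed before matching (the returned pair
    coordinates are the original, un-shifted ones).

    A pair is kept when each point is the other's nearest neighbor (after
    pre-alignment) and their separation is <= max_dist (same units as the
    coordinates).  The result is independent of input ordering.  Fewer than
    6 pairs cannot determine the 12 warp coefficients and raise ValueError.
    """
    ref = _as_xy(ref_points)
    mov = _as_xy(mov_points)
    if len(ref) == 0 or len(mov) == 0:
        raise ValueError("both point sets must be non-empty")
    mov_work = mov
    if pre_align:
        _, j0 = cKDTree(mov).query(ref)
        shift = np.median(mov[j0] - ref, axis=0)  # robust coarse translation
        mov_work = mov - shift
    tree_ref = cKDTree(ref)
    tree_mov = cKDTree(mov_work)
    d_rm, j_rm = tree_mov.query(ref)   # for each ref point its nearest mov
    _, j_mr = tree_ref.query(mov_work)  # for each mov point its nearest ref
    keep = []
    for i, (d, j) in enumerate(zip(d_rm, j_rm)):
        if d <= max_dist and j_mr[j] == i:
            keep.append((i, j))
    keep.sort()
    if len(keep) < 6:
        raise ValueError(
            f"only {len(keep)} mutual-nearest-neighbor pairs within "
            f"{max_dist} {units}; >= 6 required for a quadratic warp"
        )
    ri = np.array([i for i, _ in keep])
    mi = np.array([j for _, j in keep])
    return MatchedPairs(ref_xy=ref[ri], mov_xy=mov[mi],
                        ref_idx=ri, mov_idx=mi, units=units)


@dataclass
class RegistrationQC:
    """Residual statistics of a fitted warp (same units as the fit)."""

    n_fiducials: int
    rms_x: float
    rms_y: float
    rms_2d: float
    loo_rms_x: float
    loo_rms_y: float
    loo_rms_2d: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class WarpModel2:
    """Fitted quadratic map src -> dst with its coordinate normalization.

    The polynomial acts on u = (x - center) / scale; ``coeffs`` is (2, 6)
    in that normalized basis.  ``as_raw_warp()`` expands the affine
    substitution exactly, yielding raw-monomial coefficients comparable to
    a simulated ground-truth warp.
    """

    coeffs: np.ndarray
    center: np.ndarray   # (2,)
    scale: np.ndarray    # (2,)
    units: str = "px"
    src_label: str = "moving"
    dst_label: str = "reference"

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.coeffs.shape != (2, 6):
            raise ValueError("coeffs must be (2, 6)")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")

    def _normalize(self, xy: np.ndarray) -> np.ndarray:
        return (xy - self.center) / self.scale

    def transform(self, points, units: str | None = None) -> np.ndarray:
        """Map points from the source channel into the destination frame."""
        if units is not None and units != self.units:
            raise ValueError(f"model fitted in {self.units!r}, points given "
                             f"in {units!r}")
        xy = _as_xy(points)
        return design_matrix(self._normalize(xy)) @ self.coeffs.T

    __call__ = transform

    def as_raw_warp(self) -> QuadraticWarp:
        """Exact raw-monomial equivalent of the normalized-basis polynomial."""
        cx, cy = self.center
        sx, sy = self.scale
        # rows: normalized monomials expressed in the raw basis
        m = np.array([
            [1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [-cx / sx, 1.0 / sx, 0.0, 0.0, 0.0, 0.0],
            [-cy / sy, 0.0, 1.0 / sy, 0.0, 0.0, 0.0],
            [cx * cx / sx ** 2, -2.0 * cx / sx ** 2, 0.0, 1.0 / sx ** 2, 0.0, 0.0],
            [cx * cy / (sx * sy), -cy / (sx * sy), -cx / (sx * sy), 0.0,
             1.0 / (sx * sy), 0.0],
            [cy * cy / sy ** 2, 0.0, -2.0 * cy / sy ** 2, 0.0, 0.0, 1.0 / sy ** 2],
        ])
        return QuadraticWarp(self.coeffs @ m, units=self.units)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "monomials": list(MONOMIALS),
            "coeffs_x": self.coeffs[0].tolist(),
            "coeffs_y": self.coeffs[1].tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "units": self.units,
            "src_label": self.src_label,
            "dst_label": self.dst_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WarpModel2":
        return cls(coeffs=np.array([d["coeffs_x"], d["coeffs_y"]]),
                   center=np.array(d["center"]), scale=np.array(d["scale"]),
                   units=d.get("units", "px"),
                   src_label=d.get("src_label", "moving"),
                   dst_label=d.get("dst_label", "reference"))

    def to_json(self, path, qc: "RegistrationQC | None" = None) -> None:
        d = self.to_dict()
        if qc is not None:
            d["qc"] = qc.to_dict()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "WarpModel2":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_warp(pairs_or_src, dst=None, order: int = 2, units: str = "px",
             src_label: str = "moving", dst_label: str = "reference",
             ) -> tuple[WarpModel2, RegistrationQC]:
    """Fit the quadratic map dst = P(src) by least squares, per output axis.

    Call either with a MatchedPairs (fits mov -> ref, the analysis
    direction) or with explicit (src, dst) point arrays.  Coordinates are
    centered and scaled to [-1, 1] before fitting; the normalization is
    stored on the model, so transformed outputs and the exported raw
    coefficients are unaffected by it.

    QC residuals are in the units of the input coordinates.  The
    leave-one-out r.m.s. uses the hat-matrix identity e_loo = e / (1 - h),
    so no refitting loop is needed.
    """
    if order != 2:
        raise ValueError("only order=2 warps are supported")
    if dst is None:
        pairs: MatchedPairs = pairs_or_src
        src_xy, dst_xy = pairs.mov_xy, pairs.ref_xy
        units = pairs.units
    else:
        src_xy, dst_xy = _as_xy(pairs_or_src), _as_xy(dst)
    n = src_xy.shape[0]
    if n < 6:
        raise ValueError("at least 6 pairs required")

    center = src_xy.mean(axis=0)
    half_range = np.abs(src_xy - center).max(axis=0)
    scale = np.where(half_range > 0, half_range, 1.0)
    u = (src_xy - center) / scale
    X = design_matrix(u)
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError(
            "degenerate fiducial geometry: design matrix is rank-deficient "
            "(beads collinear or coincident); spread beads over the field"
        )
    coeffs, *_ = np.linalg.lstsq(X, dst_xy, rcond=None)
    model = WarpModel2(coeffs=coeffs.T, center=center, scale=scale,
                       units=units, src_label=src_label, dst_label=dst_label)

    resid = dst_xy - X @ coeffs                     # (N, 2)
    # hat diagonal h_i = x_i (X^T X)^{-1} x_i^T
    h = np.einsum("ij,ij->i", X, np.linalg.solve(X.T @ X, X.T).T)
    h = np.clip(h, 0.0, 1.0 - 1e-12)
    resid_loo = resid / (1.0 - h)[:, None]
    rx, ry = np.sqrt(np.mean(resid ** 2, axis=0))
    lx, ly = np.sqrt(np.mean(resid_loo ** 2, axis=0))
    qc = RegistrationQC(
        n_fiducials=n,
        rms_x=float(rx), rms_y=float(ry), rms_2d=rms_2d(rx, ry),
        loo_rms_x=float(lx), loo_rms_y=float(ly), loo_rms_2d=rms_2d(lx, ly),
    )
    return model, qc


def apply_warp(model: WarpModel2, points, units: str | None = None) -> np.ndarray:
    """Evaluate the fitted polynomial on new points (thin wrapper)."""
    return model.transform(points, units=units)
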