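"""Second-order 2D polynomial coordinate maps.

A quadratic warp sends a point (x, y) to

    x' = c0 + c1*x + c2*y + c3*x^2 + c4*x*y + c5*y^2
    y' = d0 + d1*x + d2*y + d3*x^2 + d4*x*y + d5*y^2

which is the standard model for chromatic distortion between two color
channels of one microscope at the nanometer scale.  The 12 coefficients are
stored as a (2, 6) array in the monomial order (1, x, y, x^2, xy, y^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: monomial basis order used throughout the package
MONOMIALS = ("1", "x", "y", "x^2", "xy", "y^2")


def design_matrix(xy: np.ndarray) -> np.ndarray:
    """Quadratic design matrix, one row per point, columns in MONOMIALS order."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (N, 2) array of points")
    x, y = xy[:, 0], xy[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


@dataclass
class QuadraticWarp:
    """A raw-coefficient quadratic map; used as simulation ground truth.

    Parameters
    ----------
    coeffs : (2, 6) array
        Row 0 produces x', row 1 produces y', in MONOMIALS order.
    units : str
        Unit of the coordinates the map acts on ("px" or "nm").
    """

    coeffs: np.ndarray
    units: str = "px"

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (2, 6):
            raise ValueError("coeffs must have shape (2, 6)")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("warp coefficients must be finite")

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        return design_matrix(xy) @ self.coeffs.T

    @classmethod
    def identity(cls, units: str = "px") -> "QuadraticWarp":
        c = np.zeros((2, 6))
        c[0, 1] = 1.0  # x' = x
        c[1, 2] = 1.0  # y' = y
        return cls(c, units=units)

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        shift: float = 1.0,
        linear_dev: float = 1e-3,
        quad: float = 1e-6,
        units: str = "px",
    ) -> "QuadraticWarp":
        """Draw a realistic chromatic distortion.

        Defaults (in px units) give ~1 px translation, ~0.1% scale/shear and
        a quadratic term contributing well under a pixel across a 512-px
        field — the magnitude regime of real two-camera/quad-view optics.
        """
        c = cls.identity(units=units).coeffs.copy()
        c[:, 0] += rng.uniform(-shift, shift, size=2)
        c[:, 1:3] += rng.uniform(-linear_dev, linear_dev, size=(2, 2))
        c[:, 3:6] += rng.uniform(-quad, quad, size=(2, 3))
        return cls(c, units=units)

    def is_identity(self, atol: float = 0.0) -> bool:
        return np.allclose(self.coeffs, QuadraticWarp.identity().coeffs, atol=atol)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "monomials": list(MONOMIALS),
            "coeffs_x": self.coeffs[0].tolist(),
            "coeffs_y": self.coeffs[1].tolist(),
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticWarp":
        return cls(np.array([d["coeffs_x"], d["coeffs_y"]]), units=d.get("units", "px"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QuadraticWarp":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
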