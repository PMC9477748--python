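"""Chromatic channel registration.

Dual-view image splitters project the two spectral channels through slightly
different optical paths, leaving a chromatic offset (translation, small scale
and shear) between the channel-A and channel-B coordinate systems.  Before any
two-colour co-localization the channel-B localizations must be mapped into the
channel-A frame using a transform calibrated on fiducial markers imaged in
both channels.

The transform family is a full 6-parameter 2D affine map, estimated by linear
least squares.  The convention throughout the package is B→A: the estimated
transform is applied to channel-B coordinates, never to channel A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IdentifiabilityError

__all__ = ["AffineTransform2D", "estimate_affine", "apply_affine"]

_MIN_DET = 1e-6


@dataclass(frozen=True)
class AffineTransform2D:
    """A 2D affine map ``y = M x + t`` with coordinates in nm.

    Attributes
    ----------
    matrix : (2, 2) array — linear part (rotation/scale/shear).
    offset : (2,) array — translation in nm.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        t = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(m)) <= _MIN_DET:
            raise IdentifiabilityError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "offset", t)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls()

    @classmethod
    def translation(cls, dx: float, dy: float) -> "AffineTransform2D":
        return cls(np.eye(2), np.array([dx, dy], dtype=float))

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of points."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform2D":
        minv = np.linalg.inv(self.matrix)
        return AffineTransform2D(minv, -minv @ self.offset)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return the transform applying ``other`` first, then ``self``."""
        return AffineTransform2D(
            self.matrix @ other.matrix, self.matrix @ other.offset + self.offset
        )

    # -- serialization (6 numbers, row-major linear part then offset) -------
    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "offset": self.offset.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(np.asarray(d["matrix"], float), np.asarray(d["offset"], float))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform2D":
        return cls.from_dict(json.loads(Path(path).read_text()))


def estimate_affine(
    points_a: np.ndarray, points_b: np.ndarray
) -> tuple[AffineTransform2D, float]:
    """Estimate the B→A affine transform from paired fiducial localizations.

    Solves the linear least-squares problem min Σ‖T(b_i) − a_i‖² for the six
    affine parameters.

    Parameters
    ----------
    points_a, points_b : (n, 2) arrays of paired positions in nm
        (channel A and channel B respectively), n ≥ 3 and non-collinear.

    Returns
    -------
    (transform, residual_rms_nm)

    Raises
    ------
    IdentifiabilityError
        Fewer than 3 pairs, mismatched lengths, or a collinear marker
        configuration (the affine map is then not identifiable).
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise IdentifiabilityError("paired point sets must both be (n, 2)")
    n = a.shape[0]
    if n < 3:
        raise IdentifiabilityError(f"need >= 3 fiducial pairs, got {n}")
    centered = b - b.mean(axis=0)
    # rank < 2 <=> markers collinear (or coincident)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(b).max())) < 2:
        raise IdentifiabilityError("fiducial markers are collinear")
    design = np.column_stack([b, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, a, rcond=None)
    transform = AffineTransform2D(coef[:2].T, coef[2])
    residuals = transform.apply(b) - a
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return transform, rms


def apply_affine(table: pd.DataFrame, transform: AffineTransform2D) -> pd.DataFrame:
    """Map the ``x_nm``/``y_nm`` columns of a localization table.

    All other columns are left untouched; a new DataFrame is returned.
    """
    out = table.copy()
    if len(out):
        xy = transform.apply(out[["x_nm", "y_nm"]].to_numpy(dtype=float))
        out["x_nm"] = xy[:, 0]
        out["y_nm"] = xy[:, 1]
    return out
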