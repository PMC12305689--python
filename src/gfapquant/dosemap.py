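"""Dose-grid registration and resampling into slice coordinates.

A planning-grid dose distribution is mapped into the pixel grid of a
histological slice with a 6-parameter affine transform (a deliberate,
fully testable simplification of contour-based slice-to-volume
registration) and resampled bilinearly.  Positions outside the source grid
receive 0 Gy, which matches treating the unirradiated far field as sham.

Coordinates are (row, col), 0-based, with pixel/cell centers at integer
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "DoseGrid",
    "AffineTransform2D",
    "fit_affine_from_landmarks",
    "resample_dose",
    "isodose_region",
]


@dataclass
class DoseGrid:
    """A 2-D absorbed-dose raster on a regular grid.

    Parameters
    ----------
    values : ndarray
        Dose in Gy, non-negative, shape (rows, cols).
    spacing_um : float
        Grid cell spacing in um (isotropic).
    beam_direction : tuple of float
        Unit 2-vector (row, col) of beam travel in grid coordinates.
    prescription_dose : float
        Prescribed dose in Gy; ``max(values)`` may not exceed it by more
        than 5% (tolerance for penumbra/interpolation effects).
    """

    values: np.ndarray
    spacing_um: float
    beam_direction: tuple[float, float] = (0.0, -1.0)
    prescription_dose: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("DoseGrid.values must be 2-D")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if self.values.size and float(self.values.min()) < 0:
            raise ValueError("dose values must be non-negative")
        if float(np.max(self.values, initial=0.0)) > self.prescription_dose * 1.05:
            raise ValueError("max dose exceeds prescription_dose by more than 5%")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class AffineTransform2D:
    """A 2x3 affine map from source (row, col) to target (row, col) coordinates."""

    matrix: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("matrix must have shape (2, 3)")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("linear part of affine transform is singular")
        object.__setattr__(self, "matrix", m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (row, col) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform2D":
        a = self.matrix[:, :2]
        t = self.matrix[:, 2]
        a_inv = np.linalg.inv(a)
        return AffineTransform2D(np.column_stack([a_inv, -a_inv @ t]))


def fit_affine_from_landmarks(
    src_points: np.ndarray,
    dst_points: np.ndarray,
) -> tuple[AffineTransform2D, np.ndarray]:
    """Least-squares affine transform from matched landmark pairs.

    Solves the two independent 3-unknown linear systems minimizing the sum
    of squared residuals ``|T(src) - dst|^2``.  Requires at least three
    non-collinear source points.

    Returns
    -------
    transform : AffineTransform2D
    residuals : ndarray, shape (N,)
        Euclidean residual per landmark pair under the fitted transform.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (N, 2) arrays")
    if src.shape[0] < 3:
        raise ValueError("at least 3 landmark pairs are required")
    design = np.column_stack([src, np.ones(src.shape[0])])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear; affine transform is underdetermined")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    transform = AffineTransform2D(coef.T)
    residuals = np.linalg.norm(transform.apply(src) - dst, axis=1)
    return transform, residuals


def resample_dose(
    dose: DoseGrid,
    transform: AffineTransform2D,
    target_shape: tuple[int, int],
) -> np.ndarray:
    """Resample a dose grid into slice pixel coordinates.

    ``transform`` maps dose-grid indices to slice pixel indices.  Each
    target pixel is pulled back through the inverse transform and the dose
    is interpolated bilinearly; positions outside the source grid get 0 Gy.

    Returns a float32 raster in Gy of the requested shape.
    """
    inv = transform.inverse()
    rows, cols = np.meshgrid(
        np.arange(target_shape[0], dtype=float),
        np.arange(target_shape[1], dtype=float),
        indexing="ij",
    )
    pts = np.column_stack([rows.ravel(), cols.ravel()])
    src = inv.apply(pts)
    out = ndi.map_coordinates(
        dose.values.astype(np.float64),
        [src[:, 0], src[:, 1]],
        order=1,
        mode="constant",
        cval=0.0,
    )
    return out.reshape(target_shape).astype(np.float32)


def isodose_region(dose: np.ndarray, level: float) -> np.ndarray:
    """Mask of pixels at or above ``level`` times the maximum dose.

    ``level`` must lie strictly between 0 and 1.  An all-zero dose field
    yields an empty mask (not an error).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    values = np.asarray(dose)
    peak = float(values.max(initial=0.0))
    if peak == 0.0:
        return np.zeros(values.shape, dtype=bool)
    return values >= level * peak
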