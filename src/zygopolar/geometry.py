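"""Cell-axis geometry: projection, ellipse fitting, and orientation.

The apical–basal axis of a zygote is defined as the major axis of the
moment-equivalent ellipse of its binary mask, computed on the maximum
intensity Z-projection (MIP).  The image is then rotated about the mask
centroid so that this axis is vertical with the apex (from an explicit
per-movie annotation) pointing up, and the background is zeroed.

Angle convention: ``theta`` is in degrees, in [0, 180), measured
counter-clockwise from the column (horizontal) axis on the displayed
image (row index increases downward).  A vertical major axis is 90°.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateAxisError, EmptyMaskError

__all__ = [
    "FittedAxis",
    "OrientedCell",
    "max_intensity_projection",
    "fit_ellipse_axis",
    "rotate_and_mask",
]


def max_intensity_projection(stack_frame: np.ndarray) -> np.ndarray:
    """MIP along the first (z) axis of a (z, row, col) frame."""
    frame = np.asarray(stack_frame)
    if frame.ndim != 3 or frame.shape[0] < 1:
        raise ValueError(f"expected a (z, row, col) frame, got shape {frame.shape}")
    return frame.max(axis=0)


@dataclass(frozen=True)
class FittedAxis:
    """Moment-equivalent ellipse of a binary region.

    ``major_len``/``minor_len`` are full axis lengths in pixels
    (4·sqrt of the corresponding second-moment eigenvalue), so an
    axis-aligned solid rectangle of height h has major_len ≈ h·2/sqrt(3).
    """

    centroid: tuple[float, float]  # (row, col)
    theta: float  # degrees in [0, 180), from the column axis, CCW on screen
    major_len: float
    minor_len: float
    degenerate: bool


def fit_ellipse_axis(mask: np.ndarray, *, eps: float = 0.05) -> FittedAxis:
    """Fit the moment-equivalent ellipse of a boolean mask.

    The orientation comes from the second-order central moments:
    ``theta = 0.5*atan2(2*mu11, mu20 - mu02)`` in the (col, up) frame,
    folded into [0, 180).  ``degenerate`` is set when the axis ratio is
    below ``1 + eps`` (near-isotropic region, orientation unreliable).
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("cannot fit an axis to an empty mask")
    r0, c0 = rows.mean(), cols.mean()
    dr, dc = rows - r0, cols - c0
    # math frame: x = col, y = -row (up positive)
    mu20 = np.mean(dc * dc)
    mu02 = np.mean(dr * dr)
    mu11 = np.mean(dc * -dr)
    theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    theta_deg = math.degrees(theta) % 180.0

    cov = np.array([[mu20, mu11], [mu11, mu02]])
    lam = np.linalg.eigvalsh(cov)  # ascending
    lam = np.clip(lam, 0.0, None)
    major = 4.0 * math.sqrt(lam[1])
    minor = 4.0 * math.sqrt(lam[0])
    if minor < 1.0:
        warnings.warn(
            "mask is (nearly) collinear; minor axis clamped to 1 px", stacklevel=2
        )
        minor = 1.0
    degenerate = major / minor < 1.0 + eps
    return FittedAxis(
        centroid=(float(r0), float(c0)),
        theta=float(theta_deg),
        major_len=float(major),
        minor_len=float(minor),
        degenerate=bool(degenerate),
    )


def _rotation_matrix_rc(phi_deg: float) -> np.ndarray:
    """Matrix acting on (row, col) for a CCW-on-screen rotation by phi."""
    phi = math.radians(phi_deg)
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s], [s, c]])


@dataclass
class OrientedCell:
    """A cell image rotated so its apical–basal axis is vertical, apex up.

    ``image`` is zero outside ``mask``; ``tip_row``/``base_row`` are the
    first and last rows containing mask pixels.  ``map_point`` carries the
    forward affine so annotations made on the input frame (e.g. a division
    plane) can be transferred into the oriented frame.
    """

    image: np.ndarray
    mask: np.ndarray
    tip_row: int
    base_row: int
    rotation_deg: float
    _matrix: np.ndarray
    _center_in: np.ndarray
    _center_out: np.ndarray

    def map_point(self, point_rc) -> tuple[float, float]:
        """Map an input-frame (row, col) point into the oriented frame."""
        p = np.asarray(point_rc, dtype=float)
        q = self._matrix @ (p - self._center_in) + self._center_out
        return (float(q[0]), float(q[1]))


def _rotated_canvas(shape, matrix):
    corners = np.array(
        [[0, 0], [0, shape[1] - 1], [shape[0] - 1, 0], [shape[0] - 1, shape[1] - 1]],
        dtype=float,
    )
    center_in = (np.array(shape, dtype=float) - 1.0) / 2.0
    rot = (matrix @ (corners - center_in).T).T
    lo = rot.min(axis=0)
    hi = rot.max(axis=0)
    out_shape = tuple(int(math.ceil(h - l)) + 1 for l, h in zip(lo, hi))
    center_out = -lo
    return center_in, center_out, out_shape


def rotate_and_mask(
    image: np.ndarray,
    mask: np.ndarray,
    axis: FittedAxis,
    apex_hint,
) -> OrientedCell:
    """Rotate image and mask so the major axis is vertical, apex upward.

    The rotation is by ``90° - theta`` (plus 180° when the mapped
    ``apex_hint`` would otherwise land below the centroid), about the image
    centre, on an expanded canvas containing the whole rotated frame.
    Intensity is resampled with bilinear interpolation using the mask as
    interpolation weights (normalized convolution), so edge pixels are not
    diluted by the zero background; the mask itself is resampled and
    re-binarized at 0.5 coverage.  Everything outside the rotated mask is 0.
    """
    if axis.degenerate:
        raise DegenerateAxisError(
            "cannot orient a degenerate (near-isotropic) cell; supply an "
            "explicit rotation angle instead"
        )
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")

    phi = 90.0 - axis.theta
    matrix = _rotation_matrix_rc(phi)
    center_in = (np.array(image.shape, dtype=float) - 1.0) / 2.0
    apex = np.asarray(apex_hint, dtype=float)
    cen = np.asarray(axis.centroid, dtype=float)
    apex_rot = matrix @ (apex - center_in)
    cen_rot = matrix @ (cen - center_in)
    if apex_rot[0] > cen_rot[0]:  # apex below centroid -> flip
        phi += 180.0
        matrix = _rotation_matrix_rc(phi)

    center_in, center_out, out_shape = _rotated_canvas(image.shape, matrix)
    # inverse map for ndimage: input = M^T (output - c_out) + c_in
    inv = matrix.T
    offset = center_in - inv @ center_out

    weights = mask.astype(float)
    img_w = ndimage.affine_transform(
        image * weights, inv, offset=offset, output_shape=out_shape, order=1
    )
    w_rot = ndimage.affine_transform(
        weights, inv, offset=offset, output_shape=out_shape, order=1
    )
    mask_rot = w_rot >= 0.5
    out = np.zeros(out_shape, dtype=float)
    np.divide(img_w, w_rot, out=out, where=mask_rot & (w_rot > 1e-9))

    row_any = np.nonzero(mask_rot.any(axis=1))[0]
    if row_any.size == 0:
        raise EmptyMaskError("rotated mask is empty")
    tip_row, base_row = int(row_any[0]), int(row_any[-1])
    if tip_row >= base_row:
        raise DegenerateAxisError("oriented cell spans fewer than 2 rows")
    return OrientedCell(
        image=out,
        mask=mask_rot,
        tip_row=tip_row,
        base_row=base_row,
        rotation_deg=phi,
        _matrix=matrix,
        _center_in=center_in,
        _center_out=np.asarray(center_out, dtype=float),
    )
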