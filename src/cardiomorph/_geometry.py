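"""Low-level polygon geometry used across the package.

All polygons are (n, 2) float arrays of vertices in µm, implicitly closed
(last vertex connects back to the first).  The working coordinate frame is
the image frame (x right, y down); angles shown to users are converted to
the mathematical y-up frame in exactly one place, :func:`axis_angle_y_up`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "signed_area",
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
    "ensure_positive_orientation",
    "polygon_second_moments",
    "principal_axis",
    "smooth_closed_polygon",
    "fold_axial_deg",
    "axis_angle_y_up",
    "rotate_points",
]


def _as_poly(poly) -> np.ndarray:
    p = np.asarray(poly, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise ValueError("polygon must be an (n>=3, 2) array of vertices")
    # drop an explicitly repeated closing vertex
    if np.allclose(p[0], p[-1]):
        p = p[:-1]
    if p.shape[0] < 3:
        raise ValueError("polygon degenerates to fewer than 3 distinct vertices")
    return p


def signed_area(poly) -> float:
    """Shoelace signed area (positive for the package's canonical orientation)."""
    p = _as_poly(poly)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_area(poly) -> float:
    return abs(signed_area(poly))


def polygon_perimeter(poly) -> float:
    p = _as_poly(poly)
    return float(np.sum(np.hypot(*(np.roll(p, -1, axis=0) - p).T)))


def polygon_centroid(poly) -> np.ndarray:
    """Area centroid of a simple polygon."""
    p = _as_poly(poly)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0.0:
        return p.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def ensure_positive_orientation(poly) -> np.ndarray:
    p = _as_poly(poly)
    return p if signed_area(p) > 0 else p[::-1].copy()


def polygon_second_moments(poly) -> np.ndarray:
    """Area-normalised second central moment (covariance) tensor of a polygon.

    Uses the exact Green's-theorem formulas for ``∫x² dA`` etc., so the result
    is independent of how densely the boundary happens to be sampled.
    Returns the 2×2 matrix ``[[cov_xx, cov_xy], [cov_xy, cov_yy]]``.
    """
    p = _as_poly(poly)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0.0:
        raise ValueError("degenerate polygon: zero area")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    ixx = np.sum(cross * (x * x + x * xn + xn * xn)) / 12.0
    iyy = np.sum(cross * (y * y + y * yn + yn * yn)) / 12.0
    ixy = np.sum(cross * (x * yn + 2 * x * y + 2 * xn * yn + xn * y)) / 24.0
    if a < 0:  # formulas assume positive orientation
        a, ixx, iyy, ixy = -a, -ixx, -iyy, -ixy
    cov_xx = ixx / a - cx * cx
    cov_yy = iyy / a - cy * cy
    cov_xy = ixy / a - cx * cy
    return np.array([[cov_xx, cov_xy], [cov_xy, cov_yy]])


def principal_axis(cov: np.ndarray, iso_tol: float = 1e-6):
    """Major-axis angle (radians, frame of ``cov``) and elongation.

    Elongation is ``1 - λ_min/λ_max``.  When the eigenvalue ratio exceeds
    ``1 - iso_tol`` the tensor is treated as isotropic and the axis is
    undefined (returned as ``nan``).
    """
    evals, evecs = np.linalg.eigh(cov)
    lo, hi = float(evals[0]), float(evals[1])
    if hi <= 0:
        return float("nan"), 0.0
    ratio = max(lo, 0.0) / hi
    elongation = 1.0 - ratio
    if ratio > 1.0 - iso_tol:
        return float("nan"), 0.0
    vx, vy = evecs[:, 1]
    return float(np.arctan2(vy, vx)), elongation


def smooth_closed_polygon(poly, window: int = 3, passes: int = 2) -> np.ndarray:
    """Cyclic moving-average smoothing of polygon vertices.

    Tames the staircase of pixel-edge boundaries before perimeter-sensitive
    measures (circularity, orientation).  ``window`` must be odd.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be odd and >= 1")
    p = _as_poly(poly).copy()
    if window == 1 or passes < 1:
        return p
    half = window // 2
    for _ in range(passes):
        acc = p.copy()
        for k in range(1, half + 1):
            acc += np.roll(p, k, axis=0) + np.roll(p, -k, axis=0)
        p = acc / window
    return p


def fold_axial_deg(angle_deg):
    """Fold an angle (degrees) onto the axial scale ``(-90, 90]``.

    Axes are directionless: θ and θ+180° are the same axis.  Values landing
    exactly on -90 are mapped to +90 so the interval is half-open.
    """
    a = np.mod(np.asarray(angle_deg, dtype=float), 180.0)
    a = np.where(a > 90.0, a - 180.0, a)
    a = np.where(a == -90.0, 90.0, a)
    if np.ndim(angle_deg) == 0:
        return float(a)
    return a


def axis_angle_y_up(angle_rad_y_down: float) -> float:
    """Convert an axial angle measured in the image frame (y down) to degrees
    in the mathematical frame (y up), folded to [0, 180)."""
    deg = -np.degrees(angle_rad_y_down)
    return float(np.mod(deg, 180.0))


def rotate_points(points, angle_rad: float, center=(0.0, 0.0)) -> np.ndarray:
    p = np.asarray(points, dtype=float) - np.asarray(center, dtype=float)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s], [s, c]])
    return p @ rot.T + np.asarray(center, dtype=float)
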