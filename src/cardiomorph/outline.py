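"""Organ-outline model: smoothing, landmarks, segments, angles.

The ventricle outline is traced manually as an ordered closed polyline.
It is smoothed with a closed composite cubic Bezier interpolating the
trace (Catmull-Rom construction, tension 0.5, C1 continuous), and the
cardiac centre is the arithmetic mean of the dense curve samples.  Four
anatomical landmarks given on the outline (1: AV joins IC, 2: IC joins
OFT, 3: OFT joins OC, 4: OC joins AV) are snapped to the curve; two more
are computed at one-third (5) and two-thirds (6) of the outer-curvature
arc from 3 to 4.  Rays from the centroid through the six points bound six
named sectors: IC (1-2), OFT (2-3), OC_near_OFT (3-5), OC_middle (5-6),
OC_near_AV (6-4) and AV (4-1).

Per-cell axial angles compare the cell orientation axis Ψ with the local
outline direction at the nearest curve sample.  Two conventions are
computed: "normal" (angle to the outward surface normal — 0° means the
axis points along the normal) and "tangent" (angle to the tangent).  Both
are reported because a radially oriented cell scores 0° in the first and
90° in the second; the convention used is stamped into every output.

Coordinates are stored in the image frame (x right, y down, µm); angles
are reported in the mathematical y-up frame like the rest of the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import fold_axial_deg, signed_area
from .mesh import CellMesh

__all__ = [
    "TracedOutline",
    "SmoothedOutline",
    "LandmarkSet",
    "SegmentPartition",
    "SEGMENT_NAMES",
    "smooth_outline",
    "place_landmarks",
    "partition_segments",
    "assign_cell_regions",
    "axial_angle",
    "axial_angles_for_mesh",
    "looping_angle",
]

SEGMENT_NAMES = ("IC", "OFT", "OC_near_OFT", "OC_middle", "OC_near_AV", "AV")
# segment name -> (start landmark, end landmark) walking the positive direction
_SEGMENT_BOUNDS = {
    "IC": ("lm1", "lm2"),
    "OFT": ("lm2", "lm3"),
    "OC_near_OFT": ("lm3", "lm5"),
    "OC_middle": ("lm5", "lm6"),
    "OC_near_AV": ("lm6", "lm4"),
    "AV": ("lm4", "lm1"),
}


class OutlineGeometryError(ValueError):
    pass


@dataclass
class TracedOutline:
    """Ordered closed trace of the organ circumference (µm), >= 8 points."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise OutlineGeometryError("trace must be an (n, 2) array")
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = ~np.all(np.isclose(pts[1:], pts[:-1]), axis=1)
        if not keep.all():
            warnings.warn("duplicate consecutive trace points removed")
            pts = pts[keep]
        if len(pts) < 8:
            raise OutlineGeometryError("trace needs at least 8 distinct points")
        try:
            from shapely.geometry import Polygon

            if not Polygon(pts).is_valid:
                raise OutlineGeometryError("trace is self-intersecting")
        except ImportError:  # pragma: no cover
            pass
        self.points = pts


@dataclass
class SmoothedOutline:
    """Densely sampled closed smooth curve with arc-length table."""

    points: np.ndarray  # (N, 2) samples along the closed curve
    arc: np.ndarray  # (N,) cumulative arc length, arc[0] = 0
    total_length: float
    centroid: np.ndarray  # mean of samples
    positively_oriented: bool = True

    def point_at_arc(self, s) -> np.ndarray:
        """Linear interpolation along samples at arc position(s) s (wraps)."""
        s = np.mod(np.asarray(s, dtype=float), self.total_length)
        scalar = s.ndim == 0
        s = np.atleast_1d(s)
        idx = np.searchsorted(self.arc, s, side="right") - 1
        idx = np.clip(idx, 0, len(self.arc) - 1)
        nxt = (idx + 1) % len(self.points)
        seg_len = np.where(
            idx < len(self.arc) - 1,
            self.arc[np.minimum(idx + 1, len(self.arc) - 1)] - self.arc[idx],
            self.total_length - self.arc[idx],
        )
        t = np.where(seg_len > 0, (s - self.arc[idx]) / np.where(seg_len > 0, seg_len, 1), 0.0)
        out = self.points[idx] + (self.points[nxt] - self.points[idx]) * t[:, None]
        return out[0] if scalar else out

    def nearest_sample(self, point) -> int:
        d = np.sum((self.points - np.asarray(point, dtype=float)) ** 2, axis=1)
        return int(np.argmin(d))

    def tangent_at(self, idx: int) -> np.ndarray:
        """Unit tangent at sample ``idx`` by central difference."""
        n = len(self.points)
        t = self.points[(idx + 1) % n] - self.points[(idx - 1) % n]
        norm = np.hypot(*t)
        if norm == 0:
            raise OutlineGeometryError("degenerate tangent")
        return t / norm

    def outward_normal_at(self, idx: int) -> np.ndarray:
        """Unit normal at sample ``idx`` pointing away from the centroid."""
        tx, ty = self.tangent_at(idx)
        nrm = np.array([-ty, tx])
        if np.dot(nrm, self.points[idx] - self.centroid) < 0:
            nrm = -nrm
        return nrm


def smooth_outline(traced: TracedOutline, samples_per_span: int = 20) -> SmoothedOutline:
    """Closed composite cubic Bezier through the trace (Catmull-Rom, tension 0.5).

    Each span between consecutive trace points is sampled uniformly in the
    Bezier parameter with ``samples_per_span`` points (endpoint excluded, so
    the trace points themselves are the first sample of each span).
    """
    if samples_per_span < 2:
        raise ValueError("samples_per_span must be >= 2")
    p = traced.points
    n = len(p)
    prev_ = np.roll(p, 1, axis=0)
    next_ = np.roll(p, -1, axis=0)
    next2 = np.roll(p, -2, axis=0)
    b0 = p
    b1 = p + (next_ - prev_) / 6.0
    b2 = next_ - (next2 - p) / 6.0
    b3 = next_
    t = np.linspace(0.0, 1.0, samples_per_span, endpoint=False)
    omt = 1.0 - t
    w0 = (omt**3)[:, None]
    w1 = (3 * t * omt**2)[:, None]
    w2 = (3 * t**2 * omt)[:, None]
    w3 = (t**3)[:, None]
    spans = (
        w0[None] * b0[:, None] + w1[None] * b1[:, None] + w2[None] * b2[:, None] + w3[None] * b3[:, None]
    )  # (n, samples_per_span, 2)
    samples = spans.reshape(n * samples_per_span, 2)
    seg = np.hypot(*(np.roll(samples, -1, axis=0) - samples).T)
    arc = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    total = float(seg.sum())
    centroid = samples.mean(axis=0)
    oriented = signed_area(samples) > 0
    return SmoothedOutline(
        points=samples,
        arc=arc,
        total_length=total,
        centroid=centroid,
        positively_oriented=bool(oriented),
    )


@dataclass
class LandmarkSet:
    """Snapped landmark points with their arc positions on the outline."""

    points: dict[str, np.ndarray]  # lm1..lm6 -> (2,) µm
    arc_positions: dict[str, float]
    reverse_outer: bool = False  # mirrored hearts: outer curvature runs 4 -> 3


def place_landmarks(
    smoothed: SmoothedOutline,
    lm1,
    lm2,
    lm3,
    lm4,
    tolerance_um: float = 5.0,
    reverse_outer: bool = False,
) -> LandmarkSet:
    """Snap the four given landmarks to the outline and compute 5 and 6.

    Landmarks 5 and 6 sit at one-third and two-thirds of the outer-curvature
    arc from landmark 3 to landmark 4, walking in the outline's positive
    traversal direction (set ``reverse_outer`` for mirrored hearts).  The
    four given landmarks must appear in cyclic order 1, 2, 3, 4 along that
    direction.
    """
    given = {"lm1": lm1, "lm2": lm2, "lm3": lm3, "lm4": lm4}
    pts: dict[str, np.ndarray] = {}
    arcs: dict[str, float] = {}
    for name, q in given.items():
        q = np.asarray(q, dtype=float)
        idx = smoothed.nearest_sample(q)
        dist = float(np.hypot(*(smoothed.points[idx] - q)))
        if dist > tolerance_um:
            raise OutlineGeometryError(
                f"landmark {name} is {dist:.2f} µm from the outline "
                f"(tolerance {tolerance_um} µm)"
            )
        pts[name] = smoothed.points[idx].copy()
        arcs[name] = float(smoothed.arc[idx])

    L = smoothed.total_length
    sign = -1.0 if reverse_outer else 1.0
    order = ["lm1", "lm2", "lm3", "lm4"]
    rel = [(sign * (arcs[k] - arcs["lm1"])) % L for k in order]
    if not (rel[0] < rel[1] < rel[2] < rel[3]):
        raise OutlineGeometryError(
            "landmarks are not in cyclic order 1,2,3,4 along the outline "
            f"(arc offsets {['%.1f' % r for r in rel]})"
        )

    span = (sign * (arcs["lm4"] - arcs["lm3"])) % L  # outer-curvature arc length
    for name, frac in (("lm5", 1.0 / 3.0), ("lm6", 2.0 / 3.0)):
        s = (arcs["lm3"] + sign * frac * span) % L
        arcs[name] = float(s)
        pts[name] = smoothed.point_at_arc(s)
    return LandmarkSet(points=pts, arc_positions=arcs, reverse_outer=reverse_outer)


@dataclass
class SegmentPartition:
    """Six angular sectors about the outline centroid.

    ``bounds`` maps segment name to ``(phi_start, width)`` where angles are
    polar angles about the centroid in the stored frame and ``width`` > 0 is
    measured in the walk direction (`orientation_sign`).  Sectors tile the
    full circle.
    """

    centroid: np.ndarray
    bounds: dict[str, tuple[float, float]]
    orientation_sign: float  # +1: positive polar direction; -1: negative

    def classify_point(self, point) -> str | None:
        p = np.asarray(point, dtype=float) - self.centroid
        if np.hypot(*p) == 0:
            return None
        phi = math.atan2(p[1], p[0])
        for name, (start, width) in self.bounds.items():
            off = (self.orientation_sign * (phi - start)) % (2 * math.pi)
            if off < width:
                return name
        # numerically on a boundary of the last sector
        return min(
            self.bounds,
            key=lambda nm: (self.orientation_sign * (phi - self.bounds[nm][0])) % (2 * math.pi),
        )

    def classify_points(self, points) -> list[str | None]:
        return [self.classify_point(p) for p in np.asarray(points, dtype=float)]


def partition_segments(smoothed: SmoothedOutline, landmarks: LandmarkSet) -> SegmentPartition:
    """Six sectors bounded by centroid->landmark rays (IC, OFT, OC×3, AV)."""
    c = smoothed.centroid
    phis = {}
    for name, pt in landmarks.points.items():
        v = pt - c
        if np.hypot(*v) == 0:
            raise OutlineGeometryError(f"landmark {name} coincides with the centroid")
        phis[name] = math.atan2(v[1], v[0])
    vals = sorted(phis.values())
    for a, b in zip(vals, vals[1:]):
        if abs(a - b) < 1e-12:
            raise OutlineGeometryError("two landmarks share the same polar angle")

    # walk direction about the centroid: positive polar if the outline is
    # positively oriented, flipped for mirrored hearts
    sign = 1.0 if smoothed.positively_oriented else -1.0
    if landmarks.reverse_outer:
        sign = -sign
    bounds: dict[str, tuple[float, float]] = {}
    total = 0.0
    for seg in SEGMENT_NAMES:
        a, b = _SEGMENT_BOUNDS[seg]
        width = (sign * (phis[b] - phis[a])) % (2 * math.pi)
        bounds[seg] = (phis[a], width)
        total += width
    if not math.isclose(total, 2 * math.pi, rel_tol=1e-9, abs_tol=1e-9):
        raise OutlineGeometryError(
            "landmark rays do not tile the circle in segment order; "
            "check landmark ordering/mirroring"
        )
    return SegmentPartition(centroid=c.copy(), bounds=bounds, orientation_sign=sign)


def assign_cell_regions(mesh: CellMesh, partition: SegmentPartition) -> CellMesh:
    """Label every cell with the sector containing its centroid (in place)."""
    n_unassigned = 0
    for cell in mesh.cells:
        region = partition.classify_point(cell.centroid)
        if region is None:
            n_unassigned += 1
        cell.region = region
    if n_unassigned:
        warnings.warn(f"{n_unassigned} cell(s) coincide with the centroid; unassigned")
    return mesh


def _direction_angle_y_up(vec) -> float:
    """Angle of a direction vector given in the image frame, in y-up degrees."""
    return math.degrees(math.atan2(-vec[1], vec[0]))


def axial_angle(
    cell_axis_deg: float,
    smoothed: SmoothedOutline,
    cell_centroid,
    convention: str = "normal",
) -> float:
    """Axial angle (degrees in (−90, 90]) between a cell axis and the outline.

    ``cell_axis_deg`` is the cell orientation axis Ψ in y-up degrees (as
    produced by morphometrics).  Under the default "normal" convention the
    angle is measured to the outward normal of the outline at the sample
    nearest the cell centroid (0° = radially oriented cell); under
    "tangent" it is measured to the tangent (0° = circumferential cell).
    NaN axes yield NaN.
    """
    if convention not in ("normal", "tangent"):
        raise ValueError("convention must be 'normal' or 'tangent'")
    if cell_axis_deg is None or (isinstance(cell_axis_deg, float) and math.isnan(cell_axis_deg)):
        return float("nan")
    idx = smoothed.nearest_sample(cell_centroid)
    ref_vec = (
        smoothed.outward_normal_at(idx) if convention == "normal" else smoothed.tangent_at(idx)
    )
    ref_deg = _direction_angle_y_up(ref_vec)
    return fold_axial_deg(float(cell_axis_deg) - ref_deg)


def axial_angles_for_mesh(
    mesh: CellMesh,
    smoothed: SmoothedOutline,
    shapes: pd.DataFrame,
    convention: str = "normal",
) -> pd.DataFrame:
    """Per-cell axial angles for a measured mesh.

    ``shapes`` is the morphometrics table (needs ``cell_id`` and
    ``orientation_deg``).  Cells with undefined axes get NaN angles and are
    excluded from downstream statistics with their count logged.
    """
    ax = dict(zip(shapes["cell_id"], shapes["orientation_deg"]))
    rows = []
    n_na = 0
    for cell in mesh.cells:
        psi = ax.get(cell.id, float("nan"))
        ang = axial_angle(psi, smoothed, cell.centroid, convention=convention)
        if math.isnan(ang):
            n_na += 1
        rows.append(
            dict(cell_id=cell.id, region=cell.region, angle_deg=ang, convention=convention)
        )
    if n_na:
        warnings.warn(f"{n_na} cell(s) with undefined orientation axis excluded (NaN)")
    return pd.DataFrame(rows)


def looping_angle(avj_p1, avj_p2, midline_vec) -> float:
    """Acute angle (degrees, [0, 90]) between the AVJ line and the midline.

    Invariant to swapping the AVJ endpoints and to the midline's sign; a
    2-D proxy for cardiac looping progress.
    """
    p1 = np.asarray(avj_p1, dtype=float)
    p2 = np.asarray(avj_p2, dtype=float)
    m = np.asarray(midline_vec, dtype=float)
    v = p2 - p1
    nv, nm = np.hypot(*v), np.hypot(*m)
    if nv == 0:
        raise ValueError("AVJ endpoints coincide")
    if nm == 0:
        raise ValueError("midline vector has zero length")
    cosang = abs(float(np.dot(v, m))) / (nv * nm)
    return math.degrees(math.acos(min(1.0, cosang)))
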