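"""Synthetic segmented-epithelium generator with ground-truth manifest.

Generates a bean-shaped, single-layered epithelium as a label raster plus
everything the analysis pipeline consumes: the traced organ outline, four
anatomical landmarks, two membrane-intensity channels, AVJ/midline
geometry, and a ground-truth manifest for parameter-recovery tests.

Construction
------------
The outline is a Fourier-perturbed ellipse.  Cells fill the band between
the outline and its inward offset: seeds are laid on a curvilinear
(arc-length × depth) lattice with per-segment density ``1/area_mean``,
then the band pixels are partitioned by an anisotropically weighted
nearest-seed rule — each seed carries a metric stretched along an
orientation axis drawn from an axial von Mises distribution about the
local outline normal, with the stretch chosen to reproduce the segment's
target circularity — followed by a few rounds of centroidal relaxation.
Mean cell area per segment is therefore controlled by seed count (segment
band area / n seeds), shape by the metric, and orientation by the draws.

Transition states are injected by contracting randomly chosen interior
junction edges to a point (snapped to the pixel-corner lattice so the
four cells meet exactly at one corner); each contraction is verified by
re-detection before it counts, so the injected count is exact.  Membrane
channels render every cell boundary with a Gaussian cross-section whose
amplitude depends on the segment (and, for mid-sagittal profiles, on the
apical/basal side), plus Gaussian noise, clipped to the 8-bit range.

Everything is deterministic under (spec, seed); the manifest records the
seed and a hash of the spec.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.ndimage import label as cc_label
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from . import outline as outline_mod
from .mesh import (
    CellMesh,
    PixelGrid,
    junction_corners_from_labels,
    mesh_from_labels,
    repair_label_connectivity,
)

__all__ = [
    "SegmentParams",
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticTissue",
    "generate_tissue",
    "generate_channels",
    "generate_midsagittal",
    "preset",
    "PRESETS",
    "aspect_from_circularity",
    "kappa_for_axial_sd",
    "background_mask",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SegmentParams:
    """Per-segment generator targets.

    ``orientation_mean_deg`` is the mean axial angle of the cell long axis
    relative to the local outward outline normal (0 = radial, 90 =
    circumferential); ``orientation_kappa`` is the von Mises concentration
    of the doubled-angle distribution.  ``amp`` maps channel name to
    (apical, basal) membrane amplitudes in grey levels.
    """

    area_mean: float = 95.0
    area_sd: float = 18.0
    target_circularity: float = 0.57
    orientation_mean_deg: float = 0.0
    orientation_kappa: float = 4.3
    amp: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (150.0, 150.0), "B": (150.0, 150.0)}
    )


@dataclass
class SyntheticSpec:
    seed: int = 0
    semi_axis_a: float = 90.0  # µm
    semi_axis_b: float = 60.0
    harmonics: tuple = ((2, 0.05, 0.0), (3, 0.04, 1.2))  # (k, rel. amplitude, phase)
    band_width: float = 40.0  # µm, monolayer thickness in projection
    landmark_angles_deg: dict[str, float] = field(
        default_factory=lambda: {"lm1": 280.0, "lm2": 10.0, "lm3": 60.0, "lm4": 230.0}
    )
    n_trace_points: int = 36
    segments: dict[str, SegmentParams] = field(
        default_factory=lambda: {name: SegmentParams() for name in outline_mod.SEGMENT_NAMES}
    )
    ts_rate_per_100: float = 5.5
    pixel_size: float = 0.2  # µm/px
    margin_um: float = 6.0
    relax_iterations: int = 2
    noise_sd: float = 6.0  # grey levels
    background_level: float = 12.0
    membrane_sigma_px: float = 1.0
    chanB_ts_absent_fraction: float = 0.0  # fraction of TS with channel B suppressed
    looping_angle_deg: float = 29.0
    intensity_gain: float = 1.0  # per-heart global brightness factor

    def validate(self):
        if self.pixel_size <= 0 or self.band_width <= 0:
            raise ValueError("pixel_size and band_width must be > 0")
        if self.ts_rate_per_100 < 0:
            raise ValueError("ts_rate_per_100 must be >= 0")
        for name, seg in self.segments.items():
            if name not in outline_mod.SEGMENT_NAMES:
                raise ValueError(f"unknown segment {name!r}")
            if seg.area_mean <= 0 or seg.area_sd < 0 or seg.orientation_kappa < 0:
                raise ValueError(f"invalid parameters for segment {name}")
            if not (0 < seg.target_circularity <= 1):
                raise ValueError("target_circularity must be in (0, 1]")
        missing = set(outline_mod.SEGMENT_NAMES) - set(self.segments)
        if missing:
            raise ValueError(f"segments missing: {sorted(missing)}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        segs = {
            k: SegmentParams(**{**v, "amp": {c: tuple(a) for c, a in v["amp"].items()}})
            for k, v in d.pop("segments").items()
        }
        d["harmonics"] = tuple(tuple(h) for h in d["harmonics"])
        return cls(segments=segs, **d)

    def hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


@dataclass
class GroundTruth:
    seed: int
    spec_hash: str
    cells: list[dict]  # cell_id, region, area_um2, psi_deg, delta_deg
    ts: list[dict]  # x_um, y_um, order
    landmarks: dict[str, tuple[float, float]]
    n_interior_cells: int
    ts_rate_injected: float
    avj: tuple[tuple[float, float], tuple[float, float]]
    midline_vec: tuple[float, float]
    looping_angle_deg: float
    chanB_present_ts: list[bool] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticTissue:
    labels: PixelGrid
    mesh: CellMesh
    traced_outline: outline_mod.TracedOutline
    landmarks: dict[str, np.ndarray]  # the four given landmark points
    ground_truth: GroundTruth
    smoothed: outline_mod.SmoothedOutline
    partition: outline_mod.SegmentPartition


# ---------------------------------------------------------------------------
# shape calibration helpers
# ---------------------------------------------------------------------------

def _hexagon_circularity(aspect: float) -> float:
    """Isoperimetric quotient of a regular hexagon stretched by ``aspect``."""
    ang = np.arange(6) * np.pi / 3.0
    v = np.stack([np.cos(ang) * math.sqrt(aspect), np.sin(ang) / math.sqrt(aspect)], axis=1)
    e = np.roll(v, -1, axis=0) - v
    per = float(np.hypot(*e.T).sum())
    area = 0.5 * abs(float(np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])))
    return 4.0 * math.pi * area / per**2

# tessellated cells are rougher than a regular hexagon; the measured
# circularity of generated tissue runs below the ideal-hexagon value by a
# roughly constant offset (generator calibration constant)
_CIRC_OFFSET = 0.0


def aspect_from_circularity(target_circ: float) -> float:
    """Linear stretch (long/short axis ratio) giving a hexagonal cell the
    requested isoperimetric quotient."""
    hex_max = _hexagon_circularity(1.0)
    c = target_circ + _CIRC_OFFSET
    if c >= hex_max:
        return 1.0
    return float(brentq(lambda a: _hexagon_circularity(a) - c, 1.0, 60.0, xtol=1e-6))


def kappa_for_axial_sd(sd_deg: float) -> float:
    """Doubled-angle von Mises concentration whose axial circular s.d. is
    ``sd_deg`` degrees (s.d. = sqrt(-2 ln R̄)/2 on the axial scale)."""
    from scipy.special import i0, i1

    target_rbar = math.exp(-0.5 * (2.0 * math.radians(sd_deg)) ** 2)
    f = lambda k: i1(k) / i0(k) - target_rbar
    return float(brentq(f, 1e-3, 500.0, xtol=1e-9))


# ---------------------------------------------------------------------------
# outline construction
# ---------------------------------------------------------------------------

def _outline_point(spec: SyntheticSpec, theta: np.ndarray, center: np.ndarray) -> np.ndarray:
    mod = np.ones_like(theta)
    for k, amp, phase in spec.harmonics:
        mod = mod + amp * np.cos(k * theta - phase)
    x = center[0] + mod * spec.semi_axis_a * np.cos(theta)
    y = center[1] + mod * spec.semi_axis_b * np.sin(theta)
    return np.stack([x, y], axis=1)


def _build_geometry(spec: SyntheticSpec):
    """Traced outline, smoothed curve, landmark set and partition."""
    amp_max = 1.0 + sum(a for _, a, _ in spec.harmonics)
    center = np.array(
        [spec.semi_axis_a * amp_max + spec.margin_um, spec.semi_axis_b * amp_max + spec.margin_um]
    )
    thetas = np.linspace(0.0, 2.0 * np.pi, spec.n_trace_points, endpoint=False)
    traced = outline_mod.TracedOutline(_outline_point(spec, thetas, center))
    smoothed = outline_mod.smooth_outline(traced)
    lm_pts = {
        name: _outline_point(spec, np.array([math.radians(a)]), center)[0]
        for name, a in spec.landmark_angles_deg.items()
    }
    landmarks = outline_mod.place_landmarks(
        smoothed, lm_pts["lm1"], lm_pts["lm2"], lm_pts["lm3"], lm_pts["lm4"]
    )
    partition = outline_mod.partition_segments(smoothed, landmarks)
    shape = (
        int(np.ceil((2 * spec.semi_axis_b * amp_max + 2 * spec.margin_um) / spec.pixel_size)),
        int(np.ceil((2 * spec.semi_axis_a * amp_max + 2 * spec.margin_um) / spec.pixel_size)),
    )
    return traced, smoothed, lm_pts, landmarks, partition, shape


def _band_mask(spec: SyntheticSpec, smoothed, shape) -> np.ndarray:
    from shapely.geometry import Polygon
    from skimage.draw import polygon as draw_polygon

    outer = Polygon(smoothed.points[::4])
    inner = outer.buffer(-spec.band_width)
    mask = np.zeros(shape, dtype=bool)
    ox, oy = np.asarray(outer.exterior.coords).T
    rr, cc = draw_polygon(oy / spec.pixel_size - 0.5, ox / spec.pixel_size - 0.5, shape)
    mask[rr, cc] = True
    geoms = getattr(inner, "geoms", [inner] if not inner.is_empty else [])
    for g in geoms:
        ix, iy = np.asarray(g.exterior.coords).T
        rr, cc = draw_polygon(iy / spec.pixel_size - 0.5, ix / spec.pixel_size - 0.5, shape)
        mask[rr, cc] = False
    return mask


def _classify_sector(partition, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Vectorised sector classification; returns index into SEGMENT_NAMES."""
    cx, cy = partition.centroid
    phi = np.arctan2(ys - cy, xs - cx)
    out = np.full(xs.shape, -1, dtype=np.int8)
    for k, name in enumerate(outline_mod.SEGMENT_NAMES):
        start, width = partition.bounds[name]
        off = np.mod(partition.orientation_sign * (phi - start), 2.0 * np.pi)
        out[(out == -1) & (off < width)] = k
    return out


# ---------------------------------------------------------------------------
# seed placement and anisotropic partition
# ---------------------------------------------------------------------------

def _place_seeds(spec: SyntheticSpec, smoothed, landmarks, partition, band, rng):
    """Curvilinear lattice of seeds with per-segment density and metric."""
    px = spec.pixel_size
    ys, xs = np.nonzero(band)
    seg_idx = _classify_sector(partition, (xs + 0.5) * px, (ys + 0.5) * px)
    seg_area = {
        name: float((seg_idx == k).sum()) * px * px
        for k, name in enumerate(outline_mod.SEGMENT_NAMES)
    }

    L = smoothed.total_length
    sign = -1.0 if landmarks.reverse_outer else 1.0
    px = spec.pixel_size
    h, w = band.shape
    centroid = smoothed.centroid

    def in_band(p) -> bool:
        j = int(p[0] / px)
        i = int(p[1] / px)
        return 0 <= i < h and 0 <= j < w and bool(band[i, j])

    seg_names = list(outline_mod.SEGMENT_NAMES)
    n_target = {}
    for seg_name in seg_names:
        mean_a = spec.segments[seg_name].area_mean
        if mean_a > seg_area[seg_name]:
            raise ValueError(
                f"infeasible packing: segment {seg_name} band area "
                f"{seg_area[seg_name]:.0f} µm² cannot hold a cell of mean area "
                f"{mean_a:.0f} µm²"
            )
        n_target[seg_name] = max(1, round(seg_area[seg_name] / mean_a))

    # 1. lattice positions: columns along the outline arc of each segment,
    #    rows descending along the inward normal (so the packing lattice is
    #    aligned with the frame the orientation draws refer to)
    positions: list[np.ndarray] = []
    for seg_name in seg_names:
        a_lm, b_lm = outline_mod._SEGMENT_BOUNDS[seg_name]
        s0 = landmarks.arc_positions[a_lm]
        span = (sign * (landmarks.arc_positions[b_lm] - s0)) % L
        par = spec.segments[seg_name]
        aspect = aspect_from_circularity(par.target_circularity)
        long_len = math.sqrt(par.area_mean * aspect)
        short_len = math.sqrt(par.area_mean / aspect)
        mu = math.radians(par.orientation_mean_deg)
        r_extent = abs(math.cos(mu)) * long_len + abs(math.sin(mu)) * short_len
        h_t = par.area_mean / r_extent
        n_cols = max(1, round(span / h_t))
        for c in range(n_cols):
            s = (s0 + sign * (c + 0.5 + rng.uniform(-0.15, 0.15)) * span / n_cols) % L
            idx = int(np.searchsorted(smoothed.arc, s) % len(smoothed.points))
            base = smoothed.points[idx]
            nrm_in = -smoothed.outward_normal_at(idx)
            probes = np.linspace(0.0, 1.6 * spec.band_width, 48)
            inside = np.array([in_band(base + t * nrm_in) for t in probes])
            if not inside[1]:
                continue
            stop = int(np.argmin(inside[1:]) + 1) if not inside[1:].all() else len(probes) - 1
            depth_max = float(probes[stop])
            rows = max(1, round(depth_max / r_extent))
            for r in range(rows):
                stag = 0.25 if r % 2 else -0.25
                depth = (r + 0.5 + rng.uniform(-0.12, 0.12)) / rows * depth_max
                pos = base + depth * nrm_in + stag * h_t * np.array([-nrm_in[1], nrm_in[0]])
                if not in_band(pos):
                    pos = base + depth * nrm_in
                    if not in_band(pos):
                        continue
                positions.append(pos)

    # 2. per-sector count correction: normal-descent columns can cross a
    #    sector boundary, so trim surpluses / pad deficits per sector to
    #    keep mean cell area = sector band area / n_target exactly
    pos_arr = np.asarray(positions)
    actual = _classify_sector(partition, pos_arr[:, 0], pos_arr[:, 1])
    keep_mask = np.ones(len(pos_arr), dtype=bool)
    extras: list[tuple[np.ndarray, int]] = []
    ys_b, xs_b = np.nonzero(band)
    pix_seg_all = _classify_sector(partition, (xs_b + 0.5) * px, (ys_b + 0.5) * px)
    for k, seg_name in enumerate(seg_names):
        idxs = np.flatnonzero((actual == k) & keep_mask)
        want = n_target[seg_name]
        if len(idxs) > want:
            drop = rng.choice(idxs, size=len(idxs) - want, replace=False)
            keep_mask[drop] = False
        elif len(idxs) < want:
            pool = np.flatnonzero(pix_seg_all == k)
            if len(pool):
                add = rng.choice(pool, size=min(want - len(idxs), len(pool)), replace=False)
                for j in add:
                    extras.append(
                        (np.array([(xs_b[j] + 0.5) * px, (ys_b[j] + 0.5) * px]), k)
                    )

    final_pos = [pos_arr[i] for i in np.flatnonzero(keep_mask)]
    final_seg = [seg_names[actual[i]] for i in np.flatnonzero(keep_mask)]
    final_pos += [p for p, _k in extras]
    final_seg += [seg_names[_k] for _p, _k in extras]

    # 3. per-seed metric and orientation draw, from the sector the seed
    #    actually landed in, about the normal at its nearest outline sample
    seeds, seed_axis_u, seed_scale, seed_seg, seed_psi, seed_delta = [], [], [], [], [], []
    for pos, seg_name in zip(final_pos, final_seg):
        par = spec.segments[seg_name]
        aspect = aspect_from_circularity(par.target_circularity)
        mu = math.radians(par.orientation_mean_deg)
        idx = smoothed.nearest_sample(pos)
        nrm_out = smoothed.outward_normal_at(idx)
        phi2 = (
            rng.vonmises(2.0 * mu, par.orientation_kappa)
            if par.orientation_kappa > 0
            else rng.uniform(-np.pi, np.pi)
        )
        delta = 0.5 * math.degrees(phi2)
        normal_yup = math.degrees(math.atan2(-nrm_out[1], nrm_out[0]))
        psi = (normal_yup + delta) % 180.0
        u = np.array([math.cos(math.radians(psi)), -math.sin(math.radians(psi))])
        area_i = max(0.3 * par.area_mean, rng.normal(par.area_mean, par.area_sd))
        seeds.append(pos)
        seed_axis_u.append(u)
        seed_scale.append((math.sqrt(aspect), area_i))
        seed_seg.append(seg_name)
        seed_psi.append(psi)
        seed_delta.append(delta)
    return (
        np.asarray(seeds),
        np.asarray(seed_axis_u),
        np.asarray(seed_scale),
        seed_seg,
        np.asarray(seed_psi),
        np.asarray(seed_delta),
    )


def _assign_labels(spec, band, seeds, axis_u, scale):
    """Anisotropically weighted nearest-seed partition of the band pixels."""
    px = spec.pixel_size
    h, w = band.shape
    best = np.full((h, w), np.inf, dtype=np.float32)
    lab = np.zeros((h, w), dtype=np.int32)
    for i in range(len(seeds)):
        sx, sy = seeds[i]
        stretch, area_i = scale[i]
        reach = 2.2 * math.sqrt(max(area_i, 1.0)) * stretch  # µm
        j0 = max(int((sx - reach) / px), 0)
        j1 = min(int((sx + reach) / px) + 1, w)
        i0 = max(int((sy - reach) / px), 0)
        i1 = min(int((sy + reach) / px) + 1, h)
        if i0 >= i1 or j0 >= j1:
            continue
        xs = (np.arange(j0, j1) + 0.5) * px - sx
        ys = (np.arange(i0, i1) + 0.5) * px - sy
        dx, dy = np.meshgrid(xs, ys)
        ux, uy = axis_u[i]
        along = (dx * ux + dy * uy) / stretch
        across = (-dx * uy + dy * ux) * stretch
        d2 = (along * along + across * across) / area_i
        win = best[i0:i1, j0:j1]
        m = (d2 < win) & band[i0:i1, j0:j1]
        win[m] = d2[m]
        lab[i0:i1, j0:j1][m] = i + 1
    # pixels no window reached: nearest seed by plain distance
    missed = band & (lab == 0)
    if missed.any():
        ys, xs = np.nonzero(missed)
        pts = np.stack([(xs + 0.5) * px, (ys + 0.5) * px], axis=1)
        _, idx = cKDTree(seeds).query(pts)
        lab[ys, xs] = idx.astype(np.int32) + 1
    return lab


def _relax(spec, band, seeds, axis_u, scale, iterations):
    lab = _assign_labels(spec, band, seeds, axis_u, scale)
    px = spec.pixel_size
    for _ in range(iterations):
        new_seeds = seeds.copy()
        for i in range(len(seeds)):
            ys, xs = np.nonzero(lab == i + 1)
            if len(xs) == 0:
                continue
            new_seeds[i] = [(xs.mean() + 0.5) * px, (ys.mean() + 0.5) * px]
        seeds = new_seeds
        lab = _assign_labels(spec, band, seeds, axis_u, scale)
    return lab, seeds


# ---------------------------------------------------------------------------
# transition-state surgery
# ---------------------------------------------------------------------------

def _local_ts_check(lab, corner_ij, merge_tol_px, want_cells=None, radius=4):
    """Check for a merged vertex of order >= 4 near ``corner_ij`` on the raster."""
    ci, cj = corner_ij
    i0, j0 = max(ci - radius, 0), max(cj - radius, 0)
    crop = lab[i0 : ci + radius, j0 : cj + radius]
    target = np.array([ci - i0, cj - j0], dtype=float)
    for center, inc in _merged_clusters(crop, merge_tol_px):
        if len(inc) >= 4 and np.hypot(*(center - target)) <= merge_tol_px + 1.0:
            if want_cells is None or want_cells <= inc:
                return True
    return False


def _cell_connected(lab, cell_id) -> bool:
    mask = lab == cell_id
    if not mask.any():
        return False
    _, n = cc_label(mask, structure=_STRUCT4)
    return n == 1


def _contract_edge(lab, px, v1, v2, cells_ab, cell_c, cell_d, interface_corners):
    """Collapse the shared boundary of cells A,B between junction corners
    v1,v2 onto a point m on the interface.

    A point where four cells meet has zero measure, so on a raster the T1
    configuration is realised the way anti-aliased segmentations show it:
    the one-pixel corridor of A-side pixels along the A|B interface is
    handed to C (the third cell at v1) on the v1 side of m and to D (at
    v2) on the v2 side.  A and B then meet only at m, where the two
    resulting 3-fold corners sit one pixel apart and merge into a single
    order-4 vertex under the default merge tolerance.  Verified by
    re-detection; ``lab`` is only modified on success.
    """
    A, B = sorted(cells_ab)
    mid = (np.asarray(v1, float) + np.asarray(v2, float)) / 2.0
    iface_arr = np.asarray(interface_corners, dtype=float)
    m = iface_arr[np.argmin(np.hypot(*(iface_arr - mid).T))].astype(int)

    iface = {tuple(int(x) for x in c) for c in interface_corners}
    i_min = max(int(min(c[0] for c in iface)) - 3, 0)
    i_max = min(int(max(c[0] for c in iface)) + 3, lab.shape[0])
    j_min = max(int(min(c[1] for c in iface)) - 3, 0)
    j_max = min(int(max(c[1] for c in iface)) + 3, lab.shape[1])
    backup = lab[i_min:i_max, j_min:j_max].copy()

    sub = lab[i_min:i_max, j_min:j_max]
    is_a = sub == A
    is_b = sub == B
    adj = np.zeros_like(is_a)
    adj[:, :-1] |= is_a[:, :-1] & is_b[:, 1:]
    adj[:, 1:] |= is_a[:, 1:] & is_b[:, :-1]
    adj[:-1, :] |= is_a[:-1, :] & is_b[1:, :]
    adj[1:, :] |= is_a[1:, :] & is_b[:-1, :]
    ri, rj = np.nonzero(adj)
    if len(ri) == 0:
        return None
    cy = ri + i_min + 0.5
    cx = rj + j_min + 0.5
    d1 = (cy - v1[0]) ** 2 + (cx - v1[1]) ** 2
    d2 = (cy - v2[0]) ** 2 + (cx - v2[1]) ** 2
    gained = np.where(d1 < d2, cell_c, cell_d)
    sub[ri, rj] = gained

    # the corridor follows the interface staircase, so consecutive gained
    # pixels can sit diagonally; add a stepping-stone pixel (preferring the
    # B-side one) at every diagonal step to keep the tails 4-connected
    pix_of = {}
    for k in range(len(ri)):
        pix_of[(int(ri[k]), int(rj[k]))] = int(gained[k])
    corridor = set(pix_of)
    for (i, j), cid in sorted(pix_of.items()):
        for di, dj in ((1, 1), (1, -1)):
            q = (i + di, j + dj)
            if pix_of.get(q) != cid:
                continue
            s1, s2 = (i + di, j), (i, j + dj)
            if any(s in corridor and pix_of.get(s) == cid for s in (s1, s2)):
                continue
            stone = None
            for s in (s1, s2):
                if 0 <= s[0] < sub.shape[0] and 0 <= s[1] < sub.shape[1]:
                    if sub[s] == B:
                        stone = s
                        break
                    if stone is None and sub[s] == A:
                        stone = s
            if stone is not None:
                sub[stone] = cid
                pix_of[stone] = cid
                corridor.add(stone)

    merge_tol_px = math.sqrt(2.0)
    ok = _local_ts_check(lab, (int(m[0]), int(m[1])), merge_tol_px, want_cells={A, B})
    ok = ok and all(_cell_connected_local(lab, c, None) for c in (A, B, cell_c, cell_d))
    ok = ok and not _extra_ts_in_box(
        lab, (i_min, i_max, j_min, j_max), (int(m[0]), int(m[1])), merge_tol_px
    )
    if not ok:
        lab[i_min:i_max, j_min:j_max] = backup
        return None
    return m


def _extra_ts_in_box(lab, box, m_ij, merge_tol_px) -> bool:
    """Any merged vertex of order >= 4 inside ``box`` away from ``m_ij``?"""
    i_min, i_max, j_min, j_max = box
    pad = 2
    i0, j0 = max(i_min - pad, 0), max(j_min - pad, 0)
    crop = lab[i0 : min(i_max + pad, lab.shape[0]), j0 : min(j_max + pad, lab.shape[1])]
    for center, inc in _merged_clusters(crop, merge_tol_px):
        if len(inc) >= 4:
            pos = center + np.array([i0, j0])
            if np.hypot(*(pos - np.asarray(m_ij, float))) > merge_tol_px + 1.0:
                return True
    return False


def _merged_clusters(lab_crop, merge_tol_px):
    """Junction corners of a raster crop, merged transitively within tol
    (same union-find rule as mesh_from_labels).  Yields (center_ij, cells)."""
    corners, incident = junction_corners_from_labels(lab_crop)
    if len(corners) == 0:
        return []
    pos = corners.astype(float)
    parent = list(range(len(pos)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    if len(pos) > 1:
        tree = cKDTree(pos)
        for a, b in tree.query_pairs(merge_tol_px):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for k in range(len(pos)):
        groups.setdefault(find(k), []).append(k)
    out = []
    for members in groups.values():
        inc = set().union(*(incident[g] for g in members))
        out.append((pos[members].mean(axis=0), inc))
    return out


def _cell_connected_local(lab, cid, box):
    ys, xs = np.nonzero(lab == cid)
    if len(xs) == 0:
        return False
    i0, i1 = ys.min(), ys.max() + 1
    j0, j1 = xs.min(), xs.max() + 1
    _, n = cc_label(lab[i0:i1, j0:j1] == cid, structure=_STRUCT4)
    return n == 1


def _pixel_boundary_loop(lab, cid, box):
    """Outer boundary loop of a cell in pixel-corner coordinates (x=col, y=row)."""
    from .mesh import _trace_boundary_loops

    ys, xs = np.nonzero(lab == cid)
    if len(xs) == 0:
        return None
    i0, i1 = ys.min(), ys.max() + 1
    j0, j1 = xs.min(), xs.max() + 1
    loops = _trace_boundary_loops(lab[i0:i1, j0:j1] == cid)
    if not loops:
        return None
    areas = [abs(0.5 * np.sum(lp[:, 0] * np.roll(lp[:, 1], -1) - np.roll(lp[:, 0], -1) * lp[:, 1])) for lp in loops]
    lp = loops[int(np.argmax(areas))]
    lp = lp.copy()
    lp[:, 0] += j0
    lp[:, 1] += i0
    return lp


def _break_spurious_ts(lab, merge_tol_px, rng, max_fix=50, protect_ij=None):
    """Remove accidental order->=4 raster vertices by 1-pixel reassignments,
    leaving clusters near ``protect_ij`` (row, col corners) untouched."""
    protect = [np.asarray(p, dtype=float) for p in (protect_ij or [])]
    for _ in range(max_fix):
        bad = None
        for center, inc in _merged_clusters(lab, merge_tol_px):
            if len(inc) < 4:
                continue
            if any(np.hypot(*(center - p)) <= merge_tol_px + 1.0 for p in protect):
                continue
            bad = center
            break
        if bad is None:
            return lab
        ci, cj = int(round(bad[0])), int(round(bad[1]))
        if not _try_local_fix(lab, (ci, cj), merge_tol_px):
            warnings.warn("could not break a spurious transition state")
            return lab
    return lab


def _no_ts_in_crop(lab, corner, merge_tol_px, radius=5) -> bool:
    ci, cj = corner
    i0, j0 = max(ci - radius, 0), max(cj - radius, 0)
    crop = lab[i0 : ci + radius, j0 : cj + radius]
    return all(len(inc) < 4 for _, inc in _merged_clusters(crop, merge_tol_px))


def _try_local_fix(lab, corner, merge_tol_px) -> bool:
    """Break an accidental order->=4 vertex by reassigning one or two
    nearby pixels, keeping all touched cells 4-connected."""
    ci, cj = corner
    h, w = lab.shape

    def neighbours(i, j, old):
        out = set()
        for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            ii, jj = i + di, j + dj
            if 0 <= ii < h and 0 <= jj < w and lab[ii, jj] not in (0, old):
                out.add(int(lab[ii, jj]))
        return sorted(out)

    cand_pixels = [
        (i, j)
        for i in range(max(ci - 2, 0), min(ci + 3, h))
        for j in range(max(cj - 2, 0), min(cj + 3, w))
        if lab[i, j] != 0
    ]
    # single-pixel moves first, then a second adjacent pixel of the same cell
    for i, j in cand_pixels:
        old = int(lab[i, j])
        for nv in neighbours(i, j, old):
            lab[i, j] = nv
            if (
                _no_ts_in_crop(lab, (ci, cj), merge_tol_px)
                and _cell_connected_local(lab, old, None)
                and _cell_connected_local(lab, nv, None)
            ):
                return True
            for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                ii, jj = i + di, j + dj
                if not (0 <= ii < h and 0 <= jj < w) or lab[ii, jj] != old:
                    continue
                lab[ii, jj] = nv
                if (
                    _no_ts_in_crop(lab, (ci, cj), merge_tol_px)
                    and _cell_connected_local(lab, old, None)
                    and _cell_connected_local(lab, nv, None)
                ):
                    return True
                lab[ii, jj] = old
            lab[i, j] = old
    return False


def _inject_transition_states(lab, spec, mesh, rng):
    """Contract interior junction edges until the target TS count is met."""
    px = spec.pixel_size
    interior = {c.id for c in mesh.cells if not c.is_boundary}
    n_interior = len(interior)
    # stochastic rounding keeps the injected rate unbiased across seeds
    # (the per-tissue count is quantised to ~1.5 per 100 cells otherwise)
    x = spec.ts_rate_per_100 / 100.0 * n_interior
    k_target = int(math.floor(x)) + int(rng.random() < (x - math.floor(x)))
    if k_target == 0:
        return [], n_interior

    # candidate edges: pairs of order-3 vertices sharing exactly two cells;
    # the two cells losing the junction must be interior (the state is then
    # always counted), the two gaining cells may sit at the rim
    verts = [v for v in mesh.vertices if v.order == 3]
    by_pair: dict[tuple[int, int], list[int]] = {}
    from itertools import combinations as _comb

    for vi, v in enumerate(verts):
        for pair in _comb(sorted(v.incident_cells), 2):
            by_pair.setdefault(pair, []).append(vi)
    cand = []
    for pair, vis in by_pair.items():
        if len(vis) != 2:
            continue
        a, b = vis
        shared = verts[a].incident_cells & verts[b].incident_cells
        if len(shared) != 2 or tuple(sorted(shared)) != pair:
            continue
        involved = verts[a].incident_cells | verts[b].incident_cells
        if len(involved) != 4 or not set(pair) <= interior:
            continue
        dist = float(np.hypot(*(verts[a].position - verts[b].position)))
        cand.append((dist, a, b, pair))
    cand.sort()
    if not cand:
        warnings.warn("no eligible interior edges for transition-state injection")
        return [], n_interior
    lengths = np.array([c[0] for c in cand])
    cutoff = np.quantile(lengths, 0.75)
    eligible = [c for c in cand if c[0] <= cutoff and c[0] > 2.0 * px]
    rng.shuffle(eligible)

    used_cells: set[int] = set()
    injected = []
    for dist, a, b, shared in eligible:
        if len(injected) >= k_target:
            break
        va, vb = verts[a], verts[b]
        involved = va.incident_cells | vb.incident_cells
        if involved & used_cells or len(involved) != 4:
            continue
        A, B = shared
        cell_c = next(iter(va.incident_cells - set(shared)))
        cell_d = next(iter(vb.incident_cells - set(shared)))
        # interface corners between A and B, in (row, col) corner units
        iface = _interface_corners(lab, A, B)
        v1_ij = (va.position[1] / px, va.position[0] / px)
        v2_ij = (vb.position[1] / px, vb.position[0] / px)
        m = _contract_edge(lab, px, v1_ij, v2_ij, (A, B), cell_c, cell_d, iface)
        if m is None:
            continue
        used_cells |= involved
        injected.append(
            dict(x_um=float(m[1] * px), y_um=float(m[0] * px), order=4,
                 cells=sorted(int(c) for c in involved))
        )
    if len(injected) < k_target:
        warnings.warn(
            f"injected {len(injected)}/{k_target} transition states "
            "(ran out of eligible edges)"
        )
    return injected, n_interior


def _interface_corners(lab, A, B):
    """Corners whose 2x2 block contains both labels A and B."""
    pad = np.pad(lab, 1, constant_values=0)
    blocks = np.stack([pad[:-1, :-1], pad[:-1, 1:], pad[1:, :-1], pad[1:, 1:]])
    has_a = (blocks == A).any(axis=0)
    has_b = (blocks == B).any(axis=0)
    ii, jj = np.nonzero(has_a & has_b)
    return np.stack([ii, jj], axis=1)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def generate_tissue(spec: SyntheticSpec) -> SyntheticTissue:
    """Generate a labelled synthetic epithelium with ground truth.

    Deterministic under ``(spec, spec.seed)``.  Raises if the requested
    packing is infeasible (cells too large for the band).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    traced, smoothed, lm_pts, landmarks, partition, shape = _build_geometry(spec)
    band = _band_mask(spec, smoothed, shape)
    if not band.any():
        raise ValueError("band is empty: band_width exceeds the outline size")

    seeds, axis_u, scale, seed_seg, seed_psi, seed_delta = _place_seeds(
        spec, smoothed, landmarks, partition, band, rng
    )
    if len(seeds) < 3:
        raise ValueError("infeasible packing: fewer than 3 cells fit the band")
    lab, seeds = _relax(spec, band, seeds, axis_u, scale, spec.relax_iterations)
    lab = repair_label_connectivity(lab)
    # drop empty labels and relabel contiguously, tracking the draws
    present = [int(v) for v in np.unique(lab) if v > 0]
    remap = {old: new + 1 for new, old in enumerate(present)}
    lut = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    for old, new in remap.items():
        lut[old] = new
    lab = lut[lab]
    meta = {
        remap[i + 1]: dict(psi_deg=float(seed_psi[i]), delta_deg=float(seed_delta[i]))
        for i in range(len(seeds))
        if (i + 1) in remap
    }

    merge_tol_px = math.sqrt(2.0)
    lab = _break_spurious_ts(lab, merge_tol_px, rng)
    grid = PixelGrid(lab, spec.pixel_size)
    mesh0 = mesh_from_labels(grid)

    injected, n_interior = _inject_transition_states(lab, spec, mesh0, rng)
    protect = [(t["y_um"] / spec.pixel_size, t["x_um"] / spec.pixel_size) for t in injected]
    lab = _break_spurious_ts(lab, merge_tol_px, rng, protect_ij=protect)
    grid = PixelGrid(lab, spec.pixel_size)
    mesh = mesh_from_labels(grid)
    n_det = sum(1 for v in mesh.vertices if v.order >= 4)
    if n_det != len(injected):
        warnings.warn(
            f"detected {n_det} transition states but injected {len(injected)}"
        )
    outline_mod.assign_cell_regions(mesh, partition)

    cells_gt = []
    for c in mesh.cells:
        info = meta.get(c.id, {})
        cells_gt.append(
            dict(
                cell_id=c.id,
                region=c.region,
                area_um2=float(c.area),
                psi_deg=info.get("psi_deg", float("nan")),
                delta_deg=info.get("delta_deg", float("nan")),
                is_boundary=c.is_boundary,
            )
        )

    avj_p1 = tuple(landmarks.points["lm1"])
    avj_p2 = tuple(landmarks.points["lm4"])
    avj_dir = np.asarray(avj_p2) - np.asarray(avj_p1)
    avj_dir = avj_dir / np.hypot(*avj_dir)
    ang = math.radians(spec.looping_angle_deg)
    rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
    midline = tuple(rot @ avj_dir)

    gt = GroundTruth(
        seed=spec.seed,
        spec_hash=spec.hash(),
        cells=cells_gt,
        ts=injected,
        landmarks={k: (float(v[0]), float(v[1])) for k, v in lm_pts.items()},
        n_interior_cells=n_interior,
        ts_rate_injected=(100.0 * len(injected) / n_interior) if n_interior else 0.0,
        avj=(avj_p1, avj_p2),
        midline_vec=midline,
        looping_angle_deg=spec.looping_angle_deg,
    )
    return SyntheticTissue(
        labels=grid,
        mesh=mesh,
        traced_outline=traced,
        landmarks={k: np.asarray(v) for k, v in lm_pts.items()},
        ground_truth=gt,
        smoothed=smoothed,
        partition=partition,
    )


def generate_channels(tissue: SyntheticTissue, spec: SyntheticSpec, channels=("A", "B")):
    """Render membrane-intensity channels for a generated tissue.

    Each cell boundary contributes a Gaussian ridge (σ = membrane_sigma_px)
    whose amplitude is the apical amplitude of the channel in the cell's
    segment, scaled by ``intensity_gain``; Gaussian noise is added and the
    result clipped to 8 bit.  If ``chanB_ts_absent_fraction`` > 0, channel
    "B" is suppressed in discs around that fraction of the injected
    transition states (recorded in the ground truth).
    """
    rng = np.random.default_rng(spec.seed + 7)
    lab = tissue.labels.values
    px = spec.pixel_size
    boundary = np.zeros(lab.shape, dtype=bool)
    boundary[:, :-1] |= (lab[:, :-1] != lab[:, 1:]) & (lab[:, :-1] > 0)
    boundary[:, 1:] |= (lab[:, :-1] != lab[:, 1:]) & (lab[:, 1:] > 0)
    boundary[:-1, :] |= (lab[:-1, :] != lab[1:, :]) & (lab[:-1, :] > 0)
    boundary[1:, :] |= (lab[:-1, :] != lab[1:, :]) & (lab[1:, :] > 0)
    dist, (inds_i, inds_j) = distance_transform_edt(~boundary, return_indices=True)
    ridge = np.exp(-(dist**2) / (2.0 * spec.membrane_sigma_px**2))
    nearest_label = lab[inds_i, inds_j]

    region_of = {c.id: (c.region or "OC_middle") for c in tissue.mesh.cells}
    ts_positions = [(t["x_um"], t["y_um"]) for t in tissue.ground_truth.ts]
    n_ts = len(ts_positions)
    present_b = np.ones(n_ts, dtype=bool)
    if n_ts and spec.chanB_ts_absent_fraction > 0:
        # stochastic rounding: unbiased absent fraction across tissues
        x = spec.chanB_ts_absent_fraction * n_ts
        n_off = int(np.floor(x)) + int(rng.random() < (x - np.floor(x)))
        n_off = min(n_off, n_ts)
        off = rng.choice(n_ts, size=n_off, replace=False)
        present_b[off] = False
    tissue.ground_truth.chanB_present_ts = [bool(b) for b in present_b]

    out = {}
    for ch in channels:
        amp_of = np.zeros(int(lab.max()) + 1, dtype=float)
        for cid, region in region_of.items():
            amp_of[cid] = spec.segments[region].amp[ch][0]
        amp_map = amp_of[nearest_label] * spec.intensity_gain
        img = spec.background_level + amp_map * ridge
        if ch == "B" and n_ts:
            yy, xx = np.mgrid[0 : lab.shape[0], 0 : lab.shape[1]]
            cx_um = (xx + 0.5) * px
            cy_um = (yy + 0.5) * px
            for k, (tx, ty) in enumerate(ts_positions):
                if present_b[k]:
                    continue
                mask = (cx_um - tx) ** 2 + (cy_um - ty) ** 2 <= (2.5) ** 2
                img[mask] = spec.background_level
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        out[ch] = PixelGrid(np.clip(np.round(img), 0, 255).astype(np.uint8), px)
    return out


def background_mask(labels: PixelGrid, clearance_um: float = 5.0) -> np.ndarray:
    """Pixels at least ``clearance_um`` away from any labelled tissue."""
    outside = labels.values == 0
    d = distance_transform_edt(outside) * labels.pixel_size
    return d >= clearance_um


# ---------------------------------------------------------------------------
# mid-sagittal membrane profiles
# ---------------------------------------------------------------------------

@dataclass
class MidsagittalSpec:
    seed: int = 0
    radius_apical: float = 42.0  # µm
    radius_basal: float = 34.0
    arc_span_deg: float = 170.0  # AV end -> OFT end
    pixel_size: float = 0.2
    amp_low: float = 60.0  # grey levels at the AV end
    amp_high: float = 140.0  # plateau from the OFT-window start onward
    delta: float = 0.35  # injected normalised apical-basal difference in the window
    oft_fraction: float = 0.25  # trailing fraction of the arc flagged as OFT
    noise_sd: float = 4.0
    background_level: float = 10.0
    membrane_sigma_px: float = 1.0


@dataclass
class MidsagittalSample:
    apical_path: np.ndarray  # µm polyline
    basal_path: np.ndarray
    channel: PixelGrid
    oft_window: tuple[float, float]  # arc interval of the apical path, µm
    oft_window_basal: tuple[float, float]
    delta: float
    seed: int


def _arc_points(radius, center, span_deg, n):
    t = np.linspace(math.radians(180.0), math.radians(180.0 - span_deg), n)
    return np.stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)], axis=1)


def generate_midsagittal(mspec: MidsagittalSpec) -> MidsagittalSample:
    """Two nested membrane arcs (apical outside, basal inside) with an
    apical-only amplitude plateau boost in the OFT window.

    The injected ``delta`` is, by construction, the difference of the
    jointly min–max normalised apical and basal window means in the
    noise-free image: raw window amplitudes are ``A0 + δ/(1−δ)·(A0−A_lo)``
    (apical) vs ``A0`` (basal) with minimum ``A_lo``.
    """
    if not (0.0 <= mspec.delta < 1.0):
        raise ValueError("delta must be in [0, 1)")
    rng = np.random.default_rng(mspec.seed)
    px = mspec.pixel_size
    r_ap, r_bas = mspec.radius_apical, mspec.radius_basal
    center = np.array([r_ap + 6.0, r_ap + 6.0])
    n_pts = 600
    ap = _arc_points(r_ap, center, mspec.arc_span_deg, n_pts)
    bas = _arc_points(r_bas, center, mspec.arc_span_deg, n_pts)

    def arcs(path):
        seg = np.hypot(*np.diff(path, axis=0).T)
        return np.concatenate([[0.0], np.cumsum(seg)])

    arc_ap, arc_bas = arcs(ap), arcs(bas)
    L_ap, L_bas = arc_ap[-1], arc_bas[-1]
    win_ap = ((1.0 - mspec.oft_fraction) * L_ap, L_ap)
    win_bas = ((1.0 - mspec.oft_fraction) * L_bas, L_bas)

    A_lo, A0 = mspec.amp_low, mspec.amp_high
    boost = mspec.delta / (1.0 - mspec.delta) * (A0 - A_lo)

    def amp(arc, L, window, apical: bool):
        ramp = np.clip(arc / (window[0] if window[0] > 0 else 1.0), 0.0, 1.0)
        a = A_lo + (A0 - A_lo) * ramp
        if apical:
            a = np.where(arc >= window[0], A0 + boost, a)
        else:
            a = np.where(arc >= window[0], A0, a)
        return a

    amp_ap = amp(arc_ap, L_ap, win_ap, True)
    amp_bas = amp(arc_bas, L_bas, win_bas, False)

    hw = int(np.ceil((2 * r_ap + 12.0) / px))
    yy, xx = np.mgrid[0:hw, 0:hw]
    pix = np.stack([(xx.ravel() + 0.5) * px, (yy.ravel() + 0.5) * px], axis=1)

    def render(a_bas_gain: float) -> np.ndarray:
        img = np.full((hw, hw), mspec.background_level, dtype=float)
        for path, a in ((ap, amp_ap), (bas, amp_bas * a_bas_gain)):
            tree = cKDTree(path)
            d, idx = tree.query(pix, distance_upper_bound=5.0 * mspec.membrane_sigma_px * px)
            hit = np.isfinite(d)
            contrib = np.zeros(len(pix))
            contrib[hit] = a[np.clip(idx[hit], 0, len(a) - 1)] * np.exp(
                -(d[hit] ** 2) / (2.0 * (mspec.membrane_sigma_px * px) ** 2)
            )
            img += contrib.reshape(hw, hw)
        return img

    # the rendered ridge keeps a slightly different share of its nominal
    # amplitude on the two (differently curved) membranes; calibrate the
    # basal gain on a noise-free render so the injected normalised
    # difference is realised exactly by a wide line scan
    from .intensity import line_profile

    clean = PixelGrid(render(1.0), px)
    prof_ap = line_profile(clean, ap, side="apical")
    prof_bas = line_profile(clean, bas, side="basal")
    m_ap = prof_ap.raw[prof_ap.arc_um >= win_ap[0] + 2.0].mean() - mspec.background_level
    m_bas = prof_bas.raw[prof_bas.arc_um >= win_bas[0] + 2.0].mean() - mspec.background_level
    plateau_ratio = (A0 + boost) / A0  # nominal apical/basal plateau ratio
    gain = (m_ap / plateau_ratio) / m_bas if m_bas > 0 else 1.0

    img = render(gain) + rng.normal(0.0, mspec.noise_sd, size=(hw, hw))
    chan = PixelGrid(np.clip(np.round(img), 0, 255).astype(np.uint8), px)
    # the recorded call window starts past the amplitude transition so the
    # rendering smear at the window edge does not dilute window means
    inset = 2.0
    return MidsagittalSample(
        apical_path=ap,
        basal_path=bas,
        channel=chan,
        oft_window=(win_ap[0] + inset, win_ap[1]),
        oft_window_basal=(win_bas[0] + inset, win_bas[1]),
        delta=mspec.delta,
        seed=mspec.seed,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _wt_segments() -> dict[str, SegmentParams]:
    """Wild-type-like regional targets at chamber stage.

    IC cells are small and round, OC cells large and elongated with axes
    near the outline normal; OFT and AV cells run circumferential.  The
    membrane channels (A ~ F-actin, B ~ phospho-myosin) are brighter in the
    distal/OFT segments, mirroring the tissue-scale polarisation regime.
    """
    kappa = kappa_for_axial_sd(15.0)
    high = {"A": (200.0, 110.0), "B": (190.0, 100.0)}
    low = {"A": (130.0, 130.0), "B": (120.0, 120.0)}
    return {
        "IC": SegmentParams(83.0, 16.0, 0.60, 0.0, kappa, dict(low)),
        "OFT": SegmentParams(95.0, 18.0, 0.55, 90.0, kappa, dict(high)),
        "OC_near_OFT": SegmentParams(107.0, 20.0, 0.53, 0.0, kappa, dict(high)),
        "OC_middle": SegmentParams(107.0, 20.0, 0.53, 0.0, kappa, dict(low)),
        "OC_near_AV": SegmentParams(107.0, 20.0, 0.53, 0.0, kappa, dict(low)),
        "AV": SegmentParams(90.0, 18.0, 0.58, 90.0, kappa, dict(low)),
    }


def preset(name: str, seed: int = 0) -> SyntheticSpec:
    """Named generator presets echoing the staged wild-type and
    PCP-deficient regimes (transition-state rates per 100 cells: 9.0 at
    the linear-heart-tube stage, 5.5 / 4.5 at chamber stages, 8.8 for the
    frizzled-deficient-like tissue)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    spec = PRESETS[name]()
    spec.seed = seed
    return spec


def _preset_wt54() -> SyntheticSpec:
    return SyntheticSpec(segments=_wt_segments(), ts_rate_per_100=5.5, looping_angle_deg=29.0)


def _preset_wt26() -> SyntheticSpec:
    return SyntheticSpec(segments=_wt_segments(), ts_rate_per_100=9.0, looping_angle_deg=29.0)


def _preset_wt72() -> SyntheticSpec:
    return SyntheticSpec(segments=_wt_segments(), ts_rate_per_100=4.5, looping_angle_deg=29.0)


def _preset_fzd7a() -> SyntheticSpec:
    segs = _wt_segments()
    segs["OFT"] = dataclasses.replace(
        segs["OFT"],
        orientation_mean_deg=118.0,  # shifted axis with high angular spread
        orientation_kappa=kappa_for_axial_sd(35.0),
        amp={"A": (140.0, 135.0), "B": (130.0, 128.0)},
    )
    return SyntheticSpec(segments=segs, ts_rate_per_100=8.8, looping_angle_deg=42.0)


def _preset_orientation() -> SyntheticSpec:
    """Wild-type-like tissue with an enlarged outflow tract holding on the
    order of 86 analysable OFT cells per heart, the per-heart sample size
    used for the axial-orientation recovery experiments."""
    return SyntheticSpec(
        segments=_wt_segments(),
        semi_axis_a=118.0,
        semi_axis_b=75.0,
        landmark_angles_deg={"lm1": 280.0, "lm2": 330.0, "lm3": 120.0, "lm4": 230.0},
        ts_rate_per_100=5.5,
        looping_angle_deg=29.0,
    )


PRESETS = {
    "wt-54hpf": _preset_wt54,
    "wt-26hpf": _preset_wt26,
    "wt-72hpf": _preset_wt72,
    "fzd7a-54hpf": _preset_fzd7a,
    "orientation-recovery": _preset_orientation,
}
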