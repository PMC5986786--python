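"""Membrane fluorescence analysis: line profiles, normalisation, calls.

Line profiles emulate a wide line scan: samples are placed at one-pixel
arc spacing along a path and, at each sample, the intensity is the mean of
``width_px`` bilinear sub-samples placed symmetrically along the local
perpendicular — averaging across the line width to reduce noise.
Profiles are min–max normalised over the selection, so all downstream
calls are invariant to per-channel affine intensity rescaling.

Apical-accumulation ("aa") calls compare jointly normalised apical and
basal profiles inside the OFT window against a fixed margin.  Presence of
a channel at a transition state uses a disc statistic: mean intensity
within ``radius_um`` of the vertex above background mean + k·s.d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .mesh import InputError, PixelGrid
from .transitions import TransitionState

__all__ = [
    "IntensityProfile",
    "AccumulationCall",
    "ColocTable",
    "line_profile",
    "minmax_normalise",
    "joint_normalise",
    "apical_accumulation_call",
    "ventricular_mean_intensity",
    "colocalisation_at_ts",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 always rounding up (reporting style
    for percentages)."""
    return int(math.floor(x + 0.5))


@dataclass
class IntensityProfile:
    path: np.ndarray  # polyline (µm) the scan follows
    side: str  # "apical" | "basal" | other tag
    arc_um: np.ndarray
    raw: np.ndarray
    normalised: np.ndarray | None = None
    oft_window: tuple[float, float] | None = None  # arc interval (µm)

    def window_mask(self, window: tuple[float, float] | None = None) -> np.ndarray:
        win = window or self.oft_window
        if win is None:
            raise ValueError("no OFT window set")
        lo, hi = win
        if hi <= lo:
            raise ValueError("empty OFT window")
        return (self.arc_um >= lo) & (self.arc_um <= hi)


@dataclass
class AccumulationCall:
    heart_id: str
    channel: str
    region: str
    aa: bool
    margin_used: float
    apical_mean: float
    basal_mean: float


@dataclass
class ColocTable:
    records: pd.DataFrame  # ts_id, presence_A, presence_B
    n_total: int
    n_coloc: int

    @property
    def percent(self) -> int:
        """Co-localised share as a half-up rounded integer percentage."""
        if self.n_total == 0:
            raise ValueError("no transition states scored")
        return round_half_up(100.0 * self.n_coloc / self.n_total)

    @property
    def percent_raw(self) -> float:
        return 100.0 * self.n_coloc / self.n_total


def _resample_path(path_um: np.ndarray, step_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at fixed arc spacing; returns (points, arc)."""
    p = np.asarray(path_um, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 2:
        raise InputError("path must be an (n>=2, 2) array in µm")
    seg = np.hypot(*np.diff(p, axis=0).T)
    total = float(seg.sum())
    if total == 0:
        raise InputError("zero-length path")
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.arange(0.0, total + 1e-9, step_um)
    x = np.interp(s, arc, p[:, 0])
    y = np.interp(s, arc, p[:, 1])
    return np.stack([x, y], axis=1), s


def line_profile(
    channel: PixelGrid,
    path_um: np.ndarray,
    width_px: int = 10,
    side: str = "profile",
    oft_window: tuple[float, float] | None = None,
) -> IntensityProfile:
    """Width-averaged line scan along a path (arc positions in µm).

    Samples fall at one-pixel arc spacing; at each one, ``width_px``
    bilinear sub-samples at one-pixel spacing straddle the path
    symmetrically along the local perpendicular and are averaged.  Samples
    whose footprint leaves the raster are clipped off with a warning.
    """
    if width_px < 1:
        raise InputError("width_px must be >= 1")
    px = channel.pixel_size
    pts, arc = _resample_path(np.asarray(path_um, dtype=float), px)

    # local unit tangents by central difference on the resampled points
    t = np.gradient(pts, axis=0)
    norms = np.hypot(*t.T)
    norms[norms == 0] = 1.0
    t /= norms[:, None]
    perp = np.stack([-t[:, 1], t[:, 0]], axis=1)

    offsets = (np.arange(width_px) - (width_px - 1) / 2.0) * px
    sub = pts[:, None, :] + offsets[None, :, None] * perp[:, None, :]  # (n, w, 2)

    # µm -> pixel-centre coordinates (pixel (i,j) centre at ((j+.5)px, (i+.5)px))
    cols = sub[..., 0] / px - 0.5
    rows = sub[..., 1] / px - 0.5
    h, w = channel.shape
    inside = (
        (rows >= -0.5) & (rows <= h - 0.5) & (cols >= -0.5) & (cols <= w - 0.5)
    ).all(axis=1)
    if not inside.all():
        import warnings

        warnings.warn(
            f"{int((~inside).sum())} profile sample(s) outside the raster were clipped"
        )
    if not inside.any():
        raise InputError("path lies entirely outside the raster")
    vals = map_coordinates(
        channel.values.astype(float),
        [rows[inside].ravel(), cols[inside].ravel()],
        order=1,
        mode="nearest",
    ).reshape(-1, width_px)
    return IntensityProfile(
        path=np.asarray(path_um, dtype=float),
        side=side,
        arc_um=arc[inside],
        raw=vals.mean(axis=1),
        oft_window=oft_window,
    )


def minmax_normalise(profile: IntensityProfile) -> IntensityProfile:
    """Normalise raw values to [0, 1] over the profile's own selection."""
    lo, hi = float(profile.raw.min()), float(profile.raw.max())
    if hi <= lo:
        raise ValueError("no dynamic range: flat profile cannot be normalised")
    profile.normalised = (profile.raw - lo) / (hi - lo)
    return profile


def joint_normalise(*profiles: IntensityProfile) -> tuple[IntensityProfile, ...]:
    """Min–max normalise several profiles on a shared raw scale, keeping
    them mutually comparable (used for apical-vs-basal calls)."""
    lo = min(float(p.raw.min()) for p in profiles)
    hi = max(float(p.raw.max()) for p in profiles)
    if hi <= lo:
        raise ValueError("no dynamic range across profiles")
    for p in profiles:
        p.normalised = (p.raw - lo) / (hi - lo)
    return profiles


def apical_accumulation_call(
    apical: IntensityProfile,
    basal: IntensityProfile,
    oft_window: tuple[float, float] | None = None,
    margin: float = 0.2,
    heart_id: str = "",
    channel: str = "",
    region: str = "",
) -> AccumulationCall:
    """Call apical accumulation inside the OFT window.

    Profiles must be normalised on a shared scale (see
    :func:`joint_normalise`); aa is true when the apical window mean
    exceeds the basal window mean by more than ``margin``.
    """
    if apical.normalised is None or basal.normalised is None:
        joint_normalise(apical, basal)
    am = apical.normalised[apical.window_mask(oft_window)]
    bm = basal.normalised[basal.window_mask(oft_window)]
    if am.size == 0 or bm.size == 0:
        raise ValueError("empty OFT window")
    a_mean, b_mean = float(am.mean()), float(bm.mean())
    return AccumulationCall(
        heart_id=heart_id,
        channel=channel,
        region=region,
        aa=(a_mean - b_mean) > margin,
        margin_used=margin,
        apical_mean=a_mean,
        basal_mean=b_mean,
    )


def ventricular_mean_intensity(
    channel: PixelGrid,
    ventricle_mask: np.ndarray,
    background_mask: np.ndarray,
) -> float:
    """Background-subtracted mean intensity scaled by ventricle size.

    ``(mean within ROI − mean within background) / ROI area (µm²)``.
    Cohort normalisation (divide by the cohort average) is applied by
    :func:`normalise_cohort`.
    """
    vm = np.asarray(ventricle_mask, dtype=bool)
    bm = np.asarray(background_mask, dtype=bool)
    if vm.shape != channel.shape or bm.shape != channel.shape:
        raise InputError("ROI masks must match the channel shape")
    if not vm.any() or not bm.any():
        raise InputError("empty ROI")
    if (vm & bm).any():
        raise InputError("ventricle and background ROIs overlap")
    vals = channel.values.astype(float)
    area = float(vm.sum()) * channel.pixel_size**2
    return (float(vals[vm].mean()) - float(vals[bm].mean())) / area


def normalise_cohort(values: Sequence[float]) -> np.ndarray:
    """Divide per-heart values by the cohort mean (total-average normalisation)."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        raise ValueError("cohort mean is zero; cannot normalise")
    return v / m


def _disc_mean(values: np.ndarray, px: float, center_um, radius_um: float) -> float:
    cx, cy = np.asarray(center_um, dtype=float)
    h, w = values.shape
    r_px = radius_um / px
    i0 = max(int((cy / px - 0.5) - r_px) - 1, 0)
    i1 = min(int((cy / px - 0.5) + r_px) + 2, h)
    j0 = max(int((cx / px - 0.5) - r_px) - 1, 0)
    j1 = min(int((cx / px - 0.5) + r_px) + 2, w)
    if i0 >= i1 or j0 >= j1:
        raise InputError("transition state lies outside the raster")
    ii, jj = np.mgrid[i0:i1, j0:j1]
    xs = (jj + 0.5) * px
    ys = (ii + 0.5) * px
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_um**2
    if not mask.any():
        raise InputError("transition-state disc contains no pixels")
    return float(values[i0:i1, j0:j1][mask].mean())


def colocalisation_at_ts(
    ts_list: Sequence[TransitionState],
    chan_a: PixelGrid,
    chan_b: PixelGrid,
    background_mask: np.ndarray,
    radius_um: float = 1.5,
    k_sigma: float = 2.0,
) -> ColocTable:
    """Two-channel presence and co-localisation at transition states.

    A channel is present at a transition state when the mean intensity in a
    disc of ``radius_um`` around the vertex exceeds the channel's
    background mean + ``k_sigma``·s.d.  Co-localised means present in both.
    """
    if chan_a.shape != chan_b.shape or chan_a.pixel_size != chan_b.pixel_size:
        raise InputError("channels are not co-registered")
    bm = np.asarray(background_mask, dtype=bool)
    if bm.shape != chan_a.shape or not bm.any():
        raise InputError("invalid background mask")
    rows = []
    thresholds = {}
    for name, ch in (("A", chan_a), ("B", chan_b)):
        vals = ch.values.astype(float)
        thresholds[name] = vals[bm].mean() + k_sigma * vals[bm].std()
    for i, ts in enumerate(ts_list):
        pa = _disc_mean(chan_a.values.astype(float), chan_a.pixel_size, ts.position, radius_um)
        pb = _disc_mean(chan_b.values.astype(float), chan_b.pixel_size, ts.position, radius_um)
        rows.append(
            dict(
                ts_id=i,
                presence_A=bool(pa > thresholds["A"]),
                presence_B=bool(pb > thresholds["B"]),
            )
        )
    df = pd.DataFrame(rows, columns=["ts_id", "presence_A", "presence_B"])
    n_coloc = int((df["presence_A"] & df["presence_B"]).sum()) if len(df) else 0
    return ColocTable(records=df, n_total=len(df), n_coloc=n_coloc)
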