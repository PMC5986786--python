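"""Axial circular statistics: mean axis, concentration, Rayleigh test.

Cell orientation axes are *axial* data — θ and θ+180° are the same axis —
so all statistics double the angles first (Davis's method for axial data)
and halve the resulting mean direction.  The Rayleigh statistic is
``Z = n·R̄²`` where R̄ is the mean resultant length of the doubled unit
vectors; the p-value uses the classical series approximation

    p ≈ exp(−Z)·[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)]

clamped to (0, 1].  Reported values R̄, Z and p are always separate named
fields — a bare "Rayleigh's R" is ambiguous between a concentration measure
and a p-value, so this package never prints one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._geometry import fold_axial_deg

__all__ = [
    "CircularSummary",
    "axial_summary",
    "rayleigh_p_series",
    "rayleigh_p_montecarlo",
    "region_angle_report",
]

_P_FLOOR = 1e-300


@dataclass
class CircularSummary:
    n: int
    mean_axis_deg: float  # [0, 180); NaN when R_bar ~ 0
    mean_axis_pm90: float  # same axis on the ±90° scale
    R_bar: float  # mean resultant length of doubled angles, [0, 1]
    circ_variance: float  # 1 − R_bar
    rayleigh_Z: float  # n · R_bar²
    rayleigh_p: float  # in (0, 1]
    n_excluded: int = 0  # NaN angles dropped before analysis


def rayleigh_p_series(Z: float, n: int) -> float:
    """Series approximation of the Rayleigh-test p-value."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = math.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    return min(1.0, max(_P_FLOOR, p))


def rayleigh_p_montecarlo(Z: float, n: int, n_sim: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo p-value for Z = n·R̄² under circular uniformity."""
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0.0, 2.0 * np.pi, size=(n_sim, n))
    c = np.cos(ang).sum(axis=1)
    s = np.sin(ang).sum(axis=1)
    z_null = (c * c + s * s) / n
    return float((np.sum(z_null >= Z) + 1) / (n_sim + 1))


def axial_summary(angles_deg, eps: float = 1e-12) -> CircularSummary:
    """Axial circular summary of angles in degrees (any 180°-periodic scale).

    NaN entries are excluded and counted in ``n_excluded``.  With R̄ below
    ``eps`` (e.g. equal masses at 0° and 90°) the mean axis is undefined
    and reported as NaN.
    """
    a = np.asarray(angles_deg, dtype=float).ravel()
    excluded = int(np.isnan(a).sum())
    a = a[~np.isnan(a)]
    n = a.size
    if n == 0:
        raise ValueError("no finite angles to summarise")
    phi = np.radians(2.0 * a)
    C = float(np.cos(phi).sum())
    S = float(np.sin(phi).sum())
    R_bar = math.hypot(C, S) / n
    Z = n * R_bar * R_bar
    p = rayleigh_p_series(Z, n)
    if R_bar > eps:
        mean_axis = math.degrees(0.5 * math.atan2(S, C)) % 180.0
        alias = fold_axial_deg(mean_axis)
    else:
        mean_axis = float("nan")
        alias = float("nan")
    return CircularSummary(
        n=n,
        mean_axis_deg=mean_axis,
        mean_axis_pm90=alias,
        R_bar=R_bar,
        circ_variance=1.0 - R_bar,
        rayleigh_Z=Z,
        rayleigh_p=p,
        n_excluded=excluded,
    )


def region_angle_report(
    angles_by_region: Mapping[str, Iterable[float]] | pd.DataFrame,
    min_n: int = 5,
) -> pd.DataFrame:
    """Axial summary per region.

    Accepts either ``{region: angles}`` or a DataFrame with ``region`` and
    ``angle_deg`` columns.  Regions with fewer than ``min_n`` angles are
    kept but flagged ``low_n``.
    """
    if isinstance(angles_by_region, pd.DataFrame):
        groups = {
            str(r): g["angle_deg"].to_numpy()
            for r, g in angles_by_region.groupby("region", sort=True)
        }
    else:
        groups = {str(r): np.asarray(list(v), dtype=float) for r, v in angles_by_region.items()}
    rows = []
    for region in sorted(groups):
        vals = np.asarray(groups[region], dtype=float)
        if np.isnan(vals).all() or vals.size == 0:
            continue
        s = axial_summary(vals)
        rows.append(
            dict(
                region=region,
                n=s.n,
                mean_axis_deg=s.mean_axis_deg,
                mean_axis_pm90=s.mean_axis_pm90,
                R_bar=s.R_bar,
                circ_variance=s.circ_variance,
                rayleigh_Z=s.rayleigh_Z,
                rayleigh_p=s.rayleigh_p,
                n_excluded=s.n_excluded,
                low_n=s.n < min_n,
            )
        )
    return pd.DataFrame(rows)
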