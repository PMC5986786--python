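"""Transition-state detection and frequency per 100 cells.

A transition state is a junction vertex where four or more cells share a
single boundary point: the T1 configuration (order 4) or a rosette
(order > 4) — the intermediates of cell neighbour exchange.  Frequencies
are reported per 100 cells; by default, cells on the tissue rim or image
edge are excluded from the denominator (their junctions are partly outside
the imaged field) and transition states all of whose incident cells are
rim cells are excluded from the numerator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mesh import CellMesh, JunctionVertex

__all__ = [
    "TransitionState",
    "TransitionSummary",
    "detect_transition_states",
    "ts_frequency",
    "group_anova",
]

_F_CAP = 1e12


@dataclass
class TransitionState:
    vertex: JunctionVertex
    position: np.ndarray
    order: int
    kind: str  # "T1" for order 4, "rosette" for order > 4

    @classmethod
    def from_vertex(cls, v: JunctionVertex) -> "TransitionState":
        return cls(
            vertex=v,
            position=np.asarray(v.position, dtype=float),
            order=v.order,
            kind="T1" if v.order == 4 else "rosette",
        )


@dataclass
class TransitionSummary:
    n_cells_counted: int
    n_ts: int
    ts_per_100: float
    by_kind: dict[str, int] = field(default_factory=dict)
    exclude_boundary_cells: bool = True


def detect_transition_states(mesh: CellMesh, min_order: int = 4) -> list[TransitionState]:
    """All junction vertices of order >= ``min_order``, in deterministic
    (lexicographic position) order."""
    if min_order < 4:
        raise ValueError("transition states require min_order >= 4")
    return [TransitionState.from_vertex(v) for v in mesh.vertices_of_order(min_order)]


def ts_frequency(mesh: CellMesh, exclude_boundary_cells: bool = True) -> TransitionSummary:
    """Transition states per 100 cells.

    With ``exclude_boundary_cells`` (the default) rim/edge cells do not
    count toward the denominator, and a transition state is counted only if
    at least one of its incident cells is a non-rim cell.
    """
    ts = detect_transition_states(mesh)
    if exclude_boundary_cells:
        interior = {c.id for c in mesh.cells if not c.is_boundary}
        n_cells = len(interior)
        ts = [t for t in ts if t.vertex.incident_cells & interior]
    else:
        n_cells = mesh.n_cells
    if n_cells == 0:
        raise ValueError("no countable cells (all excluded as boundary cells?)")
    by_kind: dict[str, int] = {}
    for t in ts:
        by_kind[t.kind] = by_kind.get(t.kind, 0) + 1
    return TransitionSummary(
        n_cells_counted=n_cells,
        n_ts=len(ts),
        ts_per_100=100.0 * len(ts) / n_cells,
        by_kind=by_kind,
        exclude_boundary_cells=exclude_boundary_cells,
    )


def ts_table(ts_list: Sequence[TransitionState]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(ts_id=i, x_um=t.position[0], y_um=t.position[1], order=t.order, kind=t.kind)
            for i, t in enumerate(ts_list)
        ]
    )


def group_anova(freqs_by_group: Mapping[str, Iterable[float]]):
    """Textbook one-way ANOVA with Bonferroni-adjusted pairwise comparisons.

    Pairwise tests use the pooled within-group mean square (the classical
    multiple-comparison construction); adjusted p = min(1, p·m) over the
    m = k(k−1)/2 pairs.  Returns ``(F, p, pairwise)`` where ``pairwise`` is
    a DataFrame with one row per group pair.
    """
    from scipy import stats

    groups = {str(k): np.asarray(list(v), dtype=float) for k, v in freqs_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has n={vals.size} < 2")
    names = sorted(groups)
    k = len(names)
    ns = np.array([groups[g].size for g in names])
    sums = np.array([groups[g].sum() for g in names])
    sumsq = np.array([(groups[g] ** 2).sum() for g in names])
    n_tot = int(ns.sum())
    grand = sums.sum()
    ss_total = sumsq.sum() - grand**2 / n_tot
    ss_between = float(np.sum(sums**2 / ns) - grand**2 / n_tot)
    ss_within = ss_total - ss_between
    df_b, df_w = k - 1, n_tot - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w if df_w > 0 else 0.0
    if ms_w <= 0:
        F = 0.0 if ms_b <= 0 else _F_CAP
        p = 1.0 if ms_b <= 0 else float(stats.f.sf(_F_CAP, df_b, max(df_w, 1)))
    else:
        F = float(ms_b / ms_w)
        p = float(stats.f.sf(F, df_b, df_w))
    m = k * (k - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        if ms_w <= 0:
            equal = np.isclose(groups[a].mean(), groups[b].mean())
            t_ab = 0.0 if equal else np.inf
            p_raw = 1.0 if equal else 0.0
        else:
            se = np.sqrt(ms_w * (1.0 / groups[a].size + 1.0 / groups[b].size))
            t_ab = float((groups[a].mean() - groups[b].mean()) / se)
            p_raw = float(2.0 * stats.t.sf(abs(t_ab), df_w))
        rows.append(
            dict(
                group_a=a,
                group_b=b,
                t=t_ab,
                p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * m),
            )
        )
    return F, p, pd.DataFrame(rows)
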