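"""Nearest-neighbour analyses: KMT minus-end branching and MT–MT proximity.

Distances are segment-exact (point to the polyline's segments, not to its
vertices), so results do not depend on the resampling density near the
detection thresholds.  A cKDTree over all track points prefilters candidate
neighbours; the prefilter radius includes the longest segment in the graph,
which guarantees that no polyline within the threshold can be missed, and
every candidate is then confirmed with the exact distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .graph_model import Microtubule, MTClass, Spindle
from .metrics import MetricTable

__all__ = [
    "InteractionRecord",
    "point_to_polyline_distance",
    "detect_kmt_branching",
    "detect_mt_interactions",
    "branching_table",
    "interactions_table",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One detected branching or proximity event.

    ``source_position`` is the arc-length position (nm) on the source
    microtubule where the event occurs; ``interaction_length`` is the
    source-side arc extent of a proximity run (None for branch events).
    """

    kind: str  # 'branch' | 'proximity'
    source_mt: int
    target_mt: int
    distance: float
    source_position: float
    interaction_length: Optional[float] = None
    target_class: Optional[str] = None


def _segments_of(points: np.ndarray):
    a = points[:-1]
    b = points[1:]
    return a, b - a


def point_to_polyline_distance(p, mt) -> tuple[float, float]:
    """Exact minimum distance from a point to a polyline.

    Returns ``(distance_nm, foot_arc_nm)`` where the foot position is the
    arc length from the polyline start to the nearest point on it.
    """
    pts = np.asarray(getattr(mt, "points", mt), float)
    p = np.asarray(p, float)
    a, d = _segments_of(pts)
    dd = np.einsum("ij,ij->i", d, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.einsum("ij,ij->i", p - a, d) / dd
    t = np.clip(np.nan_to_num(t), 0.0, 1.0)
    feet = a + t[:, None] * d
    dist = np.linalg.norm(feet - p, axis=1)
    i = int(np.argmin(dist))
    seg_len = np.sqrt(dd)
    arc_start = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]
    return float(dist[i]), float(arc_start[i] + t[i] * seg_len[i])


def _points_to_polyline_distances(P: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Exact distances from each row of P (m,3) to a polyline (n,3)."""
    a, d = _segments_of(pts)
    dd = np.einsum("ij,ij->i", d, d)
    dd_safe = np.where(dd == 0, 1.0, dd)
    # (m, n_seg) projection parameters
    t = np.einsum("mj,nj->mn", P, d) - np.einsum("nj,nj->n", a, d)
    t = np.clip(t / dd_safe, 0.0, 1.0)
    feet = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(feet - P[:, None, :], axis=2)
    return dist.min(axis=1)


class _GraphIndex:
    """cKDTree over all track points with per-point MT ownership."""

    def __init__(self, mts: list[Microtubule]):
        self.mts = mts
        pts = [m.points for m in mts]
        self.owner = np.concatenate(
            [np.full(len(m.points), i) for i, m in enumerate(mts)]
        ) if mts else np.zeros(0, int)
        self.all_points = np.vstack(pts) if pts else np.zeros((0, 3))
        self.tree = cKDTree(self.all_points) if len(self.all_points) else None
        self.max_seg = max(
            (float(np.linalg.norm(np.diff(m.points, axis=0), axis=1).max()) for m in mts),
            default=0.0,
        )

    def candidates_near(self, p: np.ndarray, radius: float) -> set[int]:
        if self.tree is None:
            return set()
        idx = self.tree.query_ball_point(p, radius)
        return set(int(self.owner[i]) for i in idx)


def detect_kmt_branching(
    spindle: Spindle,
    threshold: float = 25.0,
    exclude_same_fiber: bool = False,
) -> list[InteractionRecord]:
    """Find KMT minus-ends lying within ``threshold`` nm of another track.

    For every KMT minus-end the closest other microtubule (segment-exact) is
    located; a branch record is emitted iff that distance is at most the
    threshold — at most one record per KMT.  Ties on distance are broken
    toward the lower microtubule id.  The source itself is always excluded;
    members of the same k-fiber optionally so.
    """
    mts = spindle.microtubules
    index = _GraphIndex(mts)
    radius = threshold + index.max_seg
    id_to_pos = {m.mt_id: i for i, m in enumerate(mts)}
    records = []
    for m in mts:
        if m.mt_class is not MTClass.KMT or m.plus_end_index is None:
            continue
        p = m.minus_end
        best: tuple[float, int, float] | None = None  # (distance, target_id, foot)
        for ci in sorted(index.candidates_near(p, radius)):
            target = mts[ci]
            if target.mt_id == m.mt_id:
                continue
            if (
                exclude_same_fiber
                and m.fiber_id is not None
                and target.fiber_id == m.fiber_id
            ):
                continue
            dist, _foot = point_to_polyline_distance(p, target)
            if best is None or dist < best[0] - 1e-12 or (
                abs(dist - best[0]) <= 1e-12 and target.mt_id < best[1]
            ):
                best = (dist, target.mt_id, _foot)
        if best is not None and best[0] <= threshold:
            target = mts[id_to_pos[best[1]]]
            minus_arc = 0.0 if m.plus_end_index == "last" else m.length
            records.append(
                InteractionRecord(
                    kind="branch",
                    source_mt=m.mt_id,
                    target_mt=best[1],
                    distance=best[0],
                    source_position=minus_arc,
                    target_class=target.mt_class.value,
                )
            )
    return records


def detect_mt_interactions(spindle: Spindle, threshold: float = 100.0) -> list[InteractionRecord]:
    """Map microtubule–microtubule proximity within ``threshold`` nm.

    For every ordered pair (source, target) whose tracks approach within the
    threshold, the source's sample points are tested against the target
    polyline (segment-exact); each maximal contiguous run of in-threshold
    sample points yields one record whose position is the run's starting arc
    length and whose length is the run's arc extent.  The relation is
    symmetric at the pair level: both directions are reported.
    """
    mts = spindle.microtubules
    index = _GraphIndex(mts)
    if index.tree is None:
        return []
    radius = threshold + index.max_seg
    pairs = set()
    for i, j in index.tree.query_pairs(radius):
        oi, oj = int(index.owner[i]), int(index.owner[j])
        if oi != oj:
            pairs.add((min(oi, oj), max(oi, oj)))
    records = []
    for oi, oj in sorted(pairs):
        for src_i, tgt_i in ((oi, oj), (oj, oi)):
            src, tgt = mts[src_i], mts[tgt_i]
            dist = _points_to_polyline_distances(src.points, tgt.points)
            mask = dist <= threshold
            if not mask.any():
                continue
            arc = src.arc_positions()
            # maximal contiguous runs of in-threshold sample points
            edges = np.diff(mask.astype(int))
            starts = list(np.nonzero(edges == 1)[0] + 1)
            ends = list(np.nonzero(edges == -1)[0])
            if mask[0]:
                starts.insert(0, 0)
            if mask[-1]:
                ends.append(len(mask) - 1)
            for s, e in zip(starts, ends):
                records.append(
                    InteractionRecord(
                        kind="proximity",
                        source_mt=src.mt_id,
                        target_mt=tgt.mt_id,
                        distance=float(dist[s : e + 1].min()),
                        source_position=float(arc[s]),
                        interaction_length=float(arc[e] - arc[s]),
                        target_class=tgt.mt_class.value,
                    )
                )
    return records


def branching_table(spindle: Spindle, records: list[InteractionRecord]) -> MetricTable:
    rows = [
        {
            "graph_id": spindle.graph_id,
            "kmt_id": r.source_mt,
            "target_mt_id": r.target_mt,
            "target_class": r.target_class,
            "distance_nm": r.distance,
            "source_position_nm": r.source_position,
        }
        for r in records
    ]
    return MetricTable(
        "branching",
        pd.DataFrame(rows, columns=["graph_id", "kmt_id", "target_mt_id", "target_class", "distance_nm", "source_position_nm"]),
    )


def interactions_table(spindle: Spindle, records: list[InteractionRecord]) -> MetricTable:
    rows = [
        {
            "graph_id": spindle.graph_id,
            "source_mt_id": r.source_mt,
            "target_mt_id": r.target_mt,
            "target_class": r.target_class,
            "min_distance_nm": r.distance,
            "source_position_nm": r.source_position,
            "interaction_length_nm": r.interaction_length,
        }
        for r in records
    ]
    return MetricTable(
        "interactions",
        pd.DataFrame(rows, columns=["graph_id", "source_mt_id", "target_mt_id", "target_class", "min_distance_nm", "source_position_nm", "interaction_length_nm"]),
    )
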