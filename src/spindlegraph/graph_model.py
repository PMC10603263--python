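"""Spindle data model and pre-processing.

A segmented spindle arrives as a set of 3D polylines (microtubule tracks)
with per-edge labels.  Before any geometry is measured the model is
standardized:

* every track is resampled to a uniform arc-length spacing (default 20 nm),
* the whole spindle is rigidly re-oriented so the pole-to-pole axis lies on a
  coordinate axis (default +z, which makes both poles share the two off-axis
  coordinates),
* each kinetochore microtubule (KMT) gets plus/minus end designations
  (plus-end = the end farther from its pole along the spindle axis; in the
  source biology KMT plus-ends terminate at kinetochores),
* KMTs sharing a k-fiber label are bundled into :class:`KFiber` objects with
  a center curve sampled at the twist step, and
* sister k-fibers are paired across the equator by mutual-nearest plus-end
  centroids with an antiparallel direction gate.

All coordinates are in nanometres internally.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

from .amira_io import SpatialGraph
from .errors import GeometryError

__all__ = [
    "MTClass",
    "Microtubule",
    "KFiber",
    "Spindle",
    "resample_uniform",
    "reorient_to_axis",
    "infer_plus_minus_ends",
    "build_kfibers",
    "pair_sister_kfibers",
    "estimate_poles",
    "transform_rigid",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

_graph_counter = itertools.count(1)


class MTClass(str, Enum):
    KMT = "KMT"
    NON_KMT = "nonKMT"


@dataclass
class Microtubule:
    """One ordered 3D polyline with identity and class.

    ``points`` is an (n, 3) float array in nm; the first and last rows are
    the two physical ends of the track.
    """

    mt_id: int
    points: np.ndarray
    mt_class: MTClass = MTClass.NON_KMT
    plus_end_index: Optional[str] = None  # 'first' | 'last'
    fiber_id: Optional[int] = None
    pole_id: Optional[int] = None  # 1 | 2
    end_tie: bool = False
    degenerate: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise GeometryError(f"microtubule {self.mt_id}: points must be (n, 3)")
        if len(self.points) < 2:
            raise GeometryError(f"microtubule {self.mt_id}: needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise GeometryError(f"microtubule {self.mt_id}: non-finite coordinates")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length at each point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def plus_end(self) -> np.ndarray:
        if self.plus_end_index is None:
            raise GeometryError(f"microtubule {self.mt_id}: plus end not assigned")
        return self.points[0] if self.plus_end_index == "first" else self.points[-1]

    @property
    def minus_end(self) -> np.ndarray:
        if self.plus_end_index is None:
            raise GeometryError(f"microtubule {self.mt_id}: plus end not assigned")
        return self.points[-1] if self.plus_end_index == "first" else self.points[0]

    def oriented_points(self) -> np.ndarray:
        """Points ordered from the plus end toward the minus end."""
        if self.plus_end_index == "last":
            return self.points[::-1]
        return self.points


@dataclass
class KFiber:
    """A bundle of KMTs attached to one kinetochore.

    ``center_curve`` is the mean track of the member KMTs; for fibers with at
    least two members it is sampled at the twist step (arc length from the
    plus end), for a single-member fiber it is that KMT's own track.
    ``step_samples[m, k]`` is member m's 3D sample at step k (NaN where the
    member does not reach that step).
    """

    fiber_id: int
    kmt_ids: list[int]
    center_curve: np.ndarray
    step_centers: np.ndarray
    step_arc: np.ndarray
    step_samples: np.ndarray
    plus_end_centroid: np.ndarray
    pole_id: Optional[int] = None
    sister_fiber_id: Optional[int] = None

    @property
    def n_kmts(self) -> int:
        return len(self.kmt_ids)


@dataclass
class Spindle:
    """The whole annotated filament model of one spatial graph."""

    graph_id: int
    microtubules: list[Microtubule]
    fibers: dict[int, KFiber] = field(default_factory=dict)
    pole1: Optional[np.ndarray] = None
    pole2: Optional[np.ndarray] = None
    resample_spacing: float = 20.0
    warnings_log: list[str] = field(default_factory=list)

    @property
    def axis_unit(self) -> np.ndarray:
        """Unit vector pole1 -> pole2."""
        if self.pole1 is None or self.pole2 is None:
            raise GeometryError("spindle poles are not set")
        d = np.asarray(self.pole2, float) - np.asarray(self.pole1, float)
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("spindle poles coincide")
        return d / n

    def mt_by_id(self, mt_id: int) -> Microtubule:
        for mt in self.microtubules:
            if mt.mt_id == mt_id:
                return mt
        raise KeyError(mt_id)

    def kmts(self) -> list[Microtubule]:
        return [m for m in self.microtubules if m.mt_class is MTClass.KMT]

    def non_kmts(self) -> list[Microtubule]:
        return [m for m in self.microtubules if m.mt_class is not MTClass.KMT]

    def warn(self, message: str) -> None:
        self.warnings_log.append(message)
        warnings.warn(message, stacklevel=2)

    # ------------------------------------------------------------------
    # conversion to/from the on-disk document
    # ------------------------------------------------------------------
    @classmethod
    def from_spatial_graph(
        cls,
        graph: SpatialGraph,
        graph_id: Optional[int] = None,
        kmt_label: str = "KMT",
        kmt_aliases: tuple[str, ...] = (),
        fiber_label: str = "KFiberID",
        units: str = "nm",
    ) -> "Spindle":
        """Build a Spindle from a parsed document.

        Each edge becomes one microtubule with a unique id (its edge index).
        An edge is a KMT iff its ``kmt_label`` field (or an alias) is nonzero;
        a positive ``fiber_label`` value assigns it to that k-fiber.  Missing
        KMT label -> all edges classified non-KMT, with a warning.
        """
        if units not in ("nm", "um", "µm"):
            raise ValueError(f"unknown units {units!r} (expected 'nm' or 'um')")
        scale = 1.0 if units == "nm" else 1000.0

        label_field = None
        for name in (kmt_label, *kmt_aliases):
            if name in graph.edge_labels:
                label_field = name
                break

        spindle = cls(
            graph_id=graph_id if graph_id is not None else next(_graph_counter),
            microtubules=[],
        )
        if label_field is None:
            spindle.warn(
                f"no {kmt_label!r} label field in the spatial graph; all "
                "microtubules classified as non-KMT"
            )
        kmt_values = graph.edge_labels.get(label_field) if label_field else None
        fiber_values = graph.edge_labels.get(fiber_label)

        offsets = graph.point_offsets()
        for i in range(graph.n_edges):
            pts = graph.points[offsets[i] : offsets[i] + int(graph.num_points[i])] * scale
            is_kmt = bool(kmt_values is not None and kmt_values[i] != 0)
            fid = None
            if fiber_values is not None and fiber_values[i] > 0:
                fid = int(fiber_values[i])
            spindle.microtubules.append(
                Microtubule(
                    mt_id=i,
                    points=pts.copy(),
                    mt_class=MTClass.KMT if is_kmt else MTClass.NON_KMT,
                    fiber_id=fid if is_kmt else None,
                )
            )
        p1, p2 = graph.pole_coordinates()
        spindle.pole1 = p1 * scale if p1 is not None else None
        spindle.pole2 = p2 * scale if p2 is not None else None
        return spindle

    def to_spatial_graph(self) -> SpatialGraph:
        """Serialize back to a document (vertices = track endpoints)."""
        vertices = []
        edges = []
        num_points = []
        points = []
        kmt = []
        fiber = []
        for mt in self.microtubules:
            edges.append([len(vertices), len(vertices) + 1])
            vertices.append(mt.points[0])
            vertices.append(mt.points[-1])
            num_points.append(len(mt.points))
            points.append(mt.points)
            kmt.append(1 if mt.mt_class is MTClass.KMT else 0)
            fiber.append(mt.fiber_id if mt.fiber_id is not None else 0)
        params: dict[str, str] = {"ContentType": "HxSpatialGraph"}
        if self.pole1 is not None and self.pole2 is not None:
            params["SpindlePole1"] = " ".join(repr(float(v)) for v in self.pole1)
            params["SpindlePole2"] = " ".join(repr(float(v)) for v in self.pole2)
        return SpatialGraph(
            vertices=np.array(vertices).reshape(-1, 3),
            edges=np.array(edges, dtype=int).reshape(-1, 2),
            num_points=np.array(num_points, dtype=int),
            points=np.vstack(points) if points else np.zeros((0, 3)),
            edge_labels={"KMT": np.array(kmt, int), "KFiberID": np.array(fiber, int)},
            parameters=params,
        )


# ----------------------------------------------------------------------
# pre-processing operations
# ----------------------------------------------------------------------

def resample_uniform(mt: Microtubule, spacing: float = 20.0) -> Microtubule:
    """Resample a track to uniform arc-length spacing.

    Interior points are spaced exactly ``spacing`` along the original
    polyline; the final interval is whatever remains (<= spacing).  Endpoints
    are preserved exactly and all returned points lie on the original
    polyline.  A track shorter than ``spacing`` collapses to its two
    endpoints and is flagged degenerate.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    arc = mt.arc_positions()
    total = arc[-1]
    if total <= spacing:
        return replace(mt, points=np.array([mt.points[0], mt.points[-1]]), degenerate=True)
    targets = np.arange(0.0, total, spacing)
    if total - targets[-1] < 1e-9:  # avoid a duplicated endpoint
        targets = targets[:-1]
    targets = np.concatenate([targets, [total]])
    new_pts = np.column_stack(
        [np.interp(targets, arc, mt.points[:, k]) for k in range(3)]
    )
    new_pts[0] = mt.points[0]
    new_pts[-1] = mt.points[-1]
    return replace(mt, points=new_pts, degenerate=False)


def resample_spindle(spindle: Spindle, spacing: float = 20.0) -> Spindle:
    """Resample every microtubule; returns a new Spindle."""
    mts = [resample_uniform(m, spacing) for m in spindle.microtubules]
    out = replace(spindle, microtubules=mts, resample_spacing=spacing)
    return out


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation matrix taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    w = np.cross(u, v)
    s = np.linalg.norm(w)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to u
        a = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        a = a - u * np.dot(a, u)
        a /= np.linalg.norm(a)
        return 2.0 * np.outer(a, a) - np.eye(3)
    w = w / s
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def transform_rigid(spindle: Spindle, rotation: np.ndarray, translation: np.ndarray) -> Spindle:
    """Apply ``p -> R p + t`` to every point, pole, and fiber curve."""
    R = np.asarray(rotation, float)
    t = np.asarray(translation, float)

    def tf(pts):
        return pts @ R.T + t

    mts = [replace(m, points=tf(m.points)) for m in spindle.microtubules]
    fibers = {
        fid: replace(
            f,
            center_curve=tf(f.center_curve),
            step_centers=tf(f.step_centers),
            step_samples=np.where(
                np.isnan(f.step_samples), np.nan, f.step_samples @ R.T + t
            ),
            plus_end_centroid=tf(f.plus_end_centroid.reshape(1, 3))[0],
        )
        for fid, f in spindle.fibers.items()
    }
    return replace(
        spindle,
        microtubules=mts,
        fibers=fibers,
        pole1=tf(spindle.pole1.reshape(1, 3))[0] if spindle.pole1 is not None else None,
        pole2=tf(spindle.pole2.reshape(1, 3))[0] if spindle.pole2 is not None else None,
    )


def reorient_to_axis(spindle: Spindle, axis: str = "z") -> Spindle:
    """Rigidly move the spindle so pole1 sits at the origin and the
    pole-to-pole axis lies along ``axis`` (+z by default).

    Afterwards both poles share the two off-axis coordinates (to well below
    1e-6 nm), which is the standardization the downstream axis-referenced
    metrics assume.  A single proper rotation + translation is used, so all
    pairwise distances (and therefore every metric) are preserved; no
    reflection is ever applied, preserving twist handedness.
    """
    if spindle.pole1 is None or spindle.pole2 is None:
        raise GeometryError("cannot reorient: spindle poles are not set")
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of x, y, z (got {axis!r})")
    u = spindle.axis_unit
    e = np.zeros(3)
    e[_AXIS_INDEX[axis]] = 1.0
    R = _rotation_between(u, e)
    t = -R @ np.asarray(spindle.pole1, float)
    return transform_rigid(spindle, R, t)


def estimate_poles(spindle: Spindle) -> Spindle:
    """Estimate pole positions from KMT endpoints when no poles are given.

    The KMT endpoints are projected on their first principal axis; for each
    KMT the end with the more extreme projection is taken as the poleward
    (minus) candidate, and the two hemisphere centroids of those candidates
    become the poles.
    """
    if spindle.pole1 is not None and spindle.pole2 is not None:
        return spindle
    kmts = spindle.kmts()
    if len(kmts) < 2:
        raise GeometryError("cannot estimate poles: fewer than 2 KMTs")
    ends = np.array([[m.points[0], m.points[-1]] for m in kmts])  # (n, 2, 3)
    flat = ends.reshape(-1, 3)
    center = flat.mean(axis=0)
    _, _, vt = np.linalg.svd(flat - center, full_matrices=False)
    axis = vt[0]
    proj = (ends - center) @ axis  # (n, 2)
    pick = np.argmax(np.abs(proj), axis=1)
    minus = ends[np.arange(len(kmts)), pick]
    minus_proj = proj[np.arange(len(kmts)), pick]
    lo = minus[minus_proj < 0]
    hi = minus[minus_proj >= 0]
    if len(lo) == 0 or len(hi) == 0:
        raise GeometryError("cannot estimate poles: all KMT ends fall on one hemisphere")
    return replace(spindle, pole1=lo.mean(axis=0), pole2=hi.mean(axis=0))


def infer_plus_minus_ends(spindle: Spindle) -> Spindle:
    """Assign each KMT a pole and plus/minus end designations.

    A KMT belongs to the pole nearest to either of its ends; its plus end is
    the end farther from that pole along the spindle-axis direction (KMT
    plus-ends terminate at kinetochores, away from the pole).  Exact ties go
    to 'first' and are flagged.
    """
    if spindle.pole1 is None or spindle.pole2 is None:
        raise GeometryError("cannot assign ends: spindle poles are not set")
    p1 = np.asarray(spindle.pole1, float)
    p2 = np.asarray(spindle.pole2, float)
    axis = spindle.axis_unit
    mts = []
    for mt in spindle.microtubules:
        if mt.mt_class is not MTClass.KMT:
            mts.append(mt)
            continue
        first, last = mt.points[0], mt.points[-1]
        d1 = min(np.linalg.norm(first - p1), np.linalg.norm(last - p1))
        d2 = min(np.linalg.norm(first - p2), np.linalg.norm(last - p2))
        pole_id = 1 if d1 <= d2 else 2
        pole = p1 if pole_id == 1 else p2
        direction = axis if pole_id == 1 else -axis
        s_first = float(np.dot(first - pole, direction))
        s_last = float(np.dot(last - pole, direction))
        tie = abs(s_first - s_last) < 1e-9
        plus = "first" if (tie or s_first > s_last) else "last"
        mts.append(replace(mt, pole_id=pole_id, plus_end_index=plus, end_tie=tie))
    return replace(spindle, microtubules=mts)


def build_kfibers(spindle: Spindle, twist_step: float = 500.0) -> Spindle:
    """Group labelled KMTs into k-fibers and derive center curves.

    Each member is sampled at arc-length steps of ``twist_step`` from its
    plus end; the center at step k is the mean over members reaching that
    step, truncated once fewer than two members remain (single-member fibers
    keep their full track as the center curve).  The fiber plus-end centroid
    is the mean of the member plus-end coordinates.
    """
    kmts = [m for m in spindle.kmts() if m.fiber_id is not None]
    if not kmts:
        out = replace(spindle, fibers={})
        out.warnings_log = spindle.warnings_log
        out.warn("no k-fiber membership labels present; fiber-level analyses skipped")
        return out
    groups: dict[int, list[Microtubule]] = {}
    for m in kmts:
        groups.setdefault(m.fiber_id, []).append(m)

    fibers: dict[int, KFiber] = {}
    for fid in sorted(groups):
        members = groups[fid]
        poles = {m.pole_id for m in members}
        if len(poles) > 1:
            raise GeometryError(
                f"k-fiber {fid}: member KMTs disagree on pole association {sorted(poles)}"
            )
        n_steps = max(int(np.floor(m.length / twist_step)) + 1 for m in members)
        samples = np.full((len(members), n_steps, 3), np.nan)
        for mi, m in enumerate(members):
            pts = m.oriented_points()
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            reach = int(np.floor(arc[-1] / twist_step)) + 1
            targets = np.arange(reach) * twist_step
            samples[mi, :reach] = np.column_stack(
                [np.interp(targets, arc, pts[:, k]) for k in range(3)]
            )
        counts = np.sum(~np.isnan(samples[:, :, 0]), axis=0)
        min_members = 2 if len(members) >= 2 else 1
        valid = counts >= min_members
        if not valid[0]:
            cut = 0
        else:
            bad = np.nonzero(~valid)[0]
            cut = int(bad[0]) if len(bad) else n_steps
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            step_centers = np.nanmean(samples[:, :cut], axis=0)
        step_arc = np.arange(cut) * twist_step
        if len(members) == 1:
            center_curve = members[0].oriented_points().copy()
        else:
            center_curve = step_centers
        plus_centroid = np.mean([m.plus_end for m in members], axis=0)
        fibers[fid] = KFiber(
            fiber_id=fid,
            kmt_ids=[m.mt_id for m in members],
            center_curve=center_curve,
            step_centers=step_centers,
            step_arc=step_arc,
            step_samples=samples[:, :cut],
            plus_end_centroid=plus_centroid,
            pole_id=members[0].pole_id,
        )
    return replace(spindle, fibers=fibers)


def pair_sister_kfibers(spindle: Spindle, cone_deg: float = 60.0) -> Spindle:
    """Pair opposite-pole k-fibers into sisters.

    A pair is accepted iff the two fibers are mutually nearest by plus-end
    centroid distance and their pole-to-centroid directions are antiparallel
    within ``cone_deg``.  Anything else stays unpaired (with a warning only
    when an ambiguity was detected).
    """
    fibers = dict(spindle.fibers)
    if not fibers:
        return spindle
    pole_pos = {1: np.asarray(spindle.pole1, float), 2: np.asarray(spindle.pole2, float)}
    by_pole = {1: [], 2: []}
    for f in fibers.values():
        if f.pole_id in (1, 2):
            by_pole[f.pole_id].append(f)
    cos_gate = -np.cos(np.radians(cone_deg))

    def nearest(f: KFiber, candidates: list[KFiber]) -> Optional[KFiber]:
        if not candidates:
            return None
        d = [np.linalg.norm(f.plus_end_centroid - g.plus_end_centroid) for g in candidates]
        return candidates[int(np.argmin(d))]

    paired: dict[int, int] = {}
    for f in by_pole[1]:
        g = nearest(f, by_pole[2])
        if g is None:
            continue
        back = nearest(g, by_pole[1])
        if back is None or back.fiber_id != f.fiber_id:
            continue
        df = f.plus_end_centroid - pole_pos[f.pole_id]
        dg = g.plus_end_centroid - pole_pos[g.pole_id]
        nf, ng = np.linalg.norm(df), np.linalg.norm(dg)
        if nf == 0 or ng == 0:
            continue
        if float(np.dot(df, dg)) / (nf * ng) <= cos_gate:
            paired[f.fiber_id] = g.fiber_id
            paired[g.fiber_id] = f.fiber_id

    new_fibers = {
        fid: replace(f, sister_fiber_id=paired.get(fid)) for fid, f in fibers.items()
    }
    return replace(spindle, fibers=new_fibers)


def preprocess(
    spindle: Spindle,
    spacing: float = 20.0,
    axis: str = "z",
    twist_step: float = 500.0,
    sister_cone_deg: float = 60.0,
) -> Spindle:
    """Full standardization pipeline: resample, poles, reorient, ends,
    fibers, sisters."""
    s = resample_spindle(spindle, spacing)
    if s.pole1 is None or s.pole2 is None:
        s = estimate_poles(s)
    s = reorient_to_axis(s, axis=axis)
    s = infer_plus_minus_ends(s)
    s = build_kfibers(s, twist_step=twist_step)
    s = pair_sister_kfibers(s, cone_deg=sister_cone_deg)
    return s
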