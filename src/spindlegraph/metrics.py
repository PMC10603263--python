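"""Scalar and profile statistics of spindle microtubules and k-fibers.

Implemented measures
--------------------
length
    Arc length of a track: the sum of Euclidean distances between
    consecutive points.
tortuosity
    Ratio of arc length to the straight endpoint distance (chord); 1 for a
    straight line, pi/2 ~ 1.57 for a half-circle.  Local tortuosity is the
    same ratio on sliding arc-length windows.
twist
    Signed per-step rotation (degrees) of each KMT's radial position about
    the k-fiber center, evaluated every ``step`` nm (default 500) of arc from
    the plus end; the fiber-level local twist is the mean over members, the
    total twist their sum along the fiber.  Positive twist is a right-handed
    rotation about the pole1->pole2 direction.
helicity
    Accumulated azimuthal rotation of the fiber center curve about the
    pole-to-pole axis, divided by the center-curve length (degrees/µm).
cross-section area and KMT density
    At each step, member KMTs are intersected with the plane normal to the
    local center-curve tangent, projected to 2D, and the area of their alpha
    shape is computed (alpha_radius=inf reproduces the convex hull).
    Density is the member count in the plane divided by that area.
outer-kinetochore distance / KMT-number statistics
    Distances between sister plus-end centroids, and descriptive
    correlations of per-fiber KMT counts against spindle-axis position,
    radial offset, sister count, and inter-sister distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy import stats as _stats

from .graph_model import KFiber, Microtubule, MTClass, Spindle

__all__ = [
    "MetricTable",
    "polyline_length",
    "chord_length",
    "tortuosity",
    "local_tortuosity",
    "length_distribution",
    "tortuosity_table",
    "local_twist",
    "total_twist",
    "helicity",
    "alpha_shape_area",
    "fiber_cross_section_area",
    "kmt_density",
    "outer_kinetochore_distance",
    "kmt_number_stats",
]

_EPS_RADIAL = 1e-6  # nm; below this a radial vector is treated as on-axis


@dataclass
class MetricTable:
    """One long-format analysis table (the CSV/XLSX payload)."""

    name: str
    frame: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _points_of(obj) -> np.ndarray:
    pts = getattr(obj, "points", obj)
    return np.asarray(pts, dtype=float)


def polyline_length(mt) -> float:
    """Total track length: sum of consecutive 3D point distances (nm)."""
    pts = _points_of(mt)
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def chord_length(mt) -> float:
    """Straight-line distance between the two track endpoints (nm)."""
    pts = _points_of(mt)
    return float(np.linalg.norm(pts[-1] - pts[0]))


def tortuosity(mt) -> float:
    """Arc length over endpoint chord; >= 1, +inf for a closed curve."""
    L = polyline_length(mt)
    l = chord_length(mt)
    if l == 0:
        return math.inf
    return L / l


def local_tortuosity(mt, window: float = 500.0, stride: float | None = None):
    """Tortuosity on sliding arc-length windows.

    Windows of ``window`` nm start every ``stride`` nm (default: one window
    length, i.e. contiguous non-overlapping windows); each is reported at its
    arc-length center.  Returns ``(centers, values)`` arrays; empty when the
    track is shorter than one window.
    """
    pts = _points_of(mt)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if window <= 0:
        raise ValueError("window must be positive")
    if stride is None:
        stride = window
    starts = np.arange(0.0, total - window + 1e-9, stride)
    centers, values = [], []

    def at(s: float) -> np.ndarray:
        return np.array([np.interp(s, arc, pts[:, k]) for k in range(3)])

    for s0 in starts:
        s1 = s0 + window
        a, b = at(s0), at(s1)
        chord = np.linalg.norm(b - a)
        values.append(math.inf if chord == 0 else window / chord)
        centers.append(s0 + window / 2)
    return np.array(centers), np.array(values)


def length_distribution(spindle: Spindle, mt_class: MTClass | None = MTClass.KMT):
    """Per-microtubule Eq.-style lengths plus mean/median/n summary.

    Returns two tables: ``length`` (one row per microtubule) and
    ``length_summary``.
    """
    mts = spindle.microtubules
    if mt_class is not None:
        mts = [m for m in mts if m.mt_class is mt_class]
    rows = [
        {
            "graph_id": spindle.graph_id,
            "mt_id": m.mt_id,
            "mt_class": m.mt_class.value,
            "fiber_id": m.fiber_id,
            "length_nm": polyline_length(m),
        }
        for m in mts
    ]
    frame = pd.DataFrame(rows, columns=["graph_id", "mt_id", "mt_class", "fiber_id", "length_nm"])
    if frame.empty:
        spindle.warn(f"length_distribution: no microtubules of class {mt_class}")
    summary = {
        "mean_nm": float(frame["length_nm"].mean()) if len(frame) else float("nan"),
        "median_nm": float(frame["length_nm"].median()) if len(frame) else float("nan"),
        "n": int(len(frame)),
    }
    sframe = pd.DataFrame(
        [{"graph_id": spindle.graph_id, "stat": k, "value": v} for k, v in summary.items()]
    )
    return (
        MetricTable("length", frame, summary),
        MetricTable("length_summary", sframe),
    )


def tortuosity_table(spindle: Spindle, window: float = 500.0):
    """Total and local tortuosity for every KMT and every fiber center curve."""
    total_rows, local_rows = [], []

    def add(object_type: str, object_id, obj):
        tau = tortuosity(obj)
        total_rows.append(
            {
                "graph_id": spindle.graph_id,
                "object_type": object_type,
                "object_id": object_id,
                "tortuosity": tau if math.isfinite(tau) else np.nan,
                "closed_curve": not math.isfinite(tau),
            }
        )
        centers, values = local_tortuosity(obj, window=window)
        for c, v in zip(centers, values):
            local_rows.append(
                {
                    "graph_id": spindle.graph_id,
                    "object_type": object_type,
                    "object_id": object_id,
                    "position_nm": c,
                    "tortuosity": v if math.isfinite(v) else np.nan,
                }
            )

    for m in spindle.kmts():
        add("KMT", m.mt_id, m)
    for fid, fib in sorted(spindle.fibers.items()):
        if len(fib.center_curve) >= 2:
            add("k-fiber", fid, fib.center_curve)
    cols = ["graph_id", "object_type", "object_id", "tortuosity", "closed_curve"]
    lcols = ["graph_id", "object_type", "object_id", "position_nm", "tortuosity"]
    return (
        MetricTable("tortuosity", pd.DataFrame(total_rows, columns=cols)),
        MetricTable("local_tortuosity", pd.DataFrame(local_rows, columns=lcols)),
    )


def _signed_angle_deg(v1: np.ndarray, v2: np.ndarray, normal: np.ndarray) -> float:
    """Signed planar angle (deg) from v1 to v2, right-handed about ``normal``."""
    return math.degrees(
        math.atan2(float(np.dot(normal, np.cross(v1, v2))), float(np.dot(v1, v2)))
    )


def _center_tangents(centers: np.ndarray, axis_unit: np.ndarray) -> np.ndarray:
    """Unit tangents of the center curve, oriented along the spindle axis."""
    t = np.gradient(centers, axis=0)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    t = t / norms
    flip = (t @ axis_unit) < 0
    t[flip] *= -1
    return t


def local_twist(fiber: KFiber, axis_unit: np.ndarray, step: float = 500.0):
    """Per-step fiber twist profile.

    For each pair of consecutive steps along the fiber, every member KMT
    contributes the signed angle rotating its radial vector (KMT position
    minus fiber center, projected into the plane normal to the local center
    tangent) from step i to step i+1; the fiber value is the member mean.

    Returns ``(arc_positions, mean_deg, n_contributing)`` arrays of length
    ``n_steps - 1`` (empty for single-step fibers).  Steps where no member
    has a usable radial vector are NaN.
    """
    centers = fiber.step_centers
    samples = fiber.step_samples
    n_steps = len(centers)
    if n_steps < 2:
        return np.array([]), np.array([]), np.array([], dtype=int)
    tangents = _center_tangents(centers, np.asarray(axis_unit, float))
    arc = fiber.step_arc[:-1] + step / 2
    means = np.full(n_steps - 1, np.nan)
    counts = np.zeros(n_steps - 1, dtype=int)
    for k in range(n_steps - 1):
        n = tangents[k] + tangents[k + 1]
        nn = np.linalg.norm(n)
        n = tangents[k] if nn < 1e-12 else n / nn
        # pair the two steps on the members present at both, and center on
        # exactly those members: otherwise a member ending between steps
        # shifts the mean and manufactures twist in a perfectly straight
        # bundle
        present = ~(np.isnan(samples[:, k, 0]) | np.isnan(samples[:, k + 1, 0]))
        if not present.any():
            continue
        c_k = samples[present, k].mean(axis=0)
        c_k1 = samples[present, k + 1].mean(axis=0)
        angles = []
        for mi in np.nonzero(present)[0]:
            p_i, p_j = samples[mi, k], samples[mi, k + 1]
            r_i = p_i - c_k
            r_j = p_j - c_k1
            r_i = r_i - n * np.dot(r_i, n)
            r_j = r_j - n * np.dot(r_j, n)
            if np.linalg.norm(r_i) < _EPS_RADIAL or np.linalg.norm(r_j) < _EPS_RADIAL:
                continue
            angles.append(_signed_angle_deg(r_i, r_j, n))
        if angles:
            means[k] = float(np.mean(angles))
            counts[k] = len(angles)
    return arc, means, counts


def total_twist(fiber: KFiber, axis_unit: np.ndarray, step: float = 500.0) -> float:
    """Sum of the per-step mean twists along the fiber (degrees).

    A randomly zig-zagging fiber cancels toward 0; a coherently twisted one
    accumulates.  NaN steps (no contributing member) are skipped.
    """
    _, means, _ = local_twist(fiber, axis_unit, step=step)
    if len(means) == 0 or np.all(np.isnan(means)):
        return 0.0
    return float(np.nansum(means))


def helicity(fiber: KFiber, pole1: np.ndarray, axis_unit: np.ndarray) -> float:
    """Twist of the fiber center about the pole-to-pole axis per unit length.

    The azimuthal angle of each center-curve point about the spindle axis is
    accumulated (signed, right-handed about pole1->pole2) and divided by the
    center-curve arc length, giving degrees per micrometre.  NaN for fibers
    whose center curve has fewer than two points or lies on the axis.
    """
    curve = np.asarray(fiber.center_curve, float)
    if len(curve) < 2:
        return float("nan")
    pole1 = np.asarray(pole1, float)
    axis_unit = np.asarray(axis_unit, float)
    rel = curve - pole1
    radial = rel - np.outer(rel @ axis_unit, axis_unit)
    norms = np.linalg.norm(radial, axis=1)
    total = 0.0
    any_pair = False
    for k in range(len(curve) - 1):
        if norms[k] < _EPS_RADIAL or norms[k + 1] < _EPS_RADIAL:
            continue
        total += _signed_angle_deg(radial[k], radial[k + 1], axis_unit)
        any_pair = True
    length_um = polyline_length(curve) / 1000.0
    if length_um == 0:
        return float("nan")
    if not any_pair:
        return 0.0
    return total / length_um


def twist_tables(spindle: Spindle, step: float = 500.0):
    """twist_local, twist_total and helicity tables for all fibers."""
    axis = spindle.axis_unit
    local_rows, total_rows, heli_rows = [], [], []
    for fid, fib in sorted(spindle.fibers.items()):
        arc, means, counts = local_twist(fib, axis, step=step)
        for a, v, c in zip(arc, means, counts):
            local_rows.append(
                {
                    "graph_id": spindle.graph_id,
                    "fiber_id": fid,
                    "position_nm": a,
                    "local_twist_deg": v,
                    "n_kmts": c,
                }
            )
        total_rows.append(
            {
                "graph_id": spindle.graph_id,
                "fiber_id": fid,
                "total_twist_deg": total_twist(fib, axis, step=step),
                "n_steps": len(arc),
            }
        )
        heli_rows.append(
            {
                "graph_id": spindle.graph_id,
                "fiber_id": fid,
                "helicity_deg_per_um": helicity(fib, spindle.pole1, axis),
            }
        )
    return (
        MetricTable(
            "twist_local",
            pd.DataFrame(local_rows, columns=["graph_id", "fiber_id", "position_nm", "local_twist_deg", "n_kmts"]),
        ),
        MetricTable(
            "twist_total",
            pd.DataFrame(total_rows, columns=["graph_id", "fiber_id", "total_twist_deg", "n_steps"]),
        ),
        MetricTable(
            "helicity",
            pd.DataFrame(heli_rows, columns=["graph_id", "fiber_id", "helicity_deg_per_um"]),
        ),
    )


def alpha_shape_area(points2d: np.ndarray, alpha_radius: float = math.inf) -> float:
    """Area of the 2D alpha shape of a point set.

    The alpha complex keeps every Delaunay triangle whose circumradius is at
    most ``alpha_radius``; the area is the summed area of kept triangles.
    ``alpha_radius=inf`` keeps all triangles, i.e. the convex-hull area.
    Returns NaN for fewer than 3 points or degenerate (collinear) input.
    """
    pts = np.asarray(points2d, float)
    if len(pts) < 3:
        return float("nan")
    try:
        tri = Delaunay(pts)
    except QhullError:
        return float("nan")
    if len(tri.simplices) == 0:
        return float("nan")
    a = pts[tri.simplices[:, 0]]
    b = pts[tri.simplices[:, 1]]
    c = pts[tri.simplices[:, 2]]
    ab = b - a
    ac = c - a
    areas = 0.5 * np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    if math.isinf(alpha_radius):
        keep = np.ones(len(areas), dtype=bool)
    else:
        la = np.linalg.norm(b - c, axis=1)
        lb = np.linalg.norm(a - c, axis=1)
        lc = np.linalg.norm(a - b, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            circum = la * lb * lc / (4.0 * areas)
        keep = np.isfinite(circum) & (circum <= alpha_radius)
    total = float(areas[keep].sum())
    return total


def _plane_crossings(
    fiber: KFiber,
    spindle: Spindle,
    center: np.ndarray,
    tangent: np.ndarray,
    half_spacing: float,
) -> np.ndarray:
    """Member-KMT intersection points with the plane through ``center``
    normal to ``tangent``.

    Each member contributes the crossing (sign change, linearly interpolated)
    nearest to the fiber center; members merely tangent to the plane
    contribute their nearest point if within ``half_spacing`` of the plane.
    Returns an (m, 3) array.
    """
    hits = []
    for mid in fiber.kmt_ids:
        pts = spindle.mt_by_id(mid).points
        f = (pts - center) @ tangent
        sign_change = np.nonzero(f[:-1] * f[1:] < 0)[0]
        exact = np.nonzero(f == 0)[0]
        candidates = []
        for i in sign_change:
            t = f[i] / (f[i] - f[i + 1])
            candidates.append(pts[i] + t * (pts[i + 1] - pts[i]))
        for i in exact:
            candidates.append(pts[i])
        if not candidates:
            k = int(np.argmin(np.abs(f)))
            if abs(f[k]) <= half_spacing:
                candidates.append(pts[k])
        if candidates:
            d = [np.linalg.norm(c - center) for c in candidates]
            hits.append(candidates[int(np.argmin(d))])
    return np.array(hits).reshape(-1, 3)


def fiber_cross_section_area(
    fiber: KFiber,
    spindle: Spindle,
    step: float = 500.0,
    alpha_radius: float = math.inf,
):
    """Cross-section area profile of a k-fiber.

    At every center-curve step the plane normal to the local tangent is
    intersected with the member KMTs; the intersection points are projected
    into the plane and their alpha-shape area computed.  Positions with
    fewer than 3 intersecting KMTs yield NaN (flagged by the count column).

    Returns ``(positions, areas_nm2, counts)``.
    """
    centers = fiber.step_centers
    if len(centers) == 0:
        return np.array([]), np.array([]), np.array([], dtype=int)
    tangents = _center_tangents(centers, spindle.axis_unit)
    half_spacing = spindle.resample_spacing / 2.0
    areas = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    for k, (c, t) in enumerate(zip(centers, tangents)):
        hits = _plane_crossings(fiber, spindle, c, t, half_spacing)
        counts[k] = len(hits)
        if len(hits) < 3:
            continue
        # orthonormal basis of the plane
        e1 = np.cross(t, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(t, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        rel = hits - c
        areas[k] = alpha_shape_area(
            np.column_stack([rel @ e1, rel @ e2]), alpha_radius
        )
    return fiber.step_arc.copy(), areas, counts


def kmt_density(areas_nm2: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """KMT count per fiber cross-section area, in KMTs per µm²."""
    areas_nm2 = np.asarray(areas_nm2, float)
    counts = np.asarray(counts, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(np.isnan(areas_nm2) | (areas_nm2 == 0), np.nan, counts / areas_nm2 * 1e6)


def area_density_tables(spindle: Spindle, step: float = 500.0, alpha_radius: float = math.inf):
    """fiber_area, fiber_area_total, and kmt_density tables."""
    area_rows, total_rows, dens_rows = [], [], []
    for fid, fib in sorted(spindle.fibers.items()):
        pos, areas, counts = fiber_cross_section_area(
            fib, spindle, step=step, alpha_radius=alpha_radius
        )
        dens = kmt_density(areas, counts)
        for p, a, n, d in zip(pos, areas, counts, dens):
            area_rows.append(
                {"graph_id": spindle.graph_id, "fiber_id": fid, "position_nm": p,
                 "area_nm2": a, "n_kmts": int(n)}
            )
            dens_rows.append(
                {"graph_id": spindle.graph_id, "fiber_id": fid, "position_nm": p,
                 "n_kmts": int(n), "density_per_um2": d}
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_area = float(np.nanmean(areas)) if len(areas) else float("nan")
        total_rows.append(
            {"graph_id": spindle.graph_id, "fiber_id": fid, "mean_area_nm2": mean_area}
        )
    return (
        MetricTable("fiber_area", pd.DataFrame(area_rows, columns=["graph_id", "fiber_id", "position_nm", "area_nm2", "n_kmts"])),
        MetricTable("fiber_area_total", pd.DataFrame(total_rows, columns=["graph_id", "fiber_id", "mean_area_nm2"])),
        MetricTable("kmt_density", pd.DataFrame(dens_rows, columns=["graph_id", "fiber_id", "position_nm", "n_kmts", "density_per_um2"])),
    )


def outer_kinetochore_distance(spindle: Spindle) -> MetricTable:
    """Distance between sister k-fiber plus-end centroids (one row per pair)."""
    rows = []
    seen = set()
    for fid, fib in sorted(spindle.fibers.items()):
        sid = fib.sister_fiber_id
        if sid is None or (sid, fid) in seen:
            continue
        seen.add((fid, sid))
        sister = spindle.fibers[sid]
        rows.append(
            {
                "graph_id": spindle.graph_id,
                "fiber_id": fid,
                "sister_fiber_id": sid,
                "distance_nm": float(
                    np.linalg.norm(fib.plus_end_centroid - sister.plus_end_centroid)
                ),
            }
        )
    frame = pd.DataFrame(rows, columns=["graph_id", "fiber_id", "sister_fiber_id", "distance_nm"])
    if frame.empty and spindle.fibers:
        spindle.warn("outer_kinetochore_distance: no sister pairs found")
    return MetricTable("outer_kinetochore_distance", frame)


def kmt_number_stats(spindle: Spindle):
    """Per-fiber KMT counts vs. position and sister properties.

    Returns the per-fiber table and a correlation table (Pearson and
    Spearman of count vs. each covariate, descriptive, no multiplicity
    correction).  Correlations are NaN below 3 fibers or at zero variance.
    """
    axis = spindle.axis_unit
    p1 = np.asarray(spindle.pole1, float)
    rows = []
    for fid, fib in sorted(spindle.fibers.items()):
        rel = fib.plus_end_centroid - p1
        axial = float(rel @ axis)
        radial = float(np.linalg.norm(rel - axial * axis))
        sister = spindle.fibers.get(fib.sister_fiber_id) if fib.sister_fiber_id else None
        rows.append(
            {
                "graph_id": spindle.graph_id,
                "fiber_id": fid,
                "kmt_count": fib.n_kmts,
                "axial_position_nm": axial,
                "radial_offset_nm": radial,
                "sister_kmt_count": sister.n_kmts if sister else np.nan,
                "inter_sister_distance_nm": float(
                    np.linalg.norm(fib.plus_end_centroid - sister.plus_end_centroid)
                )
                if sister
                else np.nan,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["graph_id", "fiber_id", "kmt_count", "axial_position_nm",
                 "radial_offset_nm", "sister_kmt_count", "inter_sister_distance_nm"],
    )
    corr_rows = []
    covariates = ["axial_position_nm", "radial_offset_nm", "sister_kmt_count",
                  "inter_sister_distance_nm"]
    for cov in covariates:
        sub = frame[["kmt_count", cov]].dropna()
        pearson = spearman = np.nan
        flag = ""
        if len(sub) < 3:
            flag = "fewer than 3 fibers"
        elif sub["kmt_count"].nunique() < 2 or sub[cov].nunique() < 2:
            flag = "zero variance"
        else:
            pearson = float(_stats.pearsonr(sub["kmt_count"], sub[cov]).statistic)
            spearman = float(_stats.spearmanr(sub["kmt_count"], sub[cov]).statistic)
        corr_rows.append(
            {
                "graph_id": spindle.graph_id,
                "covariate": cov,
                "pearson_r": pearson,
                "spearman_r": spearman,
                "n": len(sub),
                "flag": flag,
            }
        )
    return (
        MetricTable("kmt_number", frame),
        MetricTable(
            "kmt_number_correlations",
            pd.DataFrame(corr_rows, columns=["graph_id", "covariate", "pearson_r", "spearman_r", "n", "flag"]),
        ),
    )
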