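"""Ground-truth spindle generator.

Emits valid Amira ASCII spatial graphs with known geometry so every analysis
stage can be tested without microscope data.  The model spindle has two
poles on the z axis, sister k-fibers facing each other across the equator at
a set inter-kinetochore distance, KMT bundles on a circle of the bundle
radius around each kinetochore, optional coherent twist (the whole fiber
cross-section pattern rotates rigidly about the pole-to-pole axis by 360°
per helix pitch of axial distance, so the fiber center curve is an ideal
helix about the spindle axis and every member's radial vector about the
fiber center rotates at the same rate), background non-KMTs, and planted
minus-end branching events.

Geometry is generated at a 100 nm node spacing (the scale of tracing nodes),
then isotropic Gaussian noise is added per node — applying noise at the
final 20 nm resampling scale instead would inflate arc lengths far beyond
tracing jitter.  The ground truth records what is actually true of the
emitted geometry (lengths measured on the noiseless polylines, the branch
events present after a clearance check), so recovery tests compare against
facts, not intentions.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .amira_io import SpatialGraph
from .graph_model import Microtubule, MTClass, Spindle
from .interactions import point_to_polyline_distance

__all__ = ["SpindleRecipe", "GroundTruth", "generate_spindle", "make_half_circle"]

_GEN_SPACING = 100.0  # nm between generated nodes (pre-noise, pre-resampling)


@dataclass
class SpindleRecipe:
    """Parameters of one synthetic spindle.

    Defaults emulate a small metaphase mammalian spindle: ~10 µm pole
    separation, kinetochores on a ~1.5 µm metaphase plate, k-fibers of a few
    µm with KMTs packed ~100 nm around the kinetochore, ~5 nm tracing
    jitter.  ``helix_pitch_um=0`` means untwisted (straight) fibers.
    """

    n_fiber_pairs: int = 4
    kmts_per_fiber: int = 5
    fiber_length_um: tuple[float, float] = (3.5, 0.8)  # mean, sd (truncated normal)
    bundle_radius_nm: float = 100.0
    helix_pitch_um: float = 0.0
    handedness: int = 1  # +1: pattern azimuth increases with z
    n_nonkmt: int = 30
    nonkmt_length_um: tuple[float, float] = (2.0, 0.8)
    n_branch_events: int = 0
    branch_distance_nm: tuple[float, float] = (5.0, 20.0)  # uniform draw range
    branch_clearance_nm: float = 30.0  # non-planted minus-ends stay beyond this
    noise_sigma_nm: float = 5.0
    inter_kinetochore_nm: float = 1000.0
    pole_distance_um: float = 10.0
    plate_radius_nm: float = 1500.0
    plate_z_jitter_nm: float = 0.0
    kmt_count_slope_per_um: float = 0.0
    kmt_count_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_fiber_pairs < 0 or self.kmts_per_fiber < 1 or self.n_nonkmt < 0:
            raise ValueError("counts must be non-negative (and >=1 KMT per fiber)")
        if self.noise_sigma_nm < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class GroundTruth:
    """Everything knowable about a generated spindle."""

    poles: list[list[float]]
    mts: list[dict] = field(default_factory=list)
    fibers: list[dict] = field(default_factory=list)
    sister_pairs: list[list[int]] = field(default_factory=list)
    branches: list[dict] = field(default_factory=list)
    inter_kinetochore_nm: float = 0.0
    mean_kmt_length_nm: float = 0.0
    expected_helicity_deg_per_um: dict = field(default_factory=dict)
    expected_density_per_um2: float = float("nan")
    expected_local_twist_deg: float = 0.0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def make_half_circle(radius: float, n_points: int, mt_id: int = 0) -> Microtubule:
    """A planar semicircle track, uniformly sampled by angle.

    The textbook tortuosity fixture: arc length pi*r over chord 2r gives
    tau = pi/2 ~ 1.57.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    theta = np.linspace(0.0, math.pi, n_points)
    pts = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n_points)]
    )
    return Microtubule(mt_id=mt_id, points=pts, mt_class=MTClass.KMT)


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(200):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


def _helical_track(
    plus_xy: np.ndarray,
    z_plus: float,
    z_direction: float,
    arc_length: float,
    pitch_nm: float,
    handedness: int,
) -> np.ndarray:
    """Generate a track of ``arc_length`` from the plus end poleward.

    The point at axial offset dz is the plus-end position rotated about the
    z axis by ``handedness * 2*pi * (z - z_plus) / pitch``; pitch 0 disables
    rotation.  Points are spaced ~100 nm in arc, ordered plus -> minus.
    """
    rho = float(np.hypot(plus_xy[0], plus_xy[1]))
    if pitch_nm > 0:
        arc_factor = math.sqrt(1.0 + (2.0 * math.pi * rho / pitch_nm) ** 2)
    else:
        arc_factor = 1.0
    axial_extent = arc_length / arc_factor
    n = max(2, int(math.ceil(axial_extent / (_GEN_SPACING / arc_factor))) + 1)
    dz = np.linspace(0.0, axial_extent, n)
    z = z_plus + z_direction * dz
    if pitch_nm > 0:
        alpha = handedness * 2.0 * math.pi * (z - z_plus) / pitch_nm
    else:
        alpha = np.zeros_like(z)
    phi0 = math.atan2(plus_xy[1], plus_xy[0])
    x = rho * np.cos(phi0 + alpha)
    y = rho * np.sin(phi0 + alpha)
    return np.column_stack([x, y, z])


def generate_spindle(recipe: SpindleRecipe) -> tuple[SpatialGraph, GroundTruth]:
    """Generate one spindle and its ground truth.

    Deterministic: the same recipe (including seed) produces byte-identical
    Amira output.  Returns ``(graph, truth)``.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)

    pole_dist = recipe.pole_distance_um * 1000.0
    pole1 = np.array([0.0, 0.0, 0.0])
    pole2 = np.array([0.0, 0.0, pole_dist])
    z_eq = pole_dist / 2.0
    d0 = recipe.inter_kinetochore_nm
    pitch_nm = recipe.helix_pitch_um * 1000.0
    mean_len = recipe.fiber_length_um[0] * 1000.0
    sd_len = recipe.fiber_length_um[1] * 1000.0

    truth = GroundTruth(
        poles=[pole1.tolist(), pole2.tolist()],
        inter_kinetochore_nm=d0,
    )

    tracks: list[np.ndarray] = []  # pre-noise geometry, plus end first
    meta: list[dict] = []

    fiber_id = 0
    for pair in range(recipe.n_fiber_pairs):
        phi = 2.0 * math.pi * pair / max(recipe.n_fiber_pairs, 1)
        rho = recipe.plate_radius_nm
        # bounded (uniform) plate-thickness displacement; an unbounded draw
        # could push a kinetochore past the equator and flip its fibers'
        # pole association
        z_jit = (
            rng.uniform(-recipe.plate_z_jitter_nm, recipe.plate_z_jitter_nm)
            if recipe.plate_z_jitter_nm > 0
            else 0.0
        )
        kx, ky = rho * math.cos(phi), rho * math.sin(phi)
        pair_ids = []
        for pole_id, z_k, z_dir in ((1, z_eq - d0 / 2 + z_jit, -1.0), (2, z_eq + d0 / 2 + z_jit, +1.0)):
            fiber_id += 1
            count = recipe.kmts_per_fiber
            if recipe.kmt_count_slope_per_um != 0 or recipe.kmt_count_noise > 0:
                count = int(
                    round(
                        recipe.kmts_per_fiber
                        + recipe.kmt_count_slope_per_um * (z_k - z_eq) / 1000.0
                        + (rng.normal(0.0, recipe.kmt_count_noise) if recipe.kmt_count_noise > 0 else 0.0)
                    )
                )
                count = max(1, count)
            psi0 = rng.uniform(0.0, 2.0 * math.pi)
            member_ids = []
            for m in range(count):
                psi = psi0 + 2.0 * math.pi * m / count
                plus_xy = np.array(
                    [kx + recipe.bundle_radius_nm * math.cos(psi),
                     ky + recipe.bundle_radius_nm * math.sin(psi)]
                )
                room = (z_k if z_dir < 0 else pole_dist - z_k) - 100.0
                L = _truncnorm(rng, mean_len, sd_len, 600.0, max(700.0, room))
                track = _helical_track(plus_xy, z_k, z_dir, L, pitch_nm, recipe.handedness)
                member_ids.append(len(tracks))
                tracks.append(track)
                meta.append(
                    {"class": "KMT", "fiber": fiber_id, "pole": pole_id, "plus_end": "first"}
                )
            truth.fibers.append(
                {
                    "fiber_id": fiber_id,
                    "pole": pole_id,
                    "kinetochore": [kx, ky, z_k],
                    "kmt_ids": member_ids,
                    "n_kmts": count,
                }
            )
            pair_ids.append(fiber_id)
        truth.sister_pairs.append(pair_ids)

    # background non-KMTs: random chords in the spindle volume
    for _ in range(recipe.n_nonkmt):
        L = _truncnorm(
            rng,
            recipe.nonkmt_length_um[0] * 1000.0,
            recipe.nonkmt_length_um[1] * 1000.0,
            400.0,
            6000.0,
        )
        center = np.array(
            [
                rng.uniform(-1.2, 1.2) * max(recipe.plate_radius_nm, 500.0),
                rng.uniform(-1.2, 1.2) * max(recipe.plate_radius_nm, 500.0),
                rng.uniform(0.15, 0.85) * pole_dist,
            ]
        )
        direction = rng.normal(size=3)
        direction[2] *= 3.0  # bias along the spindle axis
        direction /= np.linalg.norm(direction)
        n = max(2, int(round(L / _GEN_SPACING)) + 1)
        s = np.linspace(-L / 2, L / 2, n)
        tracks.append(center + np.outer(s, direction))
        meta.append({"class": "nonKMT", "fiber": None, "pole": None, "plus_end": None})

    # tracing noise (per generated node)
    if recipe.noise_sigma_nm > 0:
        tracks = [t + rng.normal(0.0, recipe.noise_sigma_nm, t.shape) for t in tracks]

    # plant branch events: move chosen KMT minus-ends next to a nearby track
    kmt_indices = [i for i, m in enumerate(meta) if m["class"] == "KMT"]
    planted: set[int] = set()
    n_plant = min(recipe.n_branch_events, len(kmt_indices))
    candidates_order = list(rng.permutation(kmt_indices))
    for src in candidates_order:
        if len(planted) >= n_plant:
            break
        minus = tracks[src][-1]
        # candidate targets with any node within 1.5 µm of the minus end
        targets = [
            j
            for j in range(len(tracks))
            if j != src
            and np.min(np.linalg.norm(tracks[j] - minus, axis=1)) < 1500.0
        ]
        if not targets:
            continue
        placed = False
        for _ in range(50):
            tgt = int(targets[rng.integers(len(targets))])
            tpts = tracks[tgt]
            if len(tpts) < 4:
                continue
            # only interior segments: a track's terminal node may move later
            # (its own planting, or the clearance pass), which would silently
            # change this event's distance
            seg_i = int(rng.integers(1, len(tpts) - 2))
            a, b = tpts[seg_i], tpts[seg_i + 1]
            u = b - a
            un = np.linalg.norm(u)
            if un == 0:
                continue
            u = u / un
            foot = a + rng.uniform(0.2, 0.8) * un * u
            perp = rng.normal(size=3)
            perp -= u * np.dot(perp, u)
            pn = np.linalg.norm(perp)
            if pn < 1e-9:
                continue
            perp /= pn
            d = rng.uniform(*recipe.branch_distance_nm)
            new_minus = foot + d * perp
            # the intended target must be the unique track inside the clearance
            ok = True
            for j in range(len(tracks)):
                if j == src:
                    continue
                dist_j, _ = point_to_polyline_distance(new_minus, tracks[j])
                if j == tgt:
                    if dist_j > recipe.branch_distance_nm[1] + 1e-6:
                        ok = False
                        break
                elif dist_j <= recipe.branch_clearance_nm:
                    ok = False
                    break
            if ok:
                tracks[src] = np.vstack([tracks[src][:-1], new_minus])
                planted.add(src)
                placed = True
                break
        if not placed:
            continue

    # clearance pass: every *other* KMT minus-end must stay clear of all
    # tracks, so the planted set is exactly the set of true branch events
    for src in kmt_indices:
        if src in planted:
            continue
        minus = tracks[src][-1].copy()
        moved = False
        for _ in range(20):
            worst = None
            for j in range(len(tracks)):
                if j == src:
                    continue
                dist_j, _ = point_to_polyline_distance(minus, tracks[j])
                if worst is None or dist_j < worst[0]:
                    worst = (dist_j, j)
            if worst is None or worst[0] > recipe.branch_clearance_nm:
                break
            # push the minus end away from the nearest node of the offender
            jpts = tracks[worst[1]]
            node = jpts[int(np.argmin(np.linalg.norm(jpts - minus, axis=1)))]
            away = minus - node
            norm = np.linalg.norm(away)
            if norm < 1e-9:
                away = rng.normal(size=3)
                norm = np.linalg.norm(away)
            minus = node + away / norm * (recipe.branch_clearance_nm + 10.0)
            moved = True
        if moved:
            tracks[src] = np.vstack([tracks[src][:-1], minus])

    # final truth: branch records measured on the emitted geometry
    for src in sorted(planted):
        best = None
        for j in range(len(tracks)):
            if j == src:
                continue
            dist_j, _ = point_to_polyline_distance(tracks[src][-1], tracks[j])
            if best is None or dist_j < best[0]:
                best = (dist_j, j)
        truth.branches.append(
            {"kmt_id": int(src), "target_id": int(best[1]), "distance_nm": float(best[0])}
        )

    kmt_lengths = []
    for i, (track, m) in enumerate(zip(tracks, meta)):
        L = float(np.linalg.norm(np.diff(track, axis=0), axis=1).sum())
        truth.mts.append(
            {
                "mt_id": i,
                "class": m["class"],
                "fiber_id": m["fiber"],
                "pole": m["pole"],
                "plus_end": m["plus_end"],
                "length_nm": L,
            }
        )
        if m["class"] == "KMT":
            kmt_lengths.append(L)
    truth.mean_kmt_length_nm = float(np.mean(kmt_lengths)) if kmt_lengths else float("nan")

    # closed-form expectations; the helicity value is the small-radius limit
    # (the center curve's arc exceeds its axial extent by
    # sqrt(1 + (2*pi*rho/pitch)^2), negligible only for rho << pitch)
    if pitch_nm > 0:
        per_um = 360.0 / recipe.helix_pitch_um * recipe.handedness
        truth.expected_helicity_deg_per_um = {
            str(f["fiber_id"]): per_um * (1.0 if f["pole"] == 2 else -1.0)
            for f in truth.fibers
        }
        truth.expected_local_twist_deg = 360.0 * 500.0 / pitch_nm
    k = recipe.kmts_per_fiber
    if k >= 3:
        poly_area = 0.5 * k * recipe.bundle_radius_nm**2 * math.sin(2.0 * math.pi / k)
        truth.expected_density_per_um2 = k / poly_area * 1e6

    spindle = Spindle(graph_id=1, microtubules=[], pole1=pole1, pole2=pole2)
    for i, (track, m) in enumerate(zip(tracks, meta)):
        spindle.microtubules.append(
            Microtubule(
                mt_id=i,
                points=track,
                mt_class=MTClass.KMT if m["class"] == "KMT" else MTClass.NON_KMT,
                fiber_id=m["fiber"],
            )
        )
    return spindle.to_spatial_graph(), truth
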