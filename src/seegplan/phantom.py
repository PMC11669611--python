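"""Seeded synthetic anatomical phantoms with analytic ground truth.

A phantom scene stands in for the segmented anatomy of a real planning case:
a closed brain-like surface (an icosphere with smooth seeded radial
perturbation), tubular vessels swept along known centerline polylines of
known radius (so the exact trajectory-to-vessel distance has a closed-form
capsule answer), compact ellipsoidal target regions strictly inside the
brain, and a seven-trajectory demonstration plan whose superficial/deep
target pairings mirror a typical left-hemisphere SEEG implantation
(amygdala, hippocampus, parahippocampal, fusiform, posterior cingulate
targets approached through temporal and parietal gyri).

Everything derives from a single integer seed through fixed sub-streams
(brain / vessels / targets), so regenerating a scene is bit-reproducible and
adding vessels never perturbs the brain surface.

Trajectory 1 is engineered: a dedicated straight vessel is laid parallel to
it at a controlled capsule clearance (4 mm by default), giving an exact
ground-truth d for parameter-recovery tests.  With ``surface_bumpiness = 0``
the brain is an exact sphere and every trajectory's insertion angle also has
a closed-form ray-sphere ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from seegplan.anatomy_io import Plan, Trajectory, TriMesh, save_obj, save_plan
from seegplan.errors import GenerationError, ValidationError
from seegplan.risk_scoring import _segment_segment_distance
from seegplan.trajectory_geometry import entry_point

__all__ = [
    "PhantomSpec",
    "VesselGroundTruth",
    "PhantomScene",
    "make_brain_surface",
    "make_vessel_tree",
    "make_target_region",
    "capsule_min_distance",
    "capsule_segment_clearance",
    "generate_scene",
]

# superficial / deep pairings of the seven-trajectory demonstration plan
# (left-hemisphere structures named AAL-style; trajectory 2 targets the same
# region superficially and deeply)
DEMO_PAIRINGS: list[tuple[str, str]] = [
    ("Temporal_Pole_Mid_L", "Amygdala_L"),
    ("Temporal_Pole_Mid_L", "Temporal_Pole_Mid_L"),
    ("Temporal_Mid_L_ant", "Hippocampus_L_ant"),
    ("Temporal_Mid_L_post", "Hippocampus_L_post"),
    ("Temporal_Mid_L", "ParaHippocampal_L"),
    ("Temporal_Inf_L", "Fusiform_L"),
    ("Parietal_Inf_L", "Cingulum_Post_L"),
]

# unit directions (pre-normalisation) from the head centre toward each deep
# target, all in the left (x < 0) hemisphere, spread over temporal/parietal
# approaches; and the tilt (deg) of each trajectory away from radial
_DEEP_DIRECTIONS = np.array(
    [
        [-0.8, 0.5, -0.3],   # amygdala (anterior-inferior)
        [-0.7, 0.7, -0.2],   # mid temporal pole
        [-0.9, 0.1, -0.3],   # anterior hippocampus
        [-0.8, -0.4, -0.2],  # posterior hippocampus
        [-0.7, -0.1, -0.55], # parahippocampal
        [-0.6, -0.3, -0.6],  # fusiform
        [-0.5, -0.7, 0.5],   # posterior cingulate via inferior parietal
    ]
)
_DEEP_RADIUS_FRAC = np.array([0.40, 0.52, 0.38, 0.40, 0.42, 0.45, 0.35])
_TILT_DEG = np.array([12.0, 8.0, 15.0, 18.0, 10.0, 20.0, 14.0])
_DEEP_SEMI_AXES = (7.0, 5.5, 5.0)
_SUPERFICIAL_SEMI_AXES = (9.0, 7.0, 6.0)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic scene.

    World-scale quantities refer to the enlarged (scale_factor x) model space:
    the 42 mm-diameter guide spheres and 12 mm-diameter endpoint markers of
    the enlarged planning environment correspond to 7 mm and 2 mm at patient
    scale.
    """

    seed: int = 0
    brain_radius: float = 70.0
    surface_bumpiness: float = 0.05
    subdivision_level: int = 4
    n_vessels: int = 6
    vessel_radius_range: tuple[float, float] = (0.6, 1.5)
    n_targets: int = 12
    guide_radius_world: float = 21.0
    endpoint_radius_world: float = 6.0
    scale_factor: float = 6.0
    engineered_clearance: float = 4.0
    tube_sides: int = 12
    tube_axial_step: float = 1.5

    def __post_init__(self) -> None:
        if self.brain_radius <= 0:
            raise ValidationError("brain_radius must be positive")
        if not 0 <= self.surface_bumpiness <= 0.3:
            raise ValidationError("surface_bumpiness must be in [0, 0.3]")
        if self.subdivision_level < 2:
            raise ValidationError("subdivision_level must be >= 2")
        lo, hi = self.vessel_radius_range
        if not 0 < lo <= hi:
            raise ValidationError("vessel_radius_range must be positive and ordered")
        if self.scale_factor <= 0 or self.guide_radius_world <= 0 or self.endpoint_radius_world <= 0:
            raise ValidationError("scale factors and radii must be positive")

    @property
    def min_surface_radius(self) -> float:
        return self.brain_radius * (1.0 - self.surface_bumpiness)


@dataclass
class VesselGroundTruth:
    """Analytic vessel model: centerline polylines with per-polyline radii."""

    polylines: list[np.ndarray]
    radii: list[float]

    def __post_init__(self) -> None:
        if len(self.polylines) != len(self.radii):
            raise ValidationError("one radius per polyline required")
        for pl in self.polylines:
            if pl.shape[0] < 2:
                raise ValidationError("each polyline needs >= 2 points")


@dataclass
class PhantomScene:
    brain: TriMesh
    vessels: TriMesh
    vessel_truth: VesselGroundTruth
    targets: dict[str, TriMesh]
    demo_plan: Plan
    spec: PhantomSpec
    truth_table: dict[str, dict] = field(default_factory=dict)
    guides_world: dict[str, list[float]] = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        """Write brain.obj, vessels.obj, targets/<name>.obj, plan.json, truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_obj(self.brain, out / "brain.obj")
        save_obj(self.vessels, out / "vessels.obj")
        tdir = out / "targets"
        tdir.mkdir(exist_ok=True)
        for name, mesh in self.targets.items():
            save_obj(mesh, tdir / f"{name}.obj")
        save_plan(self.demo_plan, out / "plan.json")
        truth = {
            "polylines": [pl.tolist() for pl in self.vessel_truth.polylines],
            "radii": self.vessel_truth.radii,
            "trajectories": self.truth_table,
            "guides_world": self.guides_world,
            "guide_radius_world": self.spec.guide_radius_world,
            "endpoint_radius_world": self.spec.endpoint_radius_world,
            "scale_factor": self.spec.scale_factor,
        }
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2)
            fh.write("\n")


def _rng(spec: PhantomSpec, label: int) -> np.random.Generator:
    """Independent sub-stream per scene component, all derived from one seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(label,)))


# ---------------------------------------------------------------------------
# Brain surface
# ---------------------------------------------------------------------------


def make_brain_surface(spec: PhantomSpec) -> TriMesh:
    """Closed brain-like surface: icosphere with smooth seeded radial bumps.

    The perturbation is a small sum of low-frequency plane waves of the unit
    direction, normalised so the radial excursion never exceeds
    ``surface_bumpiness x brain_radius``; a purely radial displacement keeps
    the icosphere topology, hence the surface stays watertight.
    """
    ico = _trimesh.creation.icosphere(subdivisions=spec.subdivision_level, radius=1.0)
    v = np.asarray(ico.vertices, dtype=float)
    if spec.surface_bumpiness > 0:
        rng = _rng(spec, 0)
        n_waves = 6
        k = rng.normal(size=(n_waves, 3)) * 2.0
        phase = rng.uniform(0, 2 * math.pi, size=n_waves)
        amp = rng.uniform(0.5, 1.0, size=n_waves)
        f = np.zeros(len(v))
        for j in range(n_waves):
            f += amp[j] * np.sin(v @ k[j] + phase[j])
        f /= max(np.abs(f).max(), 1e-12)
        radii = spec.brain_radius * (1.0 + spec.surface_bumpiness * f)
    else:
        radii = np.full(len(v), spec.brain_radius)
    verts = v * radii[:, None]
    return TriMesh(vertices=verts, faces=np.asarray(ico.faces), name="brain")


# ---------------------------------------------------------------------------
# Vessels
# ---------------------------------------------------------------------------


def _perpendicular(d: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to unit vector d."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(d, ref)
    return p / np.linalg.norm(p)


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Subdivide straight segments to at most ``step`` spacing (same geometry)."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        seg = b - a
        length = np.linalg.norm(seg)
        n = max(1, int(math.ceil(length / step)))
        for i in range(1, n + 1):
            out.append(a + seg * (i / n))
    return np.array(out)


def _sweep_tube(polyline: np.ndarray, radius: float, sides: int, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Capped tube mesh around a polyline.

    Rings of ``sides`` vertices ride parallel-transported frames; the end
    caps are cone fans whose apices sit one radius beyond the endpoints along
    the axis, so every vertex of the tube lies exactly one radius from the
    centerline (ring vertices perpendicular, apices axial).
    """
    pts = _resample_polyline(polyline, step)
    tangents = np.zeros_like(pts)
    tangents[0] = pts[1] - pts[0]
    tangents[-1] = pts[-1] - pts[-2]
    tangents[1:-1] = pts[2:] - pts[:-2]
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]

    # parallel transport of the first frame along the polyline
    u = _perpendicular(tangents[0])
    frames_u = [u]
    for i in range(1, len(pts)):
        t_prev, t_next = tangents[i - 1], tangents[i]
        axis = np.cross(t_prev, t_next)
        s = np.linalg.norm(axis)
        c = float(np.clip(np.dot(t_prev, t_next), -1.0, 1.0))
        if s < 1e-12:
            frames_u.append(frames_u[-1])
            continue
        axis = axis / s
        ang = math.atan2(s, c)
        uu = frames_u[-1]
        # Rodrigues rotation
        uu = (
            uu * math.cos(ang)
            + np.cross(axis, uu) * math.sin(ang)
            + axis * np.dot(axis, uu) * (1 - math.cos(ang))
        )
        uu = uu - np.dot(uu, t_next) * t_next
        frames_u.append(uu / np.linalg.norm(uu))

    theta = np.linspace(0, 2 * math.pi, sides, endpoint=False)
    verts: list[np.ndarray] = []
    for p, t, uu in zip(pts, tangents, frames_u):
        vv = np.cross(t, uu)
        ring = p[None, :] + radius * (np.cos(theta)[:, None] * uu[None, :] + np.sin(theta)[:, None] * vv[None, :])
        verts.append(ring)
    rings = np.concatenate(verts)
    apex0 = pts[0] - radius * tangents[0]
    apex1 = pts[-1] + radius * tangents[-1]
    vertices = np.vstack([rings, apex0, apex1])
    i_apex0 = len(vertices) - 2
    i_apex1 = len(vertices) - 1

    faces: list[tuple[int, int, int]] = []
    n_rings = len(pts)
    for i in range(n_rings - 1):
        base0 = i * sides
        base1 = (i + 1) * sides
        for j in range(sides):
            j2 = (j + 1) % sides
            faces.append((base0 + j, base1 + j, base1 + j2))
            faces.append((base0 + j, base1 + j2, base0 + j2))
    for j in range(sides):  # caps
        j2 = (j + 1) % sides
        faces.append((i_apex0, j2, j))
        base = (n_rings - 1) * sides
        faces.append((i_apex1, base + j, base + j2))
    return vertices, np.array(faces, dtype=np.int64)


def capsule_min_distance(p: np.ndarray, truth: VesselGroundTruth) -> float:
    """Exact distance from a point to the vessel capsules (0 inside a vessel)."""
    if not truth.polylines:
        raise ValidationError("empty vessel ground truth")
    p = np.asarray(p, dtype=float).reshape(3)
    best = math.inf
    for pl, r in zip(truth.polylines, truth.radii):
        a = pl[:-1]
        b = pl[1:]
        ab = b - a
        ap = p[None, :] - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", ap, ab) / np.maximum(denom, 1e-30), 0.0, 1.0)
        closest = a + t[:, None] * ab
        d = float(np.linalg.norm(p[None, :] - closest, axis=1).min()) - r
        best = min(best, d)
    return max(best, 0.0)


def capsule_segment_clearance(p0: np.ndarray, p1: np.ndarray, truth: VesselGroundTruth) -> float:
    """Exact minimum distance from segment p0..p1 to the vessel capsules."""
    p0 = np.asarray(p0, dtype=float).reshape(3)
    p1 = np.asarray(p1, dtype=float).reshape(3)
    best = math.inf
    for pl, r in zip(truth.polylines, truth.radii):
        for a, b in zip(pl[:-1], pl[1:]):
            d = _segment_segment_distance(p0, p1, a, b) - r
            best = min(best, d)
    return max(best, 0.0)


def _random_polyline(
    rng: np.random.Generator,
    spec: PhantomSpec,
    radius: float,
    n_steps: int = 12,
    step: float = 4.0,
    max_turn: float = 0.25,
) -> np.ndarray | None:
    """Clamped smooth random walk: fixed step, turning angle <= max_turn rad.

    The turn clamp keeps polyline corners gentle so swept-tube ring vertices
    stay within a fraction of a percent of one radius from the centerline.
    An inward pull that strengthens near the containment boundary steers the
    walk back toward the centre; a walk that still escapes returns None and
    the caller redraws it.
    """
    max_norm = 0.6 * spec.min_surface_radius - radius - 2.0
    start = rng.normal(size=3)
    start = start / np.linalg.norm(start) * rng.uniform(0.1, 0.7) * max_norm
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [start]
    for _ in range(n_steps):
        p = pts[-1]
        r_frac = np.linalg.norm(p) / max_norm
        pull = -1.5 * r_frac**6 * (p / max(np.linalg.norm(p), 1e-9))
        prop = d + 0.35 * rng.normal(size=3) + pull
        prop /= np.linalg.norm(prop)
        ang = math.acos(float(np.clip(np.dot(d, prop), -1.0, 1.0)))
        if ang > max_turn:
            s = math.sin(ang)
            prop = (math.sin(ang - max_turn) * d + math.sin(max_turn) * prop) / s
            prop /= np.linalg.norm(prop)
        d = prop
        nxt = p + step * d
        if np.linalg.norm(nxt) > max_norm:
            return None
        pts.append(nxt)
    return np.array(pts)


def make_vessel_tree(
    spec: PhantomSpec,
    avoid_segments: list[tuple[np.ndarray, np.ndarray, float]] | None = None,
    engineered: list[tuple[np.ndarray, float, float]] | None = None,
) -> tuple[TriMesh, VesselGroundTruth]:
    """Vessels as capped tubes around seeded smooth polylines.

    ``avoid_segments`` is a list of (p0, p1, min_clearance): candidate
    polylines whose capsule comes closer than the stated clearance to any of
    these segments are resampled (bounded retries), which lets the demo plan
    keep realistic safety margins.  ``engineered`` entries are
    (straight centerline (2,3), radius, nominal clearance) laid down verbatim.
    """
    rng = _rng(spec, 1)
    lo, hi = spec.vessel_radius_range
    polylines: list[np.ndarray] = []
    radii: list[float] = []
    if engineered:
        for line, r, _ in engineered:
            polylines.append(np.asarray(line, dtype=float))
            radii.append(float(r))
    for _ in range(spec.n_vessels):
        r = float(rng.uniform(lo, hi))
        for _attempt in range(500):
            pl = _random_polyline(rng, spec, r)
            if pl is None:
                continue
            ok = True
            for p0, p1, clearance in avoid_segments or []:
                truth_one = VesselGroundTruth(polylines=[pl], radii=[r])
                if capsule_segment_clearance(p0, p1, truth_one) < clearance:
                    ok = False
                    break
            if ok:
                polylines.append(pl)
                radii.append(r)
                break
        else:
            raise GenerationError("could not place a vessel within the clearance constraints")
    truth = VesselGroundTruth(polylines=polylines, radii=radii)

    all_v: list[np.ndarray] = []
    all_f: list[np.ndarray] = []
    offset = 0
    for pl, r in zip(polylines, radii):
        v, f = _sweep_tube(pl, r, spec.tube_sides, spec.tube_axial_step)
        all_v.append(v)
        all_f.append(f + offset)
        offset += len(v)
    mesh = TriMesh(vertices=np.vstack(all_v), faces=np.vstack(all_f), name="vessels")
    return mesh, truth


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------


def make_target_region(
    center: np.ndarray,
    semi_axes: tuple[float, float, float],
    spec: PhantomSpec,
    name: str = "target",
    subdivisions: int = 3,
) -> TriMesh:
    """Axis-aligned ellipsoid target mesh; vertex centroid equals ``center``."""
    center = np.asarray(center, dtype=float).reshape(3)
    if np.linalg.norm(center) + max(semi_axes) + 2.0 > spec.min_surface_radius:
        raise GenerationError(
            f"target '{name}' would escape the brain interior margin"
        )
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(ico.vertices, dtype=float) * np.asarray(semi_axes)[None, :] + center[None, :]
    return TriMesh(vertices=v, faces=np.asarray(ico.faces), name=name)


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------


def _tilted_direction(radial: np.ndarray, tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit direction at ``tilt_deg`` from ``radial``, rotated ``azimuth_deg`` about it."""
    r = radial / np.linalg.norm(radial)
    u = _perpendicular(r)
    v = np.cross(r, u)
    t = math.radians(tilt_deg)
    a = math.radians(azimuth_deg)
    d = math.cos(t) * r + math.sin(t) * (math.cos(a) * u + math.sin(a) * v)
    return d / np.linalg.norm(d)


def _analytic_sphere_entry(endpoint: np.ndarray, direction: np.ndarray, radius: float) -> np.ndarray:
    """Exact exit point of the ray endpoint + t*direction from a centred sphere."""
    b = float(np.dot(endpoint, direction))
    c = float(np.dot(endpoint, endpoint)) - radius * radius
    t = -b + math.sqrt(b * b - c)
    return endpoint + t * direction


def generate_scene(spec: PhantomSpec | None = None) -> PhantomScene:
    """Build a full phantom scene with its seven-trajectory demo plan.

    Deep targets sit at fixed fractions of the brain radius along spread-out
    left-hemisphere directions; each trajectory leaves its deep target along
    a direction tilted a known angle from radial, and its superficial target
    is centred on the trajectory segment so passage holds by construction.
    Vessels avoid all demo trajectories by >= 3 mm capsule clearance except
    the engineered vessel, placed parallel to trajectory 1 at the spec's
    engineered clearance (default 4 mm), which therefore sets trajectory 1's
    ground-truth d.
    """
    spec = spec or PhantomSpec()
    brain = make_brain_surface(spec)

    # --- demo trajectories ------------------------------------------------
    dirs = _DEEP_DIRECTIONS / np.linalg.norm(_DEEP_DIRECTIONS, axis=1)[:, None]
    deep_centers: dict[str, np.ndarray] = {}
    names: list[tuple[str, str]] = list(DEMO_PAIRINGS)

    trajectories: list[Trajectory] = []
    truth_table: dict[str, dict] = {}
    targets: dict[str, TriMesh] = {}
    seg_list: list[tuple[np.ndarray, np.ndarray, float]] = []

    # pass 1: endpoints and directions; trajectory 2 reuses trajectory 1's
    # superficial region as its deep target, so resolve sequentially.
    endpoints: list[np.ndarray] = []
    directions: list[np.ndarray] = []
    for i, (sup_name, deep_name) in enumerate(names):
        if deep_name in deep_centers:
            endpoint = deep_centers[deep_name]
        elif i == 1 and deep_name == names[0][0]:
            # placed after trajectory 0's superficial centre is known
            endpoint = None
        else:
            endpoint = dirs[i] * (_DEEP_RADIUS_FRAC[i] * spec.brain_radius)
            deep_centers[deep_name] = endpoint
        endpoints.append(endpoint)
        directions.append(None)

    entry_cache: list[np.ndarray] = [None] * len(names)

    def build_trajectory(i: int, endpoint: np.ndarray) -> tuple[Trajectory, np.ndarray]:
        azimuth = 47.0 * i  # spread tilts deterministically
        radial = endpoint if np.linalg.norm(endpoint) > 1e-9 else dirs[i]
        direction = _tilted_direction(radial, _TILT_DEG[i], azimuth)
        sup_name, deep_name = names[i]
        probe = Trajectory(
            name=f"T{i + 1}",
            entry=endpoint + direction * 3.0 * spec.brain_radius,
            endpoint=endpoint,
            deep_target=deep_name,
            superficial_target=sup_name,
        )
        res = entry_point(probe, brain)
        traj = Trajectory(
            name=f"T{i + 1}",
            entry=res.entry_point,
            endpoint=endpoint,
            deep_target=deep_name,
            superficial_target=sup_name,
        )
        return traj, direction

    for i, (sup_name, deep_name) in enumerate(names):
        endpoint = endpoints[i]
        if endpoint is None:  # trajectory 2: deep target = trajectory 1's superficial
            endpoint = deep_centers[deep_name]
        traj, direction = build_trajectory(i, endpoint)
        trajectories.append(traj)
        directions[i] = direction
        entry_cache[i] = traj.entry

        # superficial target centred on the segment, pulled inward until the
        # ellipsoid clears the interior margin
        if sup_name not in targets and sup_name != deep_name:
            max_axis = max(_SUPERFICIAL_SEMI_AXES)
            for u in (0.55, 0.45, 0.35, 0.25):
                center = traj.endpoint + u * (traj.entry - traj.endpoint)
                if np.linalg.norm(center) + max_axis + 2.0 <= spec.min_surface_radius:
                    break
            else:
                raise GenerationError(f"cannot place superficial target '{sup_name}'")
            targets[sup_name] = make_target_region(center, _SUPERFICIAL_SEMI_AXES, spec, name=sup_name)
            if sup_name not in deep_centers:
                deep_centers[sup_name] = center
        if deep_name not in targets:
            targets[deep_name] = make_target_region(
                deep_centers[deep_name], _DEEP_SEMI_AXES, spec, name=deep_name
            )
        seg_list.append((traj.entry, traj.endpoint, 3.0))

    # --- vessels ----------------------------------------------------------
    t1 = trajectories[0]
    w = t1.direction
    mid = 0.5 * (t1.entry + t1.endpoint)
    n_hat = _perpendicular(w)
    r_eng = float(np.mean(spec.vessel_radius_range))
    offset_center = mid + (spec.engineered_clearance + r_eng) * n_hat
    half = 15.0
    eng_line = np.array([offset_center - half * w, offset_center + half * w])
    # trajectory 1 demands extra clearance from random vessels so the
    # engineered vessel is its unambiguous nearest structure
    seg_list[0] = (t1.entry, t1.endpoint, spec.engineered_clearance + 2.0)
    vessels, truth = make_vessel_tree(
        spec,
        avoid_segments=seg_list,
        engineered=[(eng_line, r_eng, spec.engineered_clearance)],
    )

    # --- ground truth table ----------------------------------------------
    guides_world: dict[str, list[float]] = {}
    for i, traj in enumerate(trajectories):
        d_true = capsule_segment_clearance(traj.entry, traj.endpoint, truth)
        alpha_true = None
        if spec.surface_bumpiness == 0:
            entry_exact = _analytic_sphere_entry(traj.endpoint, directions[i], spec.brain_radius)
            normal = entry_exact / np.linalg.norm(entry_exact)
            alpha_true = math.degrees(
                math.acos(float(np.clip(np.dot(traj.direction, normal), -1.0, 1.0)))
            )
        truth_table[traj.name] = {
            "d_mm": float(d_true),
            "alpha_deg": alpha_true,
            "tilt_deg": float(_TILT_DEG[i]),
            "engineered_d": spec.engineered_clearance if i == 0 else None,
        }
        guides_world[traj.name] = [float(x) for x in traj.endpoint * spec.scale_factor]

    # --- extra unnamed targets, if asked for ------------------------------
    rng_t = _rng(spec, 2)
    extra = spec.n_targets - len(targets)
    k = 0
    while k < extra:
        c = rng_t.normal(size=3)
        c = c / np.linalg.norm(c) * rng_t.uniform(0.2, 0.6) * spec.min_surface_radius
        try:
            targets[f"Region_{k + 1}"] = make_target_region(c, (6.0, 5.0, 4.0), spec, name=f"Region_{k + 1}")
        except GenerationError:
            continue
        k += 1

    plan = Plan(trajectories=trajectories, space="patient_mm", scale_factor=spec.scale_factor)
    return PhantomScene(
        brain=brain,
        vessels=vessels,
        vessel_truth=truth,
        targets=targets,
        demo_plan=plan,
        spec=spec,
        truth_table=truth_table,
        guides_world=guides_world,
    )
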