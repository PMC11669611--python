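"""Mesh and electrode-plan I/O plus patient/world coordinate transforms.

All geometry is carried in right-handed millimetre coordinates with 0-based
face indexing.  Meshes travel as ASCII Wavefront OBJ; electrode plans as JSON
documents tagged with the coordinate space they live in (``patient_mm`` or
``world_mm``, where world = scale_factor x patient — surgical-planning setups
often work on enlarged models, typically 6x, for precision).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from seegplan.errors import ParseError, SchemaError, ValidationError

SPACES = ("patient_mm", "world_mm")


@dataclass
class TriMesh:
    """Indexed triangle surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array, 0-based vertex indices
    name : label carried through reports and file names
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.validate()

    def validate(self) -> None:
        if self.vertices.shape[0] < 1:
            raise ValidationError(f"mesh '{self.name}': needs at least 1 vertex")
        if not np.isfinite(self.vertices).all():
            raise ValidationError(f"mesh '{self.name}': non-finite vertex coordinates")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValidationError(
                    f"mesh '{self.name}': face index out of range "
                    f"[0, {len(self.vertices)})"
                )
            a, b, c = self.faces.T
            if ((a == b) | (b == c) | (a == c)).any():
                raise ValidationError(f"mesh '{self.name}': degenerate face (repeated vertex)")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def max_edge_length(self) -> float:
        tri = self.triangles()
        e = np.concatenate(
            [tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]]
        )
        return float(np.linalg.norm(e, axis=1).max())

    def median_edge_length(self) -> float:
        tri = self.triangles()
        e = np.concatenate(
            [tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]]
        )
        return float(np.median(np.linalg.norm(e, axis=1)))

    def to_trimesh(self):
        """Convert to a :class:`trimesh.Trimesh` (no processing/merging)."""
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(), process=False)


@dataclass
class Trajectory:
    """One electrode: an oriented straight segment from entry to endpoint (tip).

    ``direction`` points endpoint -> entry, i.e. from the tip outward through
    the skull, the direction along which the electrode is withdrawn.
    """

    name: str
    entry: np.ndarray
    endpoint: np.ndarray
    deep_target: str = ""
    superficial_target: str = ""

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float).reshape(3)
        self.endpoint = np.asarray(self.endpoint, dtype=float).reshape(3)
        if not (np.isfinite(self.entry).all() and np.isfinite(self.endpoint).all()):
            raise ValidationError(f"trajectory '{self.name}': non-finite coordinates")
        if self.length <= 1e-9:
            raise ValidationError(
                f"trajectory '{self.name}': entry and endpoint coincide (separation <= 1e-9 mm)"
            )

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.entry - self.endpoint))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector endpoint -> entry."""
        d = self.entry - self.endpoint
        return d / np.linalg.norm(d)


@dataclass
class Plan:
    """An ordered set of named trajectories in a declared coordinate space."""

    trajectories: list[Trajectory] = field(default_factory=list)
    space: str = "patient_mm"
    scale_factor: float = 6.0

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise SchemaError(f"unknown space '{self.space}', expected one of {SPACES}")
        if not (self.scale_factor > 0 and math.isfinite(self.scale_factor)):
            raise SchemaError(f"scale_factor must be positive, got {self.scale_factor}")
        names = [t.name for t in self.trajectories]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate trajectory names: {dupes}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def to_space(self, space: str) -> "Plan":
        """Return an equivalent plan expressed in ``space``.

        world coordinates = scale_factor x patient coordinates.
        """
        if space not in SPACES:
            raise SchemaError(f"unknown space '{space}'")
        if space == self.space:
            return self
        s = self.scale_factor if space == "world_mm" else 1.0 / self.scale_factor
        t = FrameTransform(scale=s)
        trajs = [
            replace(tr, entry=t.apply(tr.entry), endpoint=t.apply(tr.endpoint))
            for tr in self.trajectories
        ]
        return Plan(trajectories=trajs, space=space, scale_factor=self.scale_factor)


@dataclass
class FrameTransform:
    """Similarity transform p' = M (s p) + offset, M = identity or x-negation.

    ``mirror_x`` flips the sagittal axis (left/right); ``scale`` converts
    between patient and enlarged-model space.  The transform is invertible
    for any positive scale.
    """

    scale: float = 1.0
    mirror_x: bool = False
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValidationError(f"scale must be positive and finite, got {self.scale}")
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)

    def _mirror(self) -> np.ndarray:
        m = np.ones(3)
        if self.mirror_x:
            m[0] = -1.0
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p * (self.scale * self._mirror()) + self.offset

    def inverse(self) -> "FrameTransform":
        m = self._mirror()
        return FrameTransform(
            scale=1.0 / self.scale,
            mirror_x=self.mirror_x,
            offset=-(self.offset * m) / self.scale,
        )


def apply_transform(obj, t: FrameTransform):
    """Apply ``t`` to a point array, TriMesh or Trajectory; returns the same kind."""
    if isinstance(obj, TriMesh):
        v = t.apply(obj.vertices)
        faces = obj.faces
        if t.mirror_x:
            # a reflection reverses orientation; flip winding to keep outward normals
            faces = faces[:, ::-1]
        return TriMesh(vertices=v, faces=faces, name=obj.name)
    if isinstance(obj, Trajectory):
        return replace(obj, entry=t.apply(obj.entry), endpoint=t.apply(obj.endpoint))
    return t.apply(obj)


# ---------------------------------------------------------------------------
# Wavefront OBJ
#
# The dialect read here is the minimal ASCII subset the planning pipeline
# emits: "v" and "f" records; "vn"/"vt"/"mtllib"/"usemtl"/"g"/"o"/"s" and
# comments are ignored.  Polygon faces are fan-triangulated from their first
# vertex; 1-based (and negative, relative) OBJ indices become 0-based.
# ---------------------------------------------------------------------------

_IGNORED_KEYS = {"vn", "vt", "vp", "mtllib", "usemtl", "g", "o", "s", "l", "p"}


def load_obj(path: str | Path, name: str | None = None) -> TriMesh:
    """Read an ASCII Wavefront OBJ triangle/polygon mesh.

    Polygons with more than 3 vertices are fan-triangulated from the first
    vertex.  Raises :class:`ParseError` naming the line for malformed records
    and :class:`ValidationError` for out-of-range face indices.
    """
    path = Path(path)
    vertices: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            key = parts[0]
            if key == "v":
                if len(parts) < 4:
                    raise ParseError(f"{path.name}:{lineno}: vertex needs 3 coordinates: {line!r}")
                try:
                    vertices.append((float(parts[1]), float(parts[2]), float(parts[3])))
                except ValueError as exc:
                    raise ParseError(f"{path.name}:{lineno}: bad vertex coordinate: {line!r}") from exc
            elif key == "f":
                if len(parts) < 4:
                    raise ParseError(f"{path.name}:{lineno}: face needs >= 3 vertices: {line!r}")
                idx = []
                for token in parts[1:]:
                    head = token.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError as exc:
                        raise ParseError(f"{path.name}:{lineno}: bad face index {token!r}") from exc
                    if i == 0:
                        raise ParseError(f"{path.name}:{lineno}: OBJ indices are 1-based, got 0")
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                for j in range(1, len(idx) - 1):
                    faces.append((idx[0], idx[j], idx[j + 1]))
            elif key in _IGNORED_KEYS:
                continue
            else:
                raise ParseError(f"{path.name}:{lineno}: unrecognised record {key!r}")
    if not vertices:
        raise ParseError(f"{path.name}: no vertices found")
    mesh_name = name if name is not None else path.stem
    try:
        return TriMesh(vertices=np.array(vertices), faces=np.array(faces).reshape(-1, 3), name=mesh_name)
    except ValidationError as exc:
        raise ValidationError(f"{path.name}: {exc}") from exc


def save_obj(mesh: TriMesh, path: str | Path) -> None:
    """Write ``mesh`` as ASCII OBJ; round-trips geometry to < 1e-6 mm."""
    mesh.validate()
    path = Path(path)
    lines = [f"# seegplan mesh: {mesh.name}\n"]
    for x, y, z in mesh.vertices:
        lines.append(f"v {x:.9g} {y:.9g} {z:.9g}\n")
    for a, b, c in mesh.faces + 1:
        lines.append(f"f {a} {b} {c}\n")
    path.write_text("".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Plan JSON
# ---------------------------------------------------------------------------


def _as_point(value, where: str) -> list[float]:
    if (
        not isinstance(value, Sequence)
        or isinstance(value, (str, bytes))
        or len(value) != 3
        or not all(isinstance(x, (int, float)) and math.isfinite(x) for x in value)
    ):
        raise SchemaError(f"{where}: expected [x, y, z] finite numbers, got {value!r}")
    return [float(x) for x in value]


def plan_to_dict(plan: Plan) -> dict:
    return {
        "space": plan.space,
        "scale_factor": plan.scale_factor,
        "trajectories": [
            {
                "name": t.name,
                "entry_mm": [float(x) for x in t.entry],
                "endpoint_mm": [float(x) for x in t.endpoint],
                "deep_target": t.deep_target,
                "superficial_target": t.superficial_target,
            }
            for t in plan.trajectories
        ],
    }


def plan_from_dict(doc: dict) -> Plan:
    if not isinstance(doc, dict):
        raise SchemaError("plan document must be a JSON object")
    for key in ("space", "scale_factor", "trajectories"):
        if key not in doc:
            raise SchemaError(f"plan document missing required field '{key}'")
    space = doc["space"]
    if space not in SPACES:
        raise SchemaError(f"space must be one of {SPACES}, got {space!r}")
    sf = doc["scale_factor"]
    if not isinstance(sf, (int, float)) or not sf > 0:
        raise SchemaError(f"scale_factor must be a positive number, got {sf!r}")
    trajs = []
    if not isinstance(doc["trajectories"], list):
        raise SchemaError("'trajectories' must be a list")
    for i, td in enumerate(doc["trajectories"]):
        where = f"trajectories[{i}]"
        if not isinstance(td, dict):
            raise SchemaError(f"{where}: expected an object")
        for key in ("name", "entry_mm", "endpoint_mm", "deep_target", "superficial_target"):
            if key not in td:
                raise SchemaError(f"{where}: missing required field '{key}'")
        trajs.append(
            Trajectory(
                name=str(td["name"]),
                entry=_as_point(td["entry_mm"], f"{where}.entry_mm"),
                endpoint=_as_point(td["endpoint_mm"], f"{where}.endpoint_mm"),
                deep_target=str(td["deep_target"]),
                superficial_target=str(td["superficial_target"]),
            )
        )
    return Plan(trajectories=trajs, space=space, scale_factor=float(sf))


def load_plan(path: str | Path) -> Plan:
    """Load an electrode plan from JSON; schema violations raise :class:`SchemaError`."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{Path(path).name}: invalid JSON: {exc}") from exc
    return plan_from_dict(doc)


def save_plan(plan: Plan, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(plan_to_dict(plan), fh, indent=2)
        fh.write("\n")
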