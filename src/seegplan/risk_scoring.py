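"""Surgical risk scoring for SEEG electrode trajectories.

A trajectory is scored on two risk factors.  Vessel clearance d (mm, minimum
distance from the trajectory to the vasculature model) maps to

    f_d = reject            if d < 2 mm      (hemorrhage risk)
        = (d - 2) / (5 - 2) if 2 mm <= d <= 5 mm
        = 1                 if d > 5 mm      (risk reduction plateaus)

and the insertion angle alpha (degrees, against the outward brain-surface
normal at the entry point) maps to

    f_alpha = reject              if alpha > 30 deg  (keyhole drilling limit)
            = (30 - alpha) / 30   otherwise.

The composite quality score weights hemorrhage risk highest:

    f = 0.8 f_d + 0.2 f_alpha  in [0, 1],

reaching 1 only for a perpendicular insertion at >= 5 mm clearance.  A plan's
score is the mean of f over its accepted (non-rejected) trajectories.
Thresholds and weights are configurable; rejection boundaries are strict
exactly as stated (d = 2 mm and alpha = 30 deg are accepted with component
score 0).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from seegplan.anatomy_io import Plan, Trajectory, TriMesh
from seegplan.errors import GeometryError, ValidationError
from seegplan.trajectory_geometry import (
    SpatialGrid,
    build_vertex_grid,
    entry_point,
    insertion_angle,
    intersect_segment_mesh,
    min_vessel_distance,
    point_in_mesh,
)

REJECT_VESSEL = "vessel_too_close"
REJECT_ANGLE = "angle_too_steep"
REJECT_DEEP = "misses_deep_target"
REJECT_SUPERFICIAL = "misses_superficial_target"


@dataclass
class ScoringConfig:
    """Thresholds, weights and sampling density of the quality score.

    Defaults follow the published planning criteria: reject below 2 mm
    clearance, full clearance credit beyond 5 mm, reject insertion angles
    over 30 degrees, weights 0.8 / 0.2, 125 key points per trajectory.
    """

    d_reject: float = 2.0
    d_plateau: float = 5.0
    alpha_max: float = 30.0
    w_d: float = 0.8
    w_alpha: float = 0.2
    n_key_points: int = 125
    clearance_threshold: float = 2.0
    distance_mode: str = "vertex"

    def __post_init__(self) -> None:
        if not 0 < self.d_reject < self.d_plateau:
            raise ValidationError(
                f"need 0 < d_reject < d_plateau, got {self.d_reject}, {self.d_plateau}"
            )
        if not 0 < self.alpha_max <= 90:
            raise ValidationError(f"alpha_max must be in (0, 90], got {self.alpha_max}")
        if self.w_d < 0 or self.w_alpha < 0 or abs(self.w_d + self.w_alpha - 1.0) > 1e-12:
            raise ValidationError(f"weights must be nonnegative and sum to 1")
        if self.n_key_points < 2:
            raise ValidationError(f"n_key_points must be >= 2, got {self.n_key_points}")
        if self.clearance_threshold < 0:
            raise ValidationError("clearance_threshold must be >= 0")
        if self.distance_mode not in ("vertex", "exact"):
            raise ValidationError(f"unknown distance_mode {self.distance_mode!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoringConfig":
        """Load overrides from a YAML or JSON mapping of field names to values."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)


@dataclass
class TargetCheck:
    """Did the trajectory reach its deep target and pass its superficial one?"""

    reaches_deep: bool
    passes_superficial: bool
    warnings: list[str] = field(default_factory=list)


@dataclass
class RiskReport:
    """Per-trajectory risk metrics, component scores, and accept/reject status.

    Rejected trajectories carry no composite score (``f`` is None): the
    planning criteria reject them outright rather than scoring them 0.
    ``f_rounded`` is the display value at 3 decimals; ``f`` keeps full
    precision.
    """

    name: str
    d: float | None = None
    alpha: float | None = None
    f_d: float | None = None
    f_alpha: float | None = None
    f: float | None = None
    accepted: bool = False
    reject_reasons: list[str] = field(default_factory=list)
    nearest_vessel_point: list[float] | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def f_rounded(self) -> float | None:
        return None if self.f is None else round(self.f, 3)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "d_mm": self.d,
            "alpha_deg": self.alpha,
            "f_d": self.f_d,
            "f_alpha": self.f_alpha,
            "f": self.f_rounded,
            "f_raw": self.f,
            "accepted": self.accepted,
            "reject_reasons": list(self.reject_reasons),
            "nearest_vessel_point": self.nearest_vessel_point,
            "warnings": list(self.warnings),
        }


@dataclass
class PlanReport:
    """Aggregate of per-trajectory reports; mean score over accepted only."""

    reports: list[RiskReport]
    config: ScoringConfig

    @property
    def n_accepted(self) -> int:
        return sum(r.accepted for r in self.reports)

    @property
    def n_rejected(self) -> int:
        return len(self.reports) - self.n_accepted

    @property
    def mean_score(self) -> float | None:
        scores = [r.f for r in self.reports if r.accepted and r.f is not None]
        if not scores:
            return None
        return float(np.mean(scores))

    def to_dict(self) -> dict:
        return {
            "trajectories": [r.to_dict() for r in self.reports],
            "mean_score": self.mean_score,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "config": asdict(self.config),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Component scores
# ---------------------------------------------------------------------------


def vessel_distance_score(d: float, cfg: ScoringConfig | None = None) -> float | None:
    """Clearance sub-score f_d; None means the trajectory is rejected (d < 2 mm)."""
    cfg = cfg or ScoringConfig()
    if d < 0 or not math.isfinite(d):
        raise ValidationError(f"vessel distance must be >= 0, got {d}")
    if d < cfg.d_reject:
        return None
    if d > cfg.d_plateau:
        return 1.0
    return (d - cfg.d_reject) / (cfg.d_plateau - cfg.d_reject)


def insertion_angle_score(alpha: float, cfg: ScoringConfig | None = None) -> float | None:
    """Angle sub-score f_alpha; None means rejected (alpha > 30 deg)."""
    cfg = cfg or ScoringConfig()
    if alpha < 0 or not math.isfinite(alpha):
        raise ValidationError(f"insertion angle must be >= 0, got {alpha}")
    if alpha > cfg.alpha_max:
        return None
    return (cfg.alpha_max - alpha) / cfg.alpha_max


def quality_score(d: float, alpha: float, cfg: ScoringConfig | None = None) -> float | None:
    """Composite score f = w_d f_d + w_alpha f_alpha; None if either rejects."""
    cfg = cfg or ScoringConfig()
    f_d = vessel_distance_score(d, cfg)
    f_alpha = insertion_angle_score(alpha, cfg)
    if f_d is None or f_alpha is None:
        return None
    return cfg.w_d * f_d + cfg.w_alpha * f_alpha


# ---------------------------------------------------------------------------
# Validity checks and evaluation
# ---------------------------------------------------------------------------


def _segment_passes(traj: Trajectory, region: TriMesh) -> bool:
    """Does some point of the segment entry..endpoint lie strictly inside region?

    Decided from the sorted crossing parameters: the midpoint of each
    interval between consecutive crossings (and of the trailing interval when
    the endpoint is inside) is probed with the parity test, so a tangential
    graze with no interior interval does not count as passage.
    """
    endpoint_inside = point_in_mesh(traj.endpoint, region)
    if endpoint_inside:
        return True
    hits = intersect_segment_mesh(traj.entry, traj.endpoint, region)
    if not hits:
        return False
    ts = [t for t, _, _ in hits]
    probes = [0.5 * (ts[i] + ts[i + 1]) for i in range(len(ts) - 1)]
    probes.append(0.5 * ts[0])  # entry side, in case the entry is inside
    return any(
        point_in_mesh(traj.entry + t * (traj.endpoint - traj.entry), region) for t in probes
    )


def check_targets(traj: Trajectory, deep: TriMesh, superficial: TriMesh) -> TargetCheck:
    """Deep target must contain the endpoint; the shaft must pass the superficial.

    When the two targets are the same region, passage follows from reach.
    """
    warnings: list[str] = []
    for m in (deep, superficial):
        if not m.to_trimesh().is_watertight:
            warnings.append(f"target mesh '{m.name}' is not watertight; containment is best-effort")
    reaches = point_in_mesh(traj.endpoint, deep)
    if superficial is deep or (
        superficial.name == deep.name
        and superficial.n_vertices == deep.n_vertices
    ):
        return TargetCheck(reaches_deep=reaches, passes_superficial=reaches, warnings=warnings)
    return TargetCheck(
        reaches_deep=reaches,
        passes_superficial=_segment_passes(traj, superficial),
        warnings=warnings,
    )


def evaluate_trajectory(
    traj: Trajectory,
    brain: TriMesh,
    vessels: TriMesh,
    deep: TriMesh | None = None,
    superficial: TriMesh | None = None,
    cfg: ScoringConfig | None = None,
    grid: SpatialGrid | None = None,
) -> RiskReport:
    """Full per-trajectory risk report.

    Composes entry-point location, insertion angle, minimum vessel distance,
    and target validity, then applies the scoring rules.  Geometric failures
    are recorded as reject reasons rather than raised, and every violated
    constraint is reported, not just the first.
    """
    cfg = cfg or ScoringConfig()
    report = RiskReport(name=traj.name)
    try:
        alpha = insertion_angle(traj, brain)
        report.alpha = alpha
    except (ValidationError, GeometryError) as exc:
        report.warnings.append(str(exc))
        alpha = None

    dres = min_vessel_distance(traj, vessels, grid=grid, n=cfg.n_key_points, mode=cfg.distance_mode)
    report.d = dres.d_min
    if dres.nearest_vertex_index >= 0:
        report.nearest_vessel_point = [float(x) for x in dres.nearest_point]

    report.f_d = vessel_distance_score(dres.d_min, cfg)
    if report.f_d is None:
        report.reject_reasons.append(REJECT_VESSEL)
    if alpha is None:
        report.reject_reasons.append(REJECT_ANGLE)
    else:
        report.f_alpha = insertion_angle_score(alpha, cfg)
        if report.f_alpha is None:
            report.reject_reasons.append(REJECT_ANGLE)

    if deep is not None and superficial is not None:
        tc = check_targets(traj, deep, superficial)
        report.warnings.extend(tc.warnings)
        if not tc.reaches_deep:
            report.reject_reasons.append(REJECT_DEEP)
        if not tc.passes_superficial:
            report.reject_reasons.append(REJECT_SUPERFICIAL)

    report.accepted = not report.reject_reasons
    if report.accepted:
        report.f = cfg.w_d * report.f_d + cfg.w_alpha * report.f_alpha
    return report


def evaluate_plan(
    plan: Plan,
    brain: TriMesh,
    vessels: TriMesh,
    targets: dict[str, TriMesh] | None = None,
    cfg: ScoringConfig | None = None,
) -> PlanReport:
    """Evaluate every trajectory of a plan; plans in world space are first
    converted to patient millimetres so clinical thresholds apply at the
    right scale.

    ``targets`` maps target names (as referenced by the trajectories) to
    closed meshes; when omitted, target validity is not checked.
    """
    cfg = cfg or ScoringConfig()
    plan = plan.to_space("patient_mm")
    grid = build_vertex_grid(vessels) if vessels.n_vertices else None
    reports = []
    for traj in plan.trajectories:
        deep = superficial = None
        if targets is not None:
            deep = targets.get(traj.deep_target)
            superficial = targets.get(traj.superficial_target)
            if traj.deep_target and deep is None:
                raise ValidationError(f"no mesh provided for deep target '{traj.deep_target}'")
            if traj.superficial_target and superficial is None:
                raise ValidationError(
                    f"no mesh provided for superficial target '{traj.superficial_target}'"
                )
        reports.append(
            evaluate_trajectory(traj, brain, vessels, deep, superficial, cfg, grid=grid)
        )
    return PlanReport(reports=reports, config=cfg)


# ---------------------------------------------------------------------------
# Electrode-electrode clearance
# ---------------------------------------------------------------------------


def _segment_segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between closed segments [p1,q1] and [p2,q2]."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(np.dot(d1, d1))
    e = float(np.dot(d2, d2))
    f = float(np.dot(d2, r))
    eps = 1e-15
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(np.dot(d1, r))
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(np.dot(d1, d2))
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    c1 = p1 + s * d1
    c2 = p2 + t * d2
    return float(np.linalg.norm(c1 - c2))


def pairwise_clearance(
    trajectories: list[Trajectory], cfg: ScoringConfig | None = None
) -> tuple[np.ndarray, list[tuple[str, str, float]]]:
    """Symmetric matrix of segment-to-segment distances between electrodes.

    Electrodes must not cross each other; any pair closer than the
    configured clearance threshold is returned in the warning list.
    """
    cfg = cfg or ScoringConfig()
    if len(trajectories) < 2:
        raise ValidationError("pairwise clearance needs at least 2 trajectories")
    n = len(trajectories)
    mat = np.zeros((n, n))
    warnings: list[tuple[str, str, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = trajectories[i], trajectories[j]
            d = _segment_segment_distance(a.entry, a.endpoint, b.entry, b.endpoint)
            mat[i, j] = mat[j, i] = d
            if d < cfg.clearance_threshold:
                warnings.append((a.name, b.name, d))
    return mat, warnings


# ---------------------------------------------------------------------------
# Candidate-entry ranking
# ---------------------------------------------------------------------------


@dataclass
class EntryCandidate:
    vertex_index: int
    entry: np.ndarray
    report: RiskReport


def suggest_entries(
    endpoint: np.ndarray,
    brain: TriMesh,
    vessels: TriMesh,
    superficial: TriMesh | None = None,
    cfg: ScoringConfig | None = None,
    top_k: int = 10,
    max_candidates: int | None = 500,
) -> tuple[list[EntryCandidate], dict[str, int]]:
    """Rank candidate entry points for a fixed endpoint — a batch stand-in for
    interactively pivoting the trajectory around its endpoint.

    Evaluates the trajectory from the endpoint to brain-surface vertices
    (every vertex, or a deterministic evenly strided subsample of
    ``max_candidates``), drops rejected candidates and superficial-target
    misses, and returns the ``top_k`` by composite score descending.  Ties
    break toward larger vessel distance, then lower vertex index, so the
    ranking is deterministic and invariant to mesh vertex reordering up to
    exact ties.

    Returns the ranked list and a diagnostic count of reject reasons.
    """
    endpoint = np.asarray(endpoint, dtype=float).reshape(3)
    cfg = cfg or ScoringConfig()
    if not point_in_mesh(endpoint, brain):
        raise ValidationError("endpoint must lie inside the brain surface")
    n = brain.n_vertices
    if max_candidates is None or max_candidates >= n:
        candidate_idx = np.arange(n)
    else:
        stride = n / max_candidates
        candidate_idx = np.unique((np.arange(max_candidates) * stride).astype(int))
    grid = build_vertex_grid(vessels) if vessels.n_vertices else None
    counts = {REJECT_VESSEL: 0, REJECT_ANGLE: 0, REJECT_SUPERFICIAL: 0}
    kept: list[EntryCandidate] = []
    for vi in candidate_idx:
        v = brain.vertices[vi]
        if np.linalg.norm(v - endpoint) <= 1e-9:
            continue
        traj = Trajectory(name=f"candidate_{vi}", entry=v, endpoint=endpoint)
        rep = evaluate_trajectory(
            traj, brain, vessels,
            deep=None, superficial=None, cfg=cfg, grid=grid,
        )
        if superficial is not None and rep.accepted:
            if not _segment_passes(traj, superficial):
                rep.accepted = False
                rep.reject_reasons.append(REJECT_SUPERFICIAL)
        if rep.accepted:
            kept.append(EntryCandidate(vertex_index=int(vi), entry=v.copy(), report=rep))
        else:
            for reason in rep.reject_reasons:
                if reason in counts:
                    counts[reason] += 1
    kept.sort(key=lambda c: (-c.report.f, -c.report.d, c.vertex_index))
    return kept[:top_k], counts
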