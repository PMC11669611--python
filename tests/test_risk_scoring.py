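import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seegplan.anatomy_io import Plan, Trajectory, TriMesh
from seegplan.errors import ValidationError
from seegplan.phantom import PhantomSpec, capsule_min_distance, generate_scene
from seegplan.risk_scoring import (
    REJECT_ANGLE,
    REJECT_VESSEL,
    ScoringConfig,
    check_targets,
    evaluate_plan,
    evaluate_trajectory,
    insertion_angle_score,
    pairwise_clearance,
    quality_score,
    suggest_entries,
    vessel_distance_score,
    _segment_segment_distance,
)
from tests.conftest import icosphere


# ---------------------------------------------------------------------------
# Score functions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "d,expected",
    [(3.5, 0.5), (6.0, 1.0), (5.0, 1.0), (2.0, 0.0), (2.06, 0.02), (1.99, None), (0.0, None)],
)
def test_vessel_distance_score(d, expected):
    got = vessel_distance_score(d)
    if expected is None:
        assert got is None
    else:
        assert abs(got - expected) < 1e-12


@pytest.mark.parametrize(
    "alpha,expected",
    [(0.0, 1.0), (30.0, 0.0), (24.9, 0.17), (15.0, 0.5), (30.01, None), (90.0, None)],
)
def test_insertion_angle_score(alpha, expected):
    got = insertion_angle_score(alpha)
    if expected is None:
        assert got is None
    else:
        assert abs(got - expected) < 1e-12


def test_negative_inputs_rejected():
    with pytest.raises(ValidationError):
        vessel_distance_score(-0.1)
    with pytest.raises(ValidationError):
        insertion_angle_score(-1.0)


@pytest.mark.parametrize(
    "d,alpha,expected",
    [
        (2.06, 16.7, 0.105),
        (2.48, 17.7, 0.210),
        (3.56, 24.9, 0.450),
    ],
)
def test_quality_score_worked_examples(d, alpha, expected):
    """Observed planning examples reproduce to 3 decimals."""
    assert round(quality_score(d, alpha), 3) == expected


def test_quality_score_saturates():
    assert quality_score(6.0, 0.0) == 1.0
    assert quality_score(5.0, 0.0) == 1.0


def test_quality_score_rejects_propagate():
    assert quality_score(1.9, 0.0) is None
    assert quality_score(6.0, 31.0) is None
    assert quality_score(1.0, 45.0) is None


@settings(deadline=None, max_examples=200)
@given(
    d1=st.floats(2.0, 20.0),
    d2=st.floats(2.0, 20.0),
    a1=st.floats(0.0, 30.0),
    a2=st.floats(0.0, 30.0),
)
def test_score_monotonicity_and_range(d1, d2, a1, a2):
    """f_d non-decreasing in d, f_alpha non-increasing in alpha, f in [0,1]."""
    lo_d, hi_d = sorted([d1, d2])
    assert vessel_distance_score(lo_d) <= vessel_distance_score(hi_d) + 1e-12
    lo_a, hi_a = sorted([a1, a2])
    assert insertion_angle_score(lo_a) >= insertion_angle_score(hi_a) - 1e-12
    f = quality_score(d1, a1)
    assert 0.0 <= f <= 1.0
    # a perfect score requires full clearance credit and a (numerically)
    # perpendicular insertion
    if f == 1.0:
        assert d1 >= 5.0 and a1 < 1e-10
    if d1 >= 5.0 and a1 == 0.0:
        assert f == 1.0


def test_config_validation():
    with pytest.raises(ValidationError):
        ScoringConfig(d_reject=5, d_plateau=2)
    with pytest.raises(ValidationError):
        ScoringConfig(w_d=0.7, w_alpha=0.2)
    with pytest.raises(ValidationError):
        ScoringConfig(alpha_max=0)


def test_config_from_yaml(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("d_plateau: 8\nw_d: 0.6\nw_alpha: 0.4\n")
    cfg = ScoringConfig.from_file(p)
    assert cfg.d_plateau == 8 and cfg.w_d == 0.6
    p.write_text("no_such_key: 1\n")
    with pytest.raises(ValidationError):
        ScoringConfig.from_file(p)


# ---------------------------------------------------------------------------
# Target checks
# ---------------------------------------------------------------------------


def small_sphere(center, r=5.0, name="target"):
    m = icosphere(subdivisions=2, radius=1.0, name=name)
    return TriMesh(m.vertices * r + np.asarray(center, float), m.faces, name=name)


def test_check_targets_reach_and_pass():
    deep = small_sphere([0, 0, 0], name="deep")
    sup = small_sphere([0, 0, 30], name="sup")
    t = Trajectory("T", entry=[0, 0, 60], endpoint=[0, 0, 0])
    tc = check_targets(t, deep, sup)
    assert tc.reaches_deep and tc.passes_superficial


def test_check_targets_misses():
    deep = small_sphere([0, 0, 0], name="deep")
    sup = small_sphere([30, 0, 30], name="sup")  # off the trajectory
    t = Trajectory("T", entry=[0, 0, 60], endpoint=[0, 0, 1])
    tc = check_targets(t, deep, sup)
    assert tc.reaches_deep
    assert not tc.passes_superficial
    t2 = Trajectory("T2", entry=[0, 0, 60], endpoint=[0, 0, 20])  # stops short of deep
    assert not check_targets(t2, deep, sup).reaches_deep


def test_check_targets_same_region():
    """Superficial target equal to the deep target: passage follows from reach."""
    region = small_sphere([0, 0, 10], name="Temporal_Pole_Mid_L")
    t = Trajectory("T2", entry=[0, 0, 60], endpoint=[0, 0, 10])
    tc = check_targets(t, region, region)
    assert tc.reaches_deep and tc.passes_superficial


# ---------------------------------------------------------------------------
# Trajectory and plan evaluation
# ---------------------------------------------------------------------------


def test_evaluate_engineered_trajectory(sphere_scene):
    """Recover the engineered clearance and analytic angle within tolerance."""
    scene = sphere_scene
    t1 = scene.demo_plan.trajectories[0]
    rep = evaluate_trajectory(t1, scene.brain, scene.vessels)
    truth = scene.truth_table["T1"]
    assert rep.accepted
    assert abs(rep.d - truth["d_mm"]) < 2 * scene.vessels.max_edge_length()
    assert abs(rep.alpha - truth["alpha_deg"]) < 2.0
    f_true = 0.8 * (truth["d_mm"] - 2) / 3 + 0.2 * (30 - truth["alpha_deg"]) / 30
    assert abs(rep.f - f_true) < 0.08


def test_trajectory_through_vessel_rejected(scene):
    """Aim straight at the engineered vessel midline: d = 0, reject."""
    pl = scene.vessel_truth.polylines[0]
    mid = 0.5 * (pl[0] + pl[-1])
    axis = pl[-1] - pl[0]
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    t = Trajectory("through", entry=mid + 40 * perp, endpoint=mid - 5 * perp)
    rep = evaluate_trajectory(t, scene.brain, scene.vessels)
    assert not rep.accepted
    assert REJECT_VESSEL in rep.reject_reasons
    assert rep.f is None


def test_steep_trajectory_rejected(brain_sphere):
    """A near-tangential chord enters at > 30 deg to the surface normal."""
    vessels = TriMesh(np.array([[500.0, 0, 0]]), np.empty((0, 3), int), name="far")
    a = 0.95 * 70
    endpoint = np.array([a, 0.0, 0.0])
    direction = np.array([0.0, 1.0, 0.0])  # sin(alpha) = 0.95 -> alpha ~ 71.8 deg
    t = Trajectory("steep", entry=endpoint + 100 * direction, endpoint=endpoint)
    rep = evaluate_trajectory(t, brain_sphere, vessels)
    assert REJECT_ANGLE in rep.reject_reasons
    assert not rep.accepted


def test_all_reject_reasons_accumulate(scene):
    """A trajectory violating several constraints reports every reason."""
    pl = scene.vessel_truth.polylines[0]
    mid = 0.5 * (pl[0] + pl[-1])
    deep = small_sphere([0, 0, -40], name="deep")
    sup = small_sphere([0, 40, 0], name="sup")
    t = Trajectory(
        "bad", entry=mid + 60 * np.array([0.9, 0.1, 0.0]), endpoint=mid,
        deep_target="deep", superficial_target="sup",
    )
    rep = evaluate_trajectory(t, scene.brain, scene.vessels, deep, sup)
    assert len(rep.reject_reasons) >= 2  # at least vessel + both target misses


def test_evaluate_plan_mean_identity(scene):
    rep = evaluate_plan(scene.demo_plan, scene.brain, scene.vessels, scene.targets)
    assert len(rep.reports) == 7
    accepted = [r.f for r in rep.reports if r.accepted]
    assert abs(rep.mean_score - float(np.mean(accepted))) < 1e-12


def test_plan_mean_over_accepted_only(scene):
    """Rejected trajectories are excluded from the plan mean."""
    pl = scene.vessel_truth.polylines[0]
    mid = 0.5 * (pl[0] + pl[-1])
    good = scene.demo_plan.trajectories[2]
    bad = Trajectory("bad", entry=mid + np.array([40.0, 1.0, 0]), endpoint=mid)
    plan = Plan(trajectories=[good, bad], space="patient_mm", scale_factor=6.0)
    rep = evaluate_plan(plan, scene.brain, scene.vessels)
    assert rep.n_accepted == 1 and rep.n_rejected == 1
    assert abs(rep.mean_score - rep.reports[0].f) < 1e-12


def test_empty_plan_mean_undefined(scene):
    rep = evaluate_plan(Plan(trajectories=[]), scene.brain, scene.vessels)
    assert rep.mean_score is None and rep.reports == []


def test_world_plan_autoconverted(scene):
    """World-space plans score identically after conversion to patient mm."""
    world = scene.demo_plan.to_space("world_mm")
    rep_w = evaluate_plan(world, scene.brain, scene.vessels)
    rep_p = evaluate_plan(scene.demo_plan, scene.brain, scene.vessels)
    for a, b in zip(rep_w.reports, rep_p.reports):
        assert abs(a.d - b.d) < 1e-9
        assert abs(a.alpha - b.alpha) < 1e-9


# ---------------------------------------------------------------------------
# Pairwise clearance
# ---------------------------------------------------------------------------


def test_parallel_segments_clearance():
    a = Trajectory("A", entry=[0, 0, 0], endpoint=[10, 0, 0])
    b = Trajectory("B", entry=[0, 10, 0], endpoint=[10, 10, 0])
    mat, warn = pairwise_clearance([a, b])
    assert abs(mat[0, 1] - 10.0) < 1e-12
    assert warn == []


def test_crossing_segments_warn():
    a = Trajectory("A", entry=[-5, 0, 0], endpoint=[5, 0, 0])
    b = Trajectory("B", entry=[0, -5, 0], endpoint=[0, 5, 0])
    mat, warn = pairwise_clearance([a, b])
    assert mat[0, 1] < 1e-12
    assert warn and warn[0][:2] == ("A", "B")


def test_segment_distance_matches_dense_sampling():
    """Closed-form segment distance vs coarse-to-fine dense parameter sampling."""
    rng = np.random.default_rng(21)

    def dense_min(p1, q1, p2, q2):
        lo1, hi1, lo2, hi2 = 0.0, 1.0, 0.0, 1.0
        best = np.inf
        for _ in range(4):  # refine 60x60 grid around the argmin
            t1 = np.linspace(lo1, hi1, 60)
            t2 = np.linspace(lo2, hi2, 60)
            s1 = p1[None, :] + t1[:, None] * (q1 - p1)[None, :]
            s2 = p2[None, :] + t2[:, None] * (q2 - p2)[None, :]
            dmat = np.linalg.norm(s1[:, None, :] - s2[None, :, :], axis=2)
            i, j = np.unravel_index(np.argmin(dmat), dmat.shape)
            best = min(best, float(dmat[i, j]))
            w1, w2 = (hi1 - lo1) / 10, (hi2 - lo2) / 10
            lo1, hi1 = max(0.0, t1[i] - w1), min(1.0, t1[i] + w1)
            lo2, hi2 = max(0.0, t2[j] - w2), min(1.0, t2[j] + w2)
        return best

    for _ in range(100):
        p1, q1, p2, q2 = rng.uniform(-20, 20, size=(4, 3))
        d = _segment_segment_distance(p1, q1, p2, q2)
        dense = dense_min(p1, q1, p2, q2)
        assert d <= dense + 1e-12
        assert dense - d < 1e-3


# ---------------------------------------------------------------------------
# Entry suggestion
# ---------------------------------------------------------------------------


def test_suggest_radial_when_unobstructed():
    """With no nearby vessels the best entry is the most perpendicular one."""
    brain = icosphere(subdivisions=3, radius=70.0, name="brain")
    vessels = TriMesh(np.array([[500.0, 0, 0]]), np.empty((0, 3), int), name="far")
    ranked, counts = suggest_entries(
        np.zeros(3), brain, vessels, top_k=3, max_candidates=100,
        cfg=ScoringConfig(n_key_points=25),
    )
    assert ranked
    assert ranked[0].report.alpha < 5.0
    assert ranked[0].report.f > 0.95


def test_suggest_avoids_blocked_hemisphere():
    """A dense vessel shell over +x forces all suggested entries to the far side."""
    brain = icosphere(subdivisions=3, radius=70.0, name="brain")
    shell = icosphere(subdivisions=4, radius=40.0)  # ~5 mm vertex spacing
    mask = shell.vertices[:, 0] > 2.0
    vessels = TriMesh(shell.vertices[mask], np.empty((0, 3), int), name="wall")
    ranked, counts = suggest_entries(
        np.zeros(3), brain, vessels, top_k=8, max_candidates=150,
        cfg=ScoringConfig(n_key_points=25),
    )
    assert ranked
    for c in ranked:
        assert c.entry[0] <= 0
        assert c.report.d > 5.0  # well clear of the blocked side


def test_suggest_ranking_stable_under_vertex_reorder():
    """Same candidate entries after permuting mesh vertices (no exact score ties:
    asymmetric endpoint and vessels make every candidate's f unique)."""
    brain = icosphere(subdivisions=2, radius=70.0, name="brain")
    vessels = TriMesh(
        np.array([[30.0, 10.0, 0.0], [-12.0, 25.0, 8.0], [5.0, -28.0, -15.0]]),
        np.empty((0, 3), int),
        name="v",
    )
    endpoint = np.array([4.0, -3.0, 2.5])
    cfg = ScoringConfig(n_key_points=25)
    ranked, _ = suggest_entries(endpoint, brain, vessels, top_k=5, max_candidates=None, cfg=cfg)
    fs = [c.report.f for c in ranked]
    assert len(set(fs)) == len(fs)  # genuinely untied
    rng = np.random.default_rng(9)
    perm = rng.permutation(brain.n_vertices)
    inv = np.argsort(perm)
    brain2 = TriMesh(brain.vertices[perm], inv[brain.faces], name="brain")
    ranked2, _ = suggest_entries(endpoint, brain2, vessels, top_k=5, max_candidates=None, cfg=cfg)
    got = [tuple(np.round(c.entry, 6)) for c in ranked]
    got2 = [tuple(np.round(c.entry, 6)) for c in ranked2]
    assert got == got2


def test_suggest_endpoint_outside_rejected():
    brain = icosphere(subdivisions=2, radius=70.0, name="brain")
    vessels = TriMesh(np.array([[0.0, 0, 0]]), np.empty((0, 3), int))
    with pytest.raises(ValidationError):
        suggest_entries(np.array([200.0, 0, 0]), brain, vessels)
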