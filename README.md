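# seegplan

Headless planning geometry and risk scoring for **stereoelectroencephalography
(SEEG)** electrode trajectories.

In SEEG, a dozen or more straight electrodes are implanted through the skull
to localise the seizure onset zone. Each trajectory must end inside a *deep
target* region, pass through a *superficial target* on its way, keep a safe
margin from blood vessels, and meet the brain surface at a shallow angle so
the keyhole drill does not skive. `seegplan` implements this geometry as a
library plus CLI, for people building or evaluating planning front-ends
(VR/desktop) who need the scoring backend without any rendering stack:
surgeons' plans go in as meshes plus a JSON file of trajectories, and
per-trajectory risk metrics come out.

## The quality score

For each trajectory the library computes the minimum distance *d* (mm) from
125 uniformly spaced key points along the electrode to the vasculature model,
and the insertion angle *α* (degrees) between the trajectory and the outward
brain-surface normal at the entry point. These map to sub-scores

```
f_d = reject            if d < 2 mm
    = (d − 2) / (5 − 2) if 2 mm ≤ d ≤ 5 mm
    = 1                 if d > 5 mm

f_α = reject            if α > 30°
    = (30 − α) / 30     if α ≤ 30°
```

and combine, weighting hemorrhage risk highest, into

```
f = 0.8 f_d + 0.2 f_α        ∈ [0, 1]
```

A plan's score is the mean of *f* over its accepted trajectories. The key-point
nearest-vertex queries run on a spatial hash grid with an expanding-shell
search that is provably exact (it matches a brute-force scan to 1e-9 mm).

Because real MRI-derived meshes cannot ship with the package, a seeded
phantom generator builds brain-like surfaces, tubular vessels with analytic
capsule ground truth, ellipsoidal targets, and a seven-trajectory demo plan,
so every geometric claim is testable against closed-form answers.

## Worked example

```
$ seegplan phantom --seed 0 --out scene/
wrote phantom scene (seed 0) to scene

$ seegplan score --brain scene/brain.obj --vessels scene/vessels.obj \
    --plan scene/plan.json --targets-dir scene/targets --report report.json
7 trajectories: 7 accepted, 0 rejected; mean quality score = 0.876
report written to report.json
```

`report.json` holds one record per trajectory — for example trajectory `T1`,
which the generator engineers to lie exactly 4 mm from a dedicated vessel:

```json
{
  "name": "T1", "d_mm": 4.0000, "alpha_deg": 8.32,
  "f_d": 0.667, "f_alpha": 0.723, "f": 0.678,
  "accepted": true, "reject_reasons": []
}
```

Reading: 4 mm clearance sits two-thirds of the way up the 2–5 mm ramp
(f_d = 0.667), an 8.3° insertion is comfortably under the 30° limit
(f_α = 0.723), and the composite is 0.8·0.667 + 0.2·0.723 = 0.678. The
plan-level `mean_score` of 0.876 is the arithmetic mean of the seven accepted
composite scores. Rejected trajectories would instead carry `reject_reasons`
(`vessel_too_close`, `angle_too_steep`, `misses_deep_target`,
`misses_superficial_target`) and no composite score.

Other commands: `seegplan suggest` ranks candidate entry points for a fixed
endpoint (a batch stand-in for interactively pivoting the electrode),
`seegplan convert` maps plans between patient and 6×-enlarged model
coordinates, and `seegplan sus` / `seegplan tlx` score usability-study
questionnaires (System Usability Scale; raw NASA-TLX normalised to 0–100).

The same functionality is available as a library:

```python
from seegplan import PhantomSpec, generate_scene, evaluate_plan, quality_score

scene = generate_scene(PhantomSpec(seed=0))
report = evaluate_plan(scene.demo_plan, scene.brain, scene.vessels, scene.targets)
print(report.mean_score)          # 0.876...
print(quality_score(3.56, 24.9))  # 0.450...
```

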