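# craniotome

A headless Python toolkit implementing the computational core of a
virtual-reality craniotomy-training simulator for intracranial-aneurysm
surgery. It targets researchers in surgical simulation and computational
anatomy who need the *algorithms* of such a trainer — reproducible,
scriptable, and testable — without a game engine or headset:

- **phantom** — deterministic synthetic anatomy: a watertight two-table
  skull shell, a brain split into frontal and temporal lobes at a planar
  Sylvian-fissure stand-in, a Circle-of-Willis polyline with configurable
  M1 length, optic-nerve/pterion landmarks, and four drawing-template
  contours (2 locations × 2 line widths) on the outer skull;
- **pose** — clamped two-axis head inclination (longitudinal ±90°,
  transversal ±30°) applied as a rigid transform about the head clamp;
- **craniotomy** — a freehand contour is projected onto the skull's outer
  table, the mesh edges it crosses become a barrier, the enclosed patch is
  selected by region growing from a seed face and excised;
- **exposure** — ray-sampled visibility of an intracranial target through
  the hole toward a microscope eye, plus trajectory clearance and hole area;
- **retraction** — mass-spring lobe retraction with position-Verlet
  integration and a displacement-controlled spatula;
- **metrics** — contour-precision scores between a drawn contour `A` and a
  template `B`:

  surface DSC = 2·TP / (2·TP + FP + FN), with TP/FP/FN defined by a
  distance tolerance τ between arc-length samples of one contour and the
  other polyline, and the symmetric Hausdorff distance

  H(A, B) = max( h(A, B), h(B, A) ),  h(A, B) = max_{a∈A} min_{b∈B} ‖a − b‖.

All lengths are millimetres; the shared frame is right-handed, patient
supine: +x left, +y superior, +z anterior.

## Worked example

```python
import numpy as np
import craniotome as ct
from craniotome.geom import closest_point_on_mesh

scene = ct.generate_phantom(ct.PhantomConfig(seed=1))
target = ct.place_target(scene, 0.6)          # on the vessel, 60% arc length

pose = ct.clamp_pose(120, 45)                  # requests beyond the limits
print(pose.longitudinal_deg, pose.transversal_deg)   # -> 90.0 30.0

# trace the first template as the drawn contour and perform the craniotomy;
# the growing seed is the outer-table point closest to the contour centroid
mask = ct.outer_surface_faces(scene.skull)
proj = ct.project_contour(scene.skull, scene.templates[0], outer_faces=mask)
seed, _, _ = closest_point_on_mesh(
    scene.skull.vertices, scene.skull.faces[np.flatnonzero(mask)],
    proj.contour.points.mean(axis=0)[None])
region = ct.region_grow(scene.skull, proj, seed[0], outer_faces=mask)
print(len(region.face_ids), round(region.area_mm2, 1))   # -> 40 674.8

hole = ct.through_cut(scene.skull, region, outer_faces=mask)
view = ct.MicroscopeView(eye=target.position + 300*(seed[0]-target.position)
                         / np.linalg.norm(seed[0]-target.position),
                         look_at=target.position)
print(ct.evaluate_exposure(hole, target, view, n_rays=500, seed=1).visible_fraction)
# -> 1.0   (0.0 on the intact skull: the hole exposes the target)

report = ct.evaluate_drawing(proj.contour, scene.templates[0])
print(report.surface_dsc, round(report.hausdorff_mm, 6))  # -> 1.0 0.0
```

A perfect trace of the template scores surface DSC 1.0 and Hausdorff
≈ 0 mm; the 674.8 mm² patch is the bone flap enclosed by the 15 mm-radius
template circle (the spherical-cap area is 706 mm²; the difference is the
face-granular barrier).

The same workflow is available from the shell:

```bash
craniotome phantom --out scene/ --seed 1
craniotome run --config run.yaml --out run1/   # pose→cut→expose→retract→evaluate
```

`run` writes every stage artifact plus `manifest.json` with content
hashes; re-running the same config reproduces identical hashes.

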