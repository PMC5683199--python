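# endogeo

Geometry-aware augmented reality for stereo endoscopy, as an offline,
testable Python pipeline.

In minimally invasive surgery an AR overlay is only as good as the
geometry behind it: annotations pinned to 2D features drift out of view,
and content mapped onto fitted planes misrepresents curved organ
surfaces. `endogeo` tracks a stereo endoscope and reconstructs a dense,
metric surface mesh of the scene *while tracking*, so labels can stick to
tissue with correct orientation, distances can be measured **along** the
curved surface, and highlighted regions have physical areas in mm² — no
preoperative scan or template required.

The pipeline:

1. **Stereo features** — ORB keypoints matched left↔right (mutual
   Hamming, epipolar row filter), sub-pixel disparity by 1D ZNCC
   refinement, saturated specular keypoints removed. Depth from the
   rectified-stereo relation `Z = f·B/d`.
2. **Tracking** — constant-velocity pose prediction
   (`r_{t+1} = r_t + v_t Δt`, `q_{t+1} = q_t ⊗ q(ω_t Δt)`), guided
   landmark search by re-projection, 3-point RANSAC rigid alignment
   (`min Σ ‖p_t − (R p_{t+1} + T)‖`) with closed-form Kabsch refinement,
   then motion-only Huber reprojection refinement.
3. **Mapping** — keyframes inserted when shared keypoints drop below 80%
   with more than 50 tracked; windowed bundle adjustment minimising the
   Huber-robust reprojection cost
   `Σ ρ_h(‖p_ij − CamProj(KF_i, P_j)‖)` over stereo observations.
4. **Dense stereo** — per-keyframe ZNCC cost volume (box-filtered),
   winner-takes-all with sub-pixel fit, left-right/confidence/speckle
   masking, Huber-L1 variational smoothing.
5. **Surface** — clouds moved to world space by the SLAM poses, fused on
   a 1 mm voxel grid, triangulated into the global mesh.
6. **Overlay** — ray picking, z-buffered mesh re-projection,
   surface-anchored labels, geodesic measurement and area highlighting.

A synthetic-scene generator (analytic liver-scale surface, procedural
texture, camera-co-located spot light with strong speculars, hovering
trajectory) provides exact ground-truth poses and depth for every rendered
frame, and the evaluation suite computes the grid-sampled surface RMSD
and absolute trajectory error against it.

## Worked example

```python
import numpy as np
from endogeo import synth
from endogeo.pipeline import PipelineConfig, StereoSlamPipeline

rig = synth.default_rig()                    # f=500 px, B=5 mm, 840x640
scene = synth.generate_scene(seed=1)         # liver-scale specular scene
trajectory = synth.hover_trajectory(60)

pipe = StereoSlamPipeline(rig, PipelineConfig(seed=1))
true_poses = []
for frame in synth.iter_frames(scene, trajectory, rig):
    pipe.feed(frame.left, frame.right)
    true_poses.append(frame.pose)
report = pipe.finalise()

rms_t, rms_r = synth.trajectory_error(
    pipe.trajectory, [true_poses[i] for i in pipe.trajectory_frames])
grid = synth.sample_evaluation_grid(scene, pipe.mesh.vertices)
rmsd, coverage = synth.rmsd_surfaces(grid)
print(f"tracked {report.n_tracked}/{report.n_frames} frames, "
      f"{report.n_keyframes} keyframes")
print(f"trajectory RMS {rms_t:.2f} mm / {rms_r:.2f} deg")
print(f"surface RMSD {rmsd:.2f} mm (coverage {coverage:.0%})")
```

Output on this machine:

```
tracked 60/60 frames, 19 keyframes
trajectory RMS 0.44 mm / 0.82 deg
surface RMSD 0.66 mm (coverage 96%)
```

Every frame was tracked; the recovered camera path deviates from the
known trajectory by 0.44 mm RMS, and the fused mesh sits within 0.66 mm
RMS of the true surface over the 96% of the evaluation grid it covers.
(The uncovered 4% is mostly the saturated specular highlight, which sits
at the view centre because the light rides on the camera — dense
matching correctly refuses it.)

With the mesh in hand, the AR operations work in world units:

```python
from endogeo.overlay import pick, place_label, measure_on_surface

anchor_a = pick((300, 200), pipe.trajectory[-1], rig, pipe.mesh)
anchor_b = pick((560, 420), pipe.trajectory[-1], rig, pipe.mesh)
label = place_label(anchor_a, payload="resection margin")
path = measure_on_surface(anchor_a, anchor_b, pipe.mesh)
print(f"on-surface distance {path.length:.1f} mm (chord {path.chord:.1f} mm)")
# -> on-surface distance 65.8 mm (chord 59.6 mm)
```

A command-line interface covers batch runs on image directories and mesh
measurement:

```bash
endogeo run --calib calib.yaml --frames dataset/ --out results/ [--global-ba] [--seed N]
endogeo measure --mesh results/mesh.ply --from 0,0,95 --to 20,10,95
```

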