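# spinetrack

Qualitative motion analysis of the cervical spine in dynamic X-ray
(videofluoroscopy) recordings.

Cervical motion is usually summarized by segmental range of motion, a
metric with high inter-individual variability that only looks at static
endpoints.  A more informative description is the *sequence of segmental
contribution* (SSC): during an extension sweep, each motion segment
(a pair of adjacent vertebrae, e.g. C4–C5) shows a peak in its relative
rotation at a characteristic point of the cumulative motion, and the
order of those peaks is a consistent, clinically discriminative pattern.
Extracting it by hand requires frame-by-frame annotation of every
vertebra, which is what makes the analysis impractical — this package
automates it.

The pipeline:

1. **Segmentation** — a multi-class U-Net (2D, or 2D+t taking k
   consecutive frames and predicting the middle one) labels vertebrae
   C0–C7 plus background in every frame.  Training minimizes a
   class-weighted Dice loss,
   `L_c = 1 − 2 Σ p·g / (Σ p² + Σ g²)` with weights `W_c = 1/(Σ g)²`,
   to counter the extreme foreground/background imbalance.  The network
   and its training loop are implemented in NumPy.
2. **Thresholding** — per-vertebra binarization thresholds (0.1–0.9)
   chosen on the validation set by maximal F1 along the
   precision–recall curve; only the largest 8-connected component is
   kept.
3. **Mean shape** — vertebrae are rigid, so one binary template per
   vertebra per recording is built by rotationally aligning and
   averaging the per-frame segmentations.
4. **Tracking** — the mean shape is placed on each frame's segmentation
   centroid and rotated (coarse-to-fine grid search) until the overlap
   (IoU) is maximal, giving the orientation θ_C(t).
5. **Motion analysis** — relative rotations
   `dθ_C(t) = θ_C(t) − θ_C(t−1)` and segmental relative rotations
   `dθ_R = dθ_Ck − dθ_Cl`, outlier/exclusion rules, and the SSC.
6. **Evaluation** — IoU/DSC against reference masks, per-recording
   two-way mixed consistency ICC(3,1) of the trajectories, and Wilcoxon
   signed-rank comparisons between model variants.

Clinical recordings are private, so the package includes a seeded
synthetic-recording generator (rigid vertebra-like shapes, configurable
segmental kinematics, noise/contrast/occlusion) with exact ground-truth
masks and angles; the whole pipeline is validated closed-loop against
it.  See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a synthetic extension recording, track C4–C7 from its
ground-truth masks, and recover the configured contribution sequence:

```python
import numpy as np
from spinetrack import (KinematicsConfig, make_recording, build_mean_shape,
                        track_recording, vertebra_rotation_series,
                        icc_two_way_mixed, contribution_sequence)
from spinetrack.motion import segment_trajectories

cfg = KinematicsConfig(seed=7, n_frames=20, total_rom_deg=24.0,
                       segment_peak_order=("C6-C7", "C5-C6", "C4-C5"),
                       segment_amplitudes_deg={"C6-C7": 3.0, "C5-C6": 3.0, "C4-C5": 3.0},
                       image_size=(256, 192), vertebra_height_px=22.0, spacing_px=28.0)
rec, ann = make_recording(cfg)
frames = list(range(cfg.n_frames))
trajs = {}
for lab in ("C4", "C5", "C6", "C7"):
    shape = build_mean_shape(ann.masks[lab], label=lab)
    fits = track_recording(shape, ann.masks[lab])
    trajs[lab] = vertebra_rotation_series([f.angle_deg for f in fits], frames,
                                          n_frames=cfg.n_frames, label=lab)
    true_dtheta = np.diff(ann.true_angle_deg[lab], prepend=ann.true_angle_deg[lab][0])
    icc = icc_two_way_mixed(true_dtheta[1:], trajs[lab].dtheta_deg[1:])
    print(f"{lab}: relative-rotation ICC vs ground truth = {icc:.3f}")
order = contribution_sequence(segment_trajectories(trajs), trajs)
print("sequence of segmental contribution:", " -> ".join(order.order))
```

Output:

```
C4: relative-rotation ICC vs ground truth = 0.952
C5: relative-rotation ICC vs ground truth = 0.982
C6: relative-rotation ICC vs ground truth = 0.934
C7: relative-rotation ICC vs ground truth = 0.878
sequence of segmental contribution: C6-C7 -> C5-C6 -> C4-C5
```

The ICCs compare each tracked relative-rotation trajectory with the
exact simulated one (1.0 would be perfect agreement; at this small
22 px template scale the rasterization noise keeps them just below it),
and the recovered peak order matches the configured kinematics.

The end-to-end pipeline — simulation, training, thresholding, tracking,
reporting — runs from one configuration:

```bash
spinetrack run-all --config examples/desk.yaml --out run/ --seed 0
# or stage by stage: spinetrack simulate / split / train / predict /
#                    threshold / analyze / evaluate --out run/
```

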