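# gaitblur

Does blurring faces in video degrade markerless, 3D-pose-based gait
analysis? `gaitblur` implements the full computational chain needed to ask
that question quantitatively, and exercises it end-to-end on a synthetic
gait cohort:

* **face anonymization** — reference head (H) and neck (N) annotations are
  projected through calibrated pinhole cameras, a circle of radius
  `scale · ‖H_px − N_px‖` centred on the projected head delimits the face,
  and pixels strictly inside it are Gaussian-blurred (25×25 kernel,
  σ = 0.3·((k−1)·0.5 − 1) + 0.8 = 4.1 by default). Pixels outside the circle
  are bit-identical before and after.
* **kinematics** — 11 clinical joint angles from a 17-keypoint body model:
  shoulder flexion/abduction via intrinsic Z–X′–Y″ Euler decomposition of
  the humerus frame relative to the trunk frame, elbow and knee flexion as
  segment angles, neck flexion/side-bend, femur and hip angles in the trunk
  sagittal/frontal planes, pelvis obliquity, ankle flexion.
* **metrics** — MPJPE = mean over frames and keypoints of
  ‖Ĵ_k − J_k‖; per keypoint-group error summaries (μ, 2σ); joint-angle RMSE
  per subject and pooled; effect strength as Δ = max − min across
  experimental conditions; the acceptability rule Δ_SD < 5°/(1.96×2) = 1.27°.
* **statistics** — one-way repeated-measures ANOVA (sphericity assumed) on
  per-subject angle RMSEs across three conditions, strict p < 0.05.
* **synthetic data** — a forward-kinematic walking generator with known
  ground-truth angle profiles, a four-camera ring rig, stick-figure
  rendering, and pose-estimate noise whose per-keypoint mean error
  magnitude is calibrated to published per-condition values
  (isotropic Gaussian; mean error norm = 2σ√(2/π)).

It is written for biomechanics / computer-vision researchers who want a
reproducible, dataset-free harness for anonymization-vs-kinematics
questions, with every stage available both as a library and as a CLI.

## Worked example

```python
import gaitblur as gb

# published Δ arithmetic, recomputed from the printed per-condition values
report = gb.verify_published_deltas()
print(report["ok"].all())                     # True (35 cells)

# synthetic three-condition experiment, 4 subjects, 2 gait cycles each
cfg = gb.ExperimentConfig(n_subjects=4, gait=gb.GaitConfig(n_cycles=2),
                          master_seed=1)
res = gb.run_experiment(cfg, out_dir="run1")
print(res.angle_table[["delta_rmse_deg", "delta_sd_deg"]].round(3))
print(res.acceptability.round(3).head(3))
```

prints (abridged):

```
                    delta_rmse_deg  delta_sd_deg
angle
shoulder_flexion             0.101         0.101
shoulder_abduction           0.181         0.183
elbow_flexion                0.048         0.017
...
                  delta_sd_deg  threshold_deg  acceptable
angle
shoulder_flexion         0.101           1.27        True
shoulder_abduction       0.183           1.27        True
elbow_flexion            0.017           1.27        True
```

Reading: across the three simulated conditions (noise calibrated to the
error magnitudes of a blurred-trained, a blurred-finetuned and an
unblurred-control pose estimator), the pooled RMSE of every joint angle
varies by well under 1°, and every Δ of the difference SD stays below the
1.27° acceptability threshold — face blurring leaves the kinematic analysis
intact at these error levels.

The same stages are available as subcommands:

```bash
gaitblur simulate --frames 200 --out traj.csv --truth-out truth.csv
gaitblur angles --trajectory traj.csv --side mean --out angles.csv
gaitblur run-all --seed 1 --subjects 4 --out run1/
gaitblur verify-published
```

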