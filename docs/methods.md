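# Methods

## The question and the experimental design

Markerless gait analysis estimates 3D body keypoints from multi-camera
video and derives clinical joint angles from them. Publishing or sharing
such video requires face anonymization, and the question is whether
blurring faces measurably degrades the downstream kinematics. The design
this package mirrors is a within-subject comparison of three conditions —
a pose estimator trained on face-blurred images, one finetuned on blurred
images, and an unblurred control — evaluated against a marker-based
reference on a 16-subject test set. Two effect measures are used: the
statistical significance of the condition factor (one-way repeated-measures
ANOVA on per-subject angle RMSEs) and the effect strength
Δ = max − min of an error statistic across the three conditions.

Training pose estimators is out of scope here. The three conditions are
represented by calibrated noise models: each condition perturbs the
reference keypoints with isotropic Gaussian noise whose per-keypoint mean
error magnitude equals that condition's published per-group error (head
11.1/13.3/13.8 mm across the three conditions, and so on; see
`gaitblur/published.py`). Everything downstream of pose estimation —
anonymization geometry, angles, metrics, statistics — is implemented in
full.

## World and body model

Right-handed world frame, Y up, millimetres, gait along +Z; the subject
faces +Z so the right body side lies at world +X. The body model has 17
keypoints (head, neck, shoulders, elbows, wrists, pelvis centre, hips,
knees, ankles, feet). Reporting groups pair left/right keypoints (feet,
ankles, knees, hips, wrists, elbows, shoulders) with pelvis, neck and head
as singletons.

## Synthetic gait generator

`generate_gait_sequence` builds walking by forward kinematics from
sinusoidal joint-angle profiles, so ground truth is known exactly:

* femur (hip) flexion `A_hip·sin(2πφ)`, ankle flexion `A_ank·sin(2πφ)`,
  arm swing `−A_arm·sin(2πφ)` (anti-phase to the ipsilateral leg); the left
  side is shifted by half a cycle;
* knee flexion uses the raised cosine `A_knee·(1 − cos 2πφ)/2`, which keeps
  it non-negative with peak `A_knee` — the analyzer's knee angle is
  unsigned, so a signed sinusoid would not round-trip;
* the elbow holds `35° ± 10°`-style profiles with a strictly positive
  minimum: a perfectly straight arm leaves the humerus–forearm plane, and
  with it the shoulder frame, undefined;
* pelvis obliquity rolls the hip line about the walking axis;
* the pelvis translates along +Z at the walking speed; the trunk stays
  vertical, so the trunk frame is world-aligned and every profile above is
  recovered by the analyzer exactly (float precision) — the 0.1° round-trip
  tolerance in the tests is pure headroom.

Defaults (adult scale, chosen once): pelvis width 240 mm, trunk length
(HC→N) 500 mm, neck drop to the shoulder line 80 mm, N→H 200 mm, shoulder
width 380 mm, upper arm 280 mm, forearm 250 mm, thigh 420 mm, shank
400 mm, foot 150 mm; cycle 1.1 s, 60 Hz, 1200 mm/s, amplitudes
hip 30°, knee 60°, ankle 15°, arm 20°, elbow 30±10°, neck 5°, pelvis roll
4°. `shoulder_width` and the elbow profile are generator necessities rather
than gait literature values; all are configurable. A cohort varies
anthropometry by a per-subject uniform scale factor (σ = 5%, clipped to
[0.5, 1.5]) and a random initial gait phase.

What the generator does **not** emulate: real joint-angle waveforms,
double-support timing, soft-tissue artefact, pathology-specific gait
(the original cohort included skeletal-disease patients), occlusion- or
view-dependent estimation error, and temporally correlated error. Passing
tests therefore demonstrate correctness of the analysis chain under
controlled conditions, not validity of any biomechanical claim about real
gait.

## Noise model

Estimated keypoint = reference + ε, ε i.i.d. per frame/keypoint from an
isotropic 3D Gaussian. The error norm then follows a Maxwell distribution
with mean 2σ√(2/π), so a target mean error magnitude μ maps to per-axis
σ = μ/(2√(2/π)). Published tables report only the mean and spread of error
norms, which this two-parameter family matches in mean; it cannot (and does
not try to) match the published 2σ spreads simultaneously, since for a
Maxwell distribution the spread is tied to the mean.

## Anonymization

Projection is the homogeneous pinhole map x = K(RX + t) with perspective
division; 0-based pixel coordinates with integer pixel centres; lens
distortion is not modelled and non-zero distortion coefficients in a
calibration file raise an explicit unsupported-feature error. The face
circle is centred at the projected H with radius `scale·‖H_px − N_px‖`
(default scale 1.0) — the head-neck distance is the only scale cue the two
landmarks provide — and is recomputed per frame so it follows the
projections. The blur is a separable truncated Gaussian (half-width
(k−1)/2, renormalised, reflective border), applied only to pixels whose
centres lie strictly inside the circle, with a hard edge and no feathering;
integer images are rounded half-to-even back to their dtype, so a constant
region changes by at most one grey level. The default σ follows the
kernel-size rule 0.3·((k−1)·0.5 − 1) + 0.8, i.e. 4.1 at k = 25.

## Joint angles

Trunk frame: origin HC, Y = normalize(N − HC), X = normalize(Y × (HL − HR))
(anterior), Z = X × Y. Shoulder frame: origin S, Y = normalize(S − E)
(proximal along the humerus), X = normalize(Y × (W − E)) (normal to the
arm plane), Z = X × Y; a straight arm falls back to the trunk X axis to
resolve the plane (logged). Shoulder flexion/abduction are the Z and X
angles of the intrinsic Z–X′–Y″ decomposition of R_rel = T_trunkᵀ·T_shoulder,
with x constrained to [−90°, 90°] and, at gimbal lock, y := 0 with the
residual assigned to z (a deterministic tie-break). Signs: flexion positive
anteriorly, abduction positive away from the midline, side-bend positive to
the subject's left. Lower-limb and neck angles are projected segment
angles as documented in `kinematics.py`; the exact conventions of the
lower-limb and upper-limb methods this study family cites are not public in
detail, so these definitions are this package's explicit stand-ins — the
generator shares them, which is the property RMSE-based evaluation needs.

Pelvis obliquity is referenced to the **world** horizontal plane, so it is
invariant under yaw and translation but not under arbitrary rotations; the
other ten angles are fully rigid-motion and scale invariant (tested).
Degenerate frames yield per-frame missing values (logged), excluded
pairwise from RMSE/SD, rather than aborting a sequence. The `side_policy`
(left/right/mean, default mean) controls how sided angles are aggregated.

## Metrics and statistics

MPJPE is computed from raw per-frame distances only — the published overall
MPJPE row is not re-derivable from the rounded per-group means (weighted
recomputation gives ≈13.3/13.5/13.5 vs printed 13.0/13.4/13.3), and the
synthetic experiment's MPJPE correspondingly tracks the recomputed values.
Group summaries store the spread as 2σ explicitly to avoid silent
factor-of-two mistakes. Δ statistics are |max − min| across conditions,
computed on full-precision values; the published-table verification uses
the printed (rounded) per-condition values with a 0.05 rounding tolerance.

The repeated-measures ANOVA partitions SS_total into subjects + conditions
+ error; F = MS_cond/MS_err on (k−1, (k−1)(n−1)) df, p from the F survival
function. No sphericity correction is applied by default (the design
assumption); a Greenhouse–Geisser variant is available behind a flag.
Degenerate designs are deterministic: MS_err = 0 with no condition effect
gives F = 0, p = 1; with a condition effect, F = ∞, p = 0. Significance is
strict p < alpha with no multiplicity adjustment. The acceptability
threshold is limit/(1.96·2); its reported figure truncates to two decimals
(5° → 1.27°, the conventional printed value) while verdicts always use the
unrounded value.

Because per-subject RMSEs in the synthetic experiment are tight (hundreds
of i.i.d.-noise frames, subject-level variation limited to anthropometry),
the synthetic ANOVA has far higher power than the original human study:
conditions whose calibrated noise levels genuinely differ come out
significant even though every Δ remains far below the acceptability
threshold. The two effect measures answering different questions —
detectability vs magnitude — is precisely the point of reporting both.

## Reproducibility and problem sizes

All randomness flows from explicit seeds; the pipeline derives per-stage
seeds as SHA-256(master, stage, subject, condition) truncated below 2³¹,
so stages can be re-run in isolation. Default experiment: 16 subjects ×
3 conditions × 330 frames (5 cycles at 60 Hz), which runs in well under a
minute; the Monte-Carlo calibration checks use 10⁵ draws, and the null
calibration of the F test uses 2000 simulated 16×3 designs. Rendered
imagery is written for a small frame subset (default 2 frames × 4 views)
since it serves only to exercise the anonymizer.

## Known limitations

* The gait model is a didactic sinusoidal construction, not a validated
  biomechanical model; absolute synthetic error magnitudes carry no
  clinical meaning beyond their calibration targets.
* Noise is spatially and temporally white; real pose estimators err in a
  correlated, view-dependent way.
* Published absolute errors and p-values depend on trained network weights
  and a private dataset and are not reproducible here; only their
  self-contained Δ arithmetic is re-verified.
* No lens distortion, no rolling shutter, no synchronization error.
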