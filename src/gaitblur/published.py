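"""Published reference results of the original face-blurring gait study.

The original multi-camera experiment trained a learnable-triangulation pose
estimator under three conditions — #1 trained on face-blurred images, #2
finetuned on face-blurred images, #3 the unblurred control — and evaluated
all three on a 16-subject test set. Its printed summary tables are embedded
here for two purposes:

* re-verifying the published Δ (max - min across conditions) arithmetic,
  which is self-contained and independent of the private dataset;
* calibrating the synthetic noise conditions so the simulated experiment
  operates at the same per-keypoint error magnitudes.

Values are exactly as printed (mm for positions, degrees for angles); the
position spread row is 2σ, not σ.
"""

from __future__ import annotations

import pandas as pd

from .keypoints import KEYPOINT_GROUPS

#: The three experimental conditions (within-subject factor levels).
CONDITIONS: tuple[str, ...] = ("model1", "model2", "model3")

#: Per keypoint-group mean position error μ (mm) for each condition.
POSITION_MU_MM: dict[str, dict[str, float]] = {
    "model1": {"feet": 10.1, "ankles": 7.2, "knees": 11.0, "hips": 15.8,
               "pelvis": 12.7, "neck": 11.0, "head": 11.1, "wrists": 14.7,
               "elbows": 15.2, "shoulders": 21.7},
    "model2": {"feet": 9.7, "ankles": 7.2, "knees": 10.7, "hips": 16.3,
               "pelvis": 12.9, "neck": 10.4, "head": 13.3, "wrists": 15.4,
               "elbows": 15.4, "shoulders": 22.3},
    "model3": {"feet": 9.8, "ankles": 7.1, "knees": 11.0, "hips": 16.4,
               "pelvis": 13.1, "neck": 10.0, "head": 13.8, "wrists": 15.0,
               "elbows": 15.4, "shoulders": 21.8},
}

#: Per keypoint-group error spread, reported as 2σ (mm).
POSITION_2SIGMA_MM: dict[str, dict[str, float]] = {
    "model1": {"feet": 13.6, "ankles": 9.9, "knees": 11.2, "hips": 15.0,
               "pelvis": 11.0, "neck": 11.3, "head": 11.9, "wrists": 23.2,
               "elbows": 19.9, "shoulders": 24.1},
    "model2": {"feet": 13.0, "ankles": 9.9, "knees": 10.5, "hips": 15.8,
               "pelvis": 11.5, "neck": 11.6, "head": 14.1, "wrists": 34.2,
               "elbows": 21.4, "shoulders": 38.7},
    "model3": {"feet": 13.1, "ankles": 10.2, "knees": 12.2, "hips": 17.0,
               "pelvis": 11.7, "neck": 11.4, "head": 14.3, "wrists": 27.7,
               "elbows": 24.4, "shoulders": 36.0},
}

#: Overall MPJPE (mm) per condition.
MPJPE_MM: dict[str, float] = {"model1": 13.0, "model2": 13.4, "model3": 13.3}

#: Printed Δ row of the position table, including the MPJPE column.
POSITION_DELTA_MM: dict[str, float] = {
    "feet": 0.4, "ankles": 0.1, "knees": 0.3, "hips": 0.6, "pelvis": 0.4,
    "neck": 1.0, "head": 2.7, "wrists": 0.7, "elbows": 0.2, "shoulders": 0.6,
    "mpjpe": 0.4,
}

#: Pooled joint-angle RMSE (degrees) per condition.
ANGLE_RMSE_DEG: dict[str, dict[str, float]] = {
    "model1": {"shoulder_flexion": 4.9, "shoulder_abduction": 2.9,
               "elbow_flexion": 7.2, "neck_side_bend": 2.7, "neck_flexion": 5.1,
               "hip_abduction": 3.2, "knee_flexion": 2.6, "femur_flexion": 1.8,
               "femur_abduction": 1.2, "pelvis_abduction": 2.6, "ankle_flexion": 4.7},
    "model2": {"shoulder_flexion": 5.5, "shoulder_abduction": 3.1,
               "elbow_flexion": 7.4, "neck_side_bend": 2.6, "neck_flexion": 5.2,
               "hip_abduction": 3.2, "knee_flexion": 2.6, "femur_flexion": 1.8,
               "femur_abduction": 1.3, "pelvis_abduction": 2.6, "ankle_flexion": 5.0},
    "model3": {"shoulder_flexion": 4.9, "shoulder_abduction": 3.1,
               "elbow_flexion": 7.1, "neck_side_bend": 2.6, "neck_flexion": 5.2,
               "hip_abduction": 3.2, "knee_flexion": 2.6, "femur_flexion": 1.8,
               "femur_abduction": 1.3, "pelvis_abduction": 2.6, "ankle_flexion": 4.8},
}

#: SD of the frame-wise angle differences (degrees) per condition.
ANGLE_SD_DEG: dict[str, dict[str, float]] = {
    "model1": {"shoulder_flexion": 4.7, "shoulder_abduction": 2.9,
               "elbow_flexion": 6.5, "neck_side_bend": 2.2, "neck_flexion": 5.1,
               "hip_abduction": 3.1, "knee_flexion": 2.6, "femur_flexion": 1.8,
               "femur_abduction": 1.2, "pelvis_abduction": 2.5, "ankle_flexion": 4.6},
    "model2": {"shoulder_flexion": 5.3, "shoulder_abduction": 3.1,
               "elbow_flexion": 6.7, "neck_side_bend": 2.2, "neck_flexion": 5.2,
               "hip_abduction": 3.1, "knee_flexion": 2.6, "femur_flexion": 1.8,
               "femur_abduction": 1.3, "pelvis_abduction": 2.6, "ankle_flexion": 4.9},
    "model3": {"shoulder_flexion": 4.7, "shoulder_abduction": 3.1,
               "elbow_flexion": 6.4, "neck_side_bend": 2.2, "neck_flexion": 5.2,
               "hip_abduction": 3.1, "knee_flexion": 2.6, "femur_flexion": 1.8,
               "femur_abduction": 1.3, "pelvis_abduction": 2.5, "ankle_flexion": 4.7},
}

#: Printed Δ columns of the angle table: (ΔRMSE, ΔSD) in degrees.
ANGLE_DELTA_DEG: dict[str, tuple[float, float]] = {
    "shoulder_flexion": (0.6, 0.6), "shoulder_abduction": (0.2, 0.2),
    "elbow_flexion": (0.3, 0.3), "neck_side_bend": (0.1, 0.0),
    "neck_flexion": (0.1, 0.1), "hip_abduction": (0.0, 0.0),
    "knee_flexion": (0.0, 0.0), "femur_flexion": (0.0, 0.0),
    "femur_abduction": (0.1, 0.1), "pelvis_abduction": (0.0, 0.1),
    "ankle_flexion": (0.3, 0.3),
}

#: Published repeated-measures ANOVA p-values per joint angle.
ANOVA_P_VALUES: dict[str, float] = {
    "shoulder_flexion": 0.259, "shoulder_abduction": 0.338,
    "elbow_flexion": 0.040, "neck_side_bend": 0.237, "neck_flexion": 0.896,
    "hip_abduction": 0.895, "knee_flexion": 0.320, "femur_flexion": 0.931,
    "femur_abduction": 0.217, "pelvis_abduction": 0.756, "ankle_flexion": 0.106,
}

#: Test-set size of the original cohort.
N_SUBJECTS_TEST = 16


def keypoint_mu_targets(condition: str) -> dict[str, float]:
    """Expand the per-group μ of one condition to per-keypoint targets (mm)."""
    if condition not in POSITION_MU_MM:
        raise KeyError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    group_mu = POSITION_MU_MM[condition]
    out: dict[str, float] = {}
    for group, members in KEYPOINT_GROUPS.items():
        for kp in members:
            out[kp] = group_mu[group]
    return out


def position_table() -> pd.DataFrame:
    """Per-group μ and 2σ (mm) per condition, plus MPJPE, as one tidy table."""
    rows = []
    for cond in CONDITIONS:
        for group in KEYPOINT_GROUPS:
            rows.append(
                {"condition": cond, "group": group,
                 "mu_mm": POSITION_MU_MM[cond][group],
                 "two_sigma_mm": POSITION_2SIGMA_MM[cond][group]}
            )
    return pd.DataFrame(rows)
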