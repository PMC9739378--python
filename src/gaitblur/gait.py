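"""Synthetic gait cohort: keypoint trajectories and simulated pose estimates.

The generator builds walking sequences by forward kinematics from sinusoidal
joint-angle profiles, so the ground-truth angle of every frame is known by
construction and can be compared against what the analyzer recovers. The
profiles are deliberately simple — this is a test harness for the analysis
chain, not a biomechanically validated gait model:

* hip (femur) flexion, ankle flexion and arm swing follow sinusoids over the
  gait cycle; the left leg is phase-shifted by half a cycle and each arm
  swings in anti-phase with its ipsilateral leg;
* knee flexion uses a raised-cosine profile so it stays non-negative with
  the configured peak value;
* the elbow keeps a positive flexion offset (the humerus-forearm plane, and
  with it the shoulder frame, would be undefined for a perfectly straight
  arm);
* pelvis obliquity rolls the hip line about the walking axis;
* the whole body translates along +Z at the configured walking speed.

Simulated pose estimates add isotropic zero-mean Gaussian noise per frame and
keypoint. The error norm of such noise follows a Maxwell distribution with
mean 2σ√(2/π), so a requested mean error magnitude μ maps to a per-axis
σ = μ / (2√(2/π)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .keypoints import KEYPOINT_INDEX, KEYPOINT_NAMES, N_KEYPOINTS, MotionSequence
from .kinematics import ANGLE_NAMES, UNSIDED_ANGLES, JointAngleSeries

#: Mean of the Maxwell distribution in units of its scale σ.
MAXWELL_MEAN_FACTOR = 2.0 * np.sqrt(2.0 / np.pi)


@dataclass
class GaitConfig:
    """Anthropometry (mm), gait-cycle timing and joint-angle amplitudes (deg)."""

    # segment lengths, mm
    pelvis_width: float = 240.0
    trunk_length: float = 500.0
    neck_length: float = 80.0        # N down to the shoulder line
    head_offset: float = 200.0       # N up to H
    shoulder_width: float = 380.0
    upper_arm: float = 280.0
    forearm: float = 250.0
    thigh: float = 420.0
    shank: float = 400.0
    foot: float = 150.0
    # timing
    cycle_duration_s: float = 1.1
    n_cycles: int = 5
    frame_rate: float = 60.0
    walking_speed: float = 1200.0    # mm/s along +Z
    # angle profiles, degrees
    hip_flexion_amp: float = 30.0
    knee_flexion_amp: float = 60.0
    ankle_flexion_amp: float = 15.0
    arm_swing_amp: float = 20.0
    elbow_mean: float = 30.0
    elbow_amp: float = 10.0
    neck_flexion_amp: float = 5.0
    pelvis_roll_amp: float = 4.0
    random_seed: int | None = None   # randomises the initial gait phase

    def __post_init__(self) -> None:
        lengths = (
            self.pelvis_width, self.trunk_length, self.neck_length,
            self.head_offset, self.shoulder_width, self.upper_arm,
            self.forearm, self.thigh, self.shank, self.foot,
        )
        if any(not length > 0 for length in lengths):
            raise ConfigurationError("all segment lengths must be positive")
        if not self.cycle_duration_s > 0 or self.n_cycles < 1:
            raise ConfigurationError("cycle duration and cycle count must be positive")
        if not self.frame_rate > 0:
            raise ConfigurationError("frame_rate must be positive")
        amps = (
            self.hip_flexion_amp, self.knee_flexion_amp, self.ankle_flexion_amp,
            self.arm_swing_amp, self.elbow_mean, self.elbow_amp,
            self.neck_flexion_amp, self.pelvis_roll_amp,
        )
        if any(abs(a) > 180.0 for a in amps):
            raise ConfigurationError("angle amplitudes must lie within +/-180 degrees")

    def scaled(self, factor: float) -> "GaitConfig":
        """Uniformly scale the anthropometry (cohort size variation)."""
        if not factor > 0:
            raise ConfigurationError("scale factor must be positive")
        return replace(
            self,
            pelvis_width=self.pelvis_width * factor,
            trunk_length=self.trunk_length * factor,
            neck_length=self.neck_length * factor,
            head_offset=self.head_offset * factor,
            shoulder_width=self.shoulder_width * factor,
            upper_arm=self.upper_arm * factor,
            forearm=self.forearm * factor,
            thigh=self.thigh * factor,
            shank=self.shank * factor,
            foot=self.foot * factor,
        )


@dataclass
class SyntheticGait:
    """A generated walking sequence plus its ground-truth angle profiles.

    ``truth`` is a long table (frame_index, angle_name, side, value_deg)
    where ``side`` is 'left', 'right' or 'mid' for unsided angles.
    """

    sequence: MotionSequence
    truth: pd.DataFrame
    config: GaitConfig

    def truth_series(self, side_policy: str = "mean") -> JointAngleSeries:
        """Ground truth reshaped like the analyzer output for direct comparison."""
        if side_policy not in ("left", "right", "mean"):
            raise InputError(f"side_policy must be left/right/mean, got {side_policy!r}")
        n = self.sequence.n_frames
        out = pd.DataFrame(index=range(n), columns=list(ANGLE_NAMES), dtype=float)
        for name in ANGLE_NAMES:
            sub = self.truth[self.truth["angle_name"] == name]
            if name in UNSIDED_ANGLES:
                vals = sub.set_index("frame_index")["value_deg"].reindex(range(n))
            elif side_policy == "mean":
                vals = sub.groupby("frame_index")["value_deg"].mean().reindex(range(n))
            else:
                vals = (
                    sub[sub["side"] == side_policy]
                    .set_index("frame_index")["value_deg"]
                    .reindex(range(n))
                )
            out[name] = vals.to_numpy()
        return JointAngleSeries(values=out, side_policy=side_policy,
                                subject_id=self.sequence.subject_id)


def _profiles(config: GaitConfig, phase: np.ndarray) -> dict[tuple[str, str], np.ndarray]:
    """Ground-truth angle series keyed by (angle_name, side); degrees."""
    two_pi = 2.0 * np.pi
    out: dict[tuple[str, str], np.ndarray] = {}
    for side, shift in (("right", 0.0), ("left", 0.5)):
        ph = two_pi * (phase + shift)
        hip = config.hip_flexion_amp * np.sin(ph)
        knee = config.knee_flexion_amp * 0.5 * (1.0 - np.cos(ph))
        ankle = config.ankle_flexion_amp * np.sin(ph)
        arm = -config.arm_swing_amp * np.sin(ph)          # anti-phase to leg
        elbow = config.elbow_mean - config.elbow_amp * np.sin(ph)
        out[("femur_flexion", side)] = hip
        out[("knee_flexion", side)] = knee
        out[("ankle_flexion", side)] = ankle
        out[("shoulder_flexion", side)] = arm
        out[("shoulder_abduction", side)] = np.zeros_like(ph)
        out[("elbow_flexion", side)] = elbow
        out[("hip_abduction", side)] = np.zeros_like(ph)
        out[("femur_abduction", side)] = np.zeros_like(ph)
    ph = two_pi * phase
    out[("neck_flexion", "mid")] = config.neck_flexion_amp * np.sin(ph)
    out[("neck_side_bend", "mid")] = np.zeros_like(ph)
    out[("pelvis_abduction", "mid")] = config.pelvis_roll_amp * np.sin(ph)
    return out


def generate_gait_sequence(config: GaitConfig, subject_id: str = "subject") -> SyntheticGait:
    """Forward-kinematics walking sequence with retrievable ground truth.

    Trunk axes stay world-aligned (X_t = world +Z anterior, Y_t = world +Y up,
    Z_t = world -X) while the pelvis translates along +Z; segment lengths are
    constant across frames by construction.
    """
    n_frames = int(round(config.n_cycles * config.cycle_duration_s * config.frame_rate))
    if n_frames < 1:
        raise ConfigurationError("configuration yields an empty sequence")
    t = np.arange(n_frames) / config.frame_rate
    phase0 = 0.0
    if config.random_seed is not None:
        phase0 = float(np.random.default_rng(config.random_seed).uniform(0.0, 1.0))
    phase = (t / config.cycle_duration_s + phase0) % 1.0

    prof = _profiles(config, phase)
    rad = {k: np.radians(v) for k, v in prof.items()}

    # world-aligned trunk axes (see module docstring)
    X_t = np.array([0.0, 0.0, 1.0])
    Y_t = np.array([0.0, 1.0, 0.0])

    def sagittal(angle_rad: np.ndarray) -> np.ndarray:
        """(n, 3) unit vectors at `angle` from -Y_t toward +X_t (down = 0)."""
        return (np.sin(angle_rad)[:, None] * X_t) - (np.cos(angle_rad)[:, None] * Y_t)

    hc_height = config.thigh + config.shank + 100.0
    hc = np.column_stack(
        [np.zeros(n_frames), np.full(n_frames, hc_height), config.walking_speed * t]
    )
    data = np.empty((n_frames, N_KEYPOINTS, 3))
    data[:, KEYPOINT_INDEX["HC"]] = hc

    # pelvis with obliquity about the walking axis (left hip up = positive)
    rho = rad[("pelvis_abduction", "mid")]
    half_pelvis = 0.5 * config.pelvis_width * np.column_stack(
        [np.cos(rho), -np.sin(rho), np.zeros(n_frames)]
    )
    data[:, KEYPOINT_INDEX["HR"]] = hc + half_pelvis
    data[:, KEYPOINT_INDEX["HL"]] = hc - half_pelvis

    # trunk, neck and head
    n_kp = hc + config.trunk_length * Y_t
    data[:, KEYPOINT_INDEX["N"]] = n_kp
    nu = rad[("neck_flexion", "mid")]
    head_dir = (np.sin(nu)[:, None] * X_t) + (np.cos(nu)[:, None] * Y_t)
    data[:, KEYPOINT_INDEX["H"]] = n_kp + config.head_offset * head_dir

    shoulder_line = n_kp - config.neck_length * Y_t
    lateral = np.array([1.0, 0.0, 0.0])   # world +X = subject's right
    for side, sgn in (("right", 1.0), ("left", -1.0)):
        sfx = "R" if side == "right" else "L"
        s = shoulder_line + sgn * 0.5 * config.shoulder_width * lateral
        phi = rad[("shoulder_flexion", side)]
        e = s + config.upper_arm * sagittal(phi)
        w = e + config.forearm * sagittal(phi + rad[("elbow_flexion", side)])
        data[:, KEYPOINT_INDEX["S" + sfx]] = s
        data[:, KEYPOINT_INDEX["E" + sfx]] = e
        data[:, KEYPOINT_INDEX["W" + sfx]] = w

        hip_kp = data[:, KEYPOINT_INDEX["H" + sfx]]
        h_ang = rad[("femur_flexion", side)]
        k_ang = rad[("knee_flexion", side)]
        a_ang = rad[("ankle_flexion", side)]
        knee = hip_kp + config.thigh * sagittal(h_ang)
        ankle = knee + config.shank * sagittal(h_ang - k_ang)
        foot = ankle + config.foot * sagittal(h_ang - k_ang + np.pi / 2 + a_ang)
        data[:, KEYPOINT_INDEX["K" + sfx]] = knee
        data[:, KEYPOINT_INDEX["A" + sfx]] = ankle
        data[:, KEYPOINT_INDEX["F" + sfx]] = foot

    seq = MotionSequence(data=data, frame_rate=config.frame_rate, subject_id=subject_id)

    records = []
    for (name, side), vals in prof.items():
        records.append(
            pd.DataFrame(
                {
                    "frame_index": np.arange(n_frames),
                    "angle_name": name,
                    "side": side,
                    "value_deg": vals,
                }
            )
        )
    truth = pd.concat(records, ignore_index=True)
    return SyntheticGait(sequence=seq, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Pose-estimate noise simulation


@dataclass
class NoiseModelSpec:
    """Per-keypoint target mean error magnitude (mm) for simulated estimates."""

    mu_target: dict[str, float] = field(default_factory=dict)
    random_seed: int = 0
    label: str = "noise"

    def __post_init__(self) -> None:
        unknown = set(self.mu_target) - set(KEYPOINT_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown keypoints in noise spec: {sorted(unknown)}")
        if any(mu < 0 for mu in self.mu_target.values()):
            raise ConfigurationError("mu_target must be non-negative")

    def mu_vector(self) -> np.ndarray:
        """(17,) per-keypoint mean error magnitudes; missing names default to 0."""
        return np.array([self.mu_target.get(k, 0.0) for k in KEYPOINT_NAMES])

    @classmethod
    def uniform(cls, mu: float, random_seed: int = 0, label: str = "noise") -> "NoiseModelSpec":
        return cls(mu_target={k: mu for k in KEYPOINT_NAMES},
                   random_seed=random_seed, label=label)


def sigma_for_mean_norm(mu: float) -> float:
    """Per-axis Gaussian σ whose 3D error norm has expected value μ."""
    if mu < 0:
        raise ConfigurationError("mean error magnitude must be non-negative")
    return mu / MAXWELL_MEAN_FACTOR


def simulate_pose_estimates(reference: MotionSequence, noise: NoiseModelSpec) -> MotionSequence:
    """Reference + i.i.d. isotropic Gaussian noise per frame and keypoint.

    The per-axis σ for each keypoint is chosen so the expected error norm
    equals the configured μ (Maxwell-distribution mean). Reproducible under a
    fixed ``noise.random_seed``.
    """
    sigma = noise.mu_vector() / MAXWELL_MEAN_FACTOR
    rng = np.random.default_rng(noise.random_seed)
    eps = rng.standard_normal(reference.data.shape) * sigma[None, :, None]
    return MotionSequence(
        data=reference.data + eps,
        frame_rate=reference.frame_rate,
        subject_id=reference.subject_id,
    )
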