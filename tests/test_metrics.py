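import numpy as np
import pandas as pd
import pytest

from gaitblur import (ANGLE_NAMES, JointAngleSeries, MotionSequence,
                      NoiseModelSpec, acceptability, angle_rmse_table, delta_mu,
                      delta_rmse_sd, joint_error_summary, mpjpe,
                      simulate_pose_estimates)
from gaitblur.errors import ConfigurationError, InputError
from gaitblur.keypoints import KEYPOINT_GROUPS
from gaitblur import published


def _seq(data):
    return MotionSequence(np.asarray(data, float), frame_rate=60.0)


def _series(values: np.ndarray) -> JointAngleSeries:
    return JointAngleSeries(pd.DataFrame(values, columns=list(ANGLE_NAMES)))


# --- MPJPE -------------------------------------------------------------------

def test_mpjpe_identity_and_345_displacement(rng):
    ref = _seq(rng.normal(size=(4, 17, 3)))
    assert mpjpe(ref, ref) == 0.0
    est = ref.data.copy()
    est[2, 5] += [3.0, 4.0, 0.0]
    assert mpjpe(_seq(est), ref) == pytest.approx(5.0 / (4 * 17))
    one = _seq(np.zeros((1, 17, 3)))
    moved = np.zeros((1, 17, 3))
    moved[0] += [3.0, 4.0, 0.0]
    assert mpjpe(_seq(moved), one) == pytest.approx(5.0)


def test_mpjpe_matches_double_loop_oracle(rng):
    ref = _seq(rng.normal(scale=50.0, size=(10, 17, 3)))
    est = _seq(ref.data + rng.normal(scale=5.0, size=(10, 17, 3)))
    total = 0.0
    for i in range(10):
        for k in range(17):
            total += float(np.sqrt(((est.data[i, k] - ref.data[i, k]) ** 2).sum()))
    assert mpjpe(est, ref) == pytest.approx(total / (10 * 17), abs=1e-12)


def test_mpjpe_is_a_pseudometric(rng):
    a = _seq(rng.normal(size=(5, 17, 3)))
    b = _seq(rng.normal(size=(5, 17, 3)))
    c = _seq(rng.normal(size=(5, 17, 3)))
    assert mpjpe(a, b) == pytest.approx(mpjpe(b, a))
    assert mpjpe(a, c) <= mpjpe(a, b) + mpjpe(b, c) + 1e-12
    with pytest.raises(InputError):
        mpjpe(a, _seq(rng.normal(size=(6, 17, 3))))


# --- grouped error summary ---------------------------------------------------

def test_joint_error_summary_zero_and_constant_errors():
    ref = _seq(np.zeros((3, 17, 3)))
    summ = joint_error_summary(ref, ref)
    assert (summ.per_group["mu_mm"] == 0).all()
    assert (summ.per_group["two_sigma_mm"] == 0).all()
    est = np.zeros((3, 17, 3))
    est[:, :, 0] = 5.0
    summ = joint_error_summary(_seq(est), ref)
    np.testing.assert_allclose(summ.per_group["mu_mm"], 5.0)
    np.testing.assert_allclose(summ.per_group["two_sigma_mm"], 0.0, atol=1e-9)
    assert summ.mpjpe_mm == pytest.approx(5.0)


def test_joint_error_summary_rejects_unknown_group():
    ref = _seq(np.zeros((2, 17, 3)))
    with pytest.raises(ConfigurationError):
        joint_error_summary(ref, ref, grouping={"torso": ("N", "XX")})


def test_group_means_calibrate_to_published_targets():
    """Simulated condition noise reproduces the published per-group μ."""
    ref = _seq(np.zeros((10_000, 17, 3)))
    spec = NoiseModelSpec(mu_target=published.keypoint_mu_targets("model1"),
                          random_seed=11)
    summ = joint_error_summary(simulate_pose_estimates(ref, spec), ref)
    for group, target in published.POSITION_MU_MM["model1"].items():
        assert summ.mu(group) == pytest.approx(target, rel=0.05)


# --- delta statistics --------------------------------------------------------

def test_delta_mu_published_examples():
    assert delta_mu([11.1, 13.3, 13.8]).delta == pytest.approx(2.7)   # head
    assert delta_mu([11.0, 10.4, 10.0]).delta == pytest.approx(1.0)   # neck
    assert delta_mu([4.0, 4.0, 4.0]).delta == 0.0
    with pytest.raises(InputError):
        delta_mu([1.0])


def test_delta_rmse_sd_published_examples():
    d = delta_rmse_sd([4.9, 5.5, 4.9], [4.7, 5.3, 4.7],
                      labels=["m1", "m2", "m3"])
    assert d.delta_rmse == pytest.approx(0.6)
    assert d.delta_sd == pytest.approx(0.6)
    assert d.argmax_rmse == "m2"
    assert delta_rmse_sd([4.7, 5.0, 4.8], [1, 1, 1]).delta_rmse == pytest.approx(0.3)


def test_delta_is_permutation_invariant(rng):
    vals = rng.normal(size=6)
    base = delta_mu(vals).delta
    for _ in range(10):
        assert delta_mu(rng.permutation(vals)).delta == pytest.approx(base)
        assert base >= 0


# --- angle RMSE table --------------------------------------------------------

def test_angle_rmse_identity_and_constant_offset(rng):
    vals = rng.normal(scale=10.0, size=(50, len(ANGLE_NAMES)))
    ref = {"s1": _series(vals)}
    est = {"s1": _series(vals.copy())}
    tab = angle_rmse_table(est, ref)
    assert (tab.per_subject.to_numpy() == 0).all()
    offset = vals.copy()
    offset[:, 2] += 2.0     # constant bias on one angle
    tab = angle_rmse_table({"s1": _series(offset)}, ref)
    angle = ANGLE_NAMES[2]
    assert tab.per_subject.loc["s1", angle] == pytest.approx(2.0)
    assert tab.pooled.loc[angle, "rmse_deg"] == pytest.approx(2.0)
    assert tab.pooled.loc[angle, "sd_deg"] == pytest.approx(0.0, abs=1e-12)


def test_pooled_rmse_matches_brute_force_and_bias_variance(rng):
    ref, est = {}, {}
    diffs = {a: [] for a in ANGLE_NAMES}
    for s in ("s1", "s2", "s3"):
        r = rng.normal(scale=15.0, size=(40, len(ANGLE_NAMES)))
        e = r + rng.normal(scale=3.0, size=r.shape) + 1.0
        ref[s], est[s] = _series(r), _series(e)
        for j, a in enumerate(ANGLE_NAMES):
            diffs[a].append(e[:, j] - r[:, j])
    tab = angle_rmse_table(est, ref)
    for a in ANGLE_NAMES:
        d = np.concatenate(diffs[a])
        rmse = np.sqrt((d ** 2).mean())
        assert tab.pooled.loc[a, "rmse_deg"] == pytest.approx(rmse, abs=1e-10)
        # RMSE^2 = bias^2 + SD^2 and pooled RMSE >= |bias|
        sd = tab.pooled.loc[a, "sd_deg"]
        assert rmse ** 2 == pytest.approx(d.mean() ** 2 + sd ** 2, abs=1e-10)
        assert rmse >= abs(d.mean()) - 1e-12


def test_missing_frames_excluded_pairwise():
    vals = np.ones((10, len(ANGLE_NAMES)))
    est = vals.copy()
    est[0, 0] = np.nan
    est[:, 1] += 3.0
    tab = angle_rmse_table({"s": _series(est)}, {"s": _series(vals)})
    assert tab.n_missing == 1
    assert tab.per_subject.loc["s", ANGLE_NAMES[0]] == pytest.approx(0.0)
    assert tab.per_subject.loc["s", ANGLE_NAMES[1]] == pytest.approx(3.0)


# --- acceptability -----------------------------------------------------------

def test_acceptability_threshold_and_verdicts():
    threshold, ok = acceptability(0.6)
    assert threshold == pytest.approx(1.27)
    assert ok
    _, ok = acceptability(1.30)
    assert not ok
    _, ok = acceptability(5.0 / (1.96 * 2.0))   # exactly at the threshold
    assert not ok                                # strict inequality
    with pytest.raises(ConfigurationError):
        acceptability(0.1, limit=0.0)
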