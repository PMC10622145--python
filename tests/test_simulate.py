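"""Generator contracts: determinism, geometry, injected signal shapes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPoint

from isoimap import behavior as bh
from isoimap import simulate as sim


def test_frame_times_match_acquisition_windows():
    cfg = sim.SimConfig()
    t = cfg.frame_times
    assert len(t) == 70
    assert np.isclose(t[0], -0.9) and np.isclose(t[-1], 6.0)
    assert (t <= 0).sum() == 10            # baseline frames -1.0 to 0 s
    assert ((t >= 2.2) & (t <= 6.0)).sum() == 39   # post-movement window
    assert ((t >= 2.8) & (t <= 6.0)).sum() == 33


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        sim.SimConfig(condition_amplitude={
            "precision": 1e-3, "power": 2e-3, "reach-only": 5e-4, "withhold": 0.0})
    with pytest.raises(ValueError):
        sim.SimConfig(condition_amplitude={
            "precision": 1e-3, "power": 9e-4, "reach-only": 5e-4, "withhold": 1e-4})
    with pytest.raises(ValueError):
        sim.SimConfig(site_spacing_mm=0.2)


def test_motor_sites_deterministic(cfg_small):
    a = sim.gen_motor_sites(cfg_small, 3)
    b = sim.gen_motor_sites(cfg_small, 3)
    pd.testing.assert_frame_equal(a, b)
    c = sim.gen_motor_sites(cfg_small, 4)
    assert not a["threshold_uA"].equals(c["threshold_uA"])


def test_motor_sites_thresholds_by_area(cfg_small):
    sites = sim.gen_motor_sites(cfg_small, 3)
    m1 = sites[sites["true_area"] == "M1"]
    pm = sites[sites["true_area"] != "M1"]
    assert (m1["threshold_uA"] < 30).all()
    assert (pm["threshold_uA"] > 30).all()
    assert len(m1) > 0 and len(pm) > 0


def test_hand_core_surrounded_by_arm():
    """The hand zone's convex hull is nested inside the arm ring."""
    cfg = sim.SimConfig(seed=5)
    sites = sim.gen_motor_sites(cfg, 5)
    m1 = sites[sites["true_area"] == "M1"].drop_duplicates(["x_mm", "y_mm"])
    hand = m1[m1["true_class"] == "hand"]
    arm = m1[m1["true_class"] == "arm"]
    hull_hand = MultiPoint(list(zip(hand["x_mm"], hand["y_mm"]))).convex_hull
    hull_arm = MultiPoint(list(zip(arm["x_mm"], arm["y_mm"]))).convex_hull
    assert hull_arm.contains(hull_hand)
    assert hull_hand.area < hull_arm.area


def test_response_zero_before_cue_and_for_withhold(gt_small):
    profile = gt_small.patches[0].profile
    t = np.array([-0.9, -0.5, -0.1, 0.0])
    assert np.all(sim.response_timecourse(profile, t, "precision") == 0)
    t_post = np.linspace(0.1, 6.0, 60)
    assert np.all(sim.response_timecourse(profile, t_post, "withhold") == 0)


def test_hand_profile_flat_before_ramp():
    profile = sim.ResponseProfile(
        zone_kind="hand", peak_time_s=4.2, neg_sigma_s=0.8,
        amplitude_by_condition={"power": 1e-3},
    )
    v = sim.response_timecourse(profile, 1.0, "power")
    assert abs(v) < 1e-6 * 1e-3 * 1e3  # essentially zero vs the 1e-3 peak


def test_arm_profile_argmin_matches_dense_sampling():
    profile = sim.ResponseProfile(
        zone_kind="arm", peak_time_s=5.0, neg_sigma_s=0.9,
        amplitude_by_condition={"precision": 1e-3},
    )
    t = np.linspace(0, 7, 7001)
    curve = sim.response_timecourse(profile, t, "precision")
    # brute-force minimum of the densely sampled curve
    t_star = t[np.argmin(curve)]
    assert abs(curve.min() - np.min(curve)) == 0
    coarse = sim.response_timecourse(profile, np.array([t_star]), "precision")[0]
    assert np.isclose(coarse, curve.min())
    assert abs(t_star - 5.0) < 0.01  # far from the positive lobe


def test_unknown_zone_kind_raises():
    p = sim.ResponseProfile(zone_kind="tail", amplitude_by_condition={"power": 1.0})
    with pytest.raises(ValueError, match="zone_kind"):
        p.shape(np.array([1.0]))


def test_trial_stack_determinism(cfg_small, gt_small):
    a = sim.gen_trial_stack("precision", gt_small, cfg_small, 42)
    b = sim.gen_trial_stack("precision", gt_small, cfg_small, 42)
    assert a.frames.tobytes() == b.frames.tobytes()
    assert np.array_equal(a.true_shifts_px, b.true_shifts_px)


def test_withhold_stack_is_noise_only(cfg_small):
    cfg = dataclasses.replace(cfg_small, rigid_jitter_px=0.0, motion_artifact_px=0.0)
    gt = sim.make_ground_truth(cfg)
    ts = sim.gen_trial_stack("withhold", gt, cfg, 9)
    sd = ts.frames.std(axis=0) / gt.base_image  # per-pixel temporal SD in dR/R
    assert abs(np.median(sd) - cfg.noise_sd) < 0.1 * cfg.noise_sd


def test_noiseless_trial_reconstructs_profile(cfg_small):
    cfg = dataclasses.replace(
        cfg_small, noise_sd=0.0, rigid_jitter_px=0.0, motion_artifact_px=0.0
    )
    gt = sim.make_ground_truth(cfg)
    ts = sim.gen_trial_stack("precision", gt, cfg, 1)
    patch = gt.patches[0]
    cy, cx = np.argwhere(patch.mask).mean(axis=0).astype(int)
    expected = gt.base_image[cy, cx] * (
        1.0 + sim.response_timecourse(patch.profile, cfg.frame_times, "precision")
    )
    np.testing.assert_allclose(ts.frames[:, cy, cx], expected, rtol=1e-12)


def test_excessive_amplitude_raises(cfg_small):
    cfg = dataclasses.replace(
        cfg_small,
        condition_amplitude={"precision": 1.5, "power": 1.2, "reach-only": 1.0,
                             "withhold": 0.0},
    )
    gt = sim.make_ground_truth(cfg)
    with pytest.raises(ValueError, match="negative"):
        sim.gen_trial_stack("precision", gt, cfg, 1)


def test_session_block_structure(cfg_small, gt_small):
    sess = sim.gen_session(cfg_small, gt_small, "S1", 2)
    man = sess.manifest
    for _, block in man.groupby("block"):
        assert sorted(block["condition"]) == sorted(cfg_small.conditions)
    assert len(sess.trials) == 4 * cfg_small.n_trials_per_condition


def test_session_landmarks_equal_warp_at_landmarks(cfg_small, gt_small):
    sess = sim.gen_session(cfg_small, gt_small, "S2", 3, max_warp_px=8.0)
    disp = sess.warp_fn(sess.landmarks_session)
    np.testing.assert_allclose(
        sess.landmarks_reference, sess.landmarks_session + disp, atol=1e-12
    )
    assert np.abs(disp).max() <= 8.0 + 1e-9


def test_identity_warp_session(cfg_small, gt_small):
    sess = sim.gen_session(cfg_small, gt_small, "S3", 3, max_warp_px=0.0)
    np.testing.assert_allclose(
        sess.landmarks_reference, sess.landmarks_session, atol=1e-12
    )


def test_session_streaming_matches_materialized(cfg_small, gt_small):
    cfg = dataclasses.replace(cfg_small, n_trials_per_condition=2)
    sess = sim.gen_session(cfg, gt_small, "S4", 5)
    regenerated = list(
        sim.SessionRecord(
            session_id="S4", trials=[], landmarks_session=sess.landmarks_session,
            landmarks_reference=sess.landmarks_reference, warp_fn=sess.warp_fn,
            manifest=sess.manifest, cfg=cfg,
        ).iter_trials(gt_small)
    )
    for a, b in zip(sess.trials, regenerated):
        assert a.frames.tobytes() == b.frames.tobytes()


def test_emg_withhold_flat(cfg_small):
    quiet = sim.gen_emg_trial("withhold", "arm", cfg_small, 3)
    active = sim.gen_emg_trial("precision", "arm", cfg_small, 3)
    assert quiet.samples.std() < 3.0        # noise floor only (2 uV)
    assert active.samples.std() > 3 * quiet.samples.std()


def test_emg_condition_ordering(cfg_small):
    peaks = {}
    for cond in sim.MOVEMENT_CONDITIONS:
        t = sim.gen_emg_trial(cond, "arm", cfg_small, 4)
        peaks[cond] = bh.emg_envelope(t).max()
    assert peaks["precision"] > peaks["power"] > peaks["reach-only"]


def test_kin_round_trip_exact(cfg_small):
    t = np.arange(int(7 * 480)) / 480 - 1.0
    curve = 30 + 60 * np.clip((t - 0.5) / 1.5, 0, 1)  # programmed 30->90 sweep
    trial = sim.gen_kin_trial(
        "precision", "elbow", cfg_small, 5, angle_curve_deg=curve
    )
    recomputed = bh.joint_angle(trial)
    np.testing.assert_allclose(recomputed, curve, atol=1e-6)


def test_kin_pronation_round_trip(cfg_small):
    trial = sim.gen_kin_trial(
        "power", "forearm", cfg_small, 6, dof="pronation/supination"
    )
    recomputed = bh.joint_angle(trial)
    np.testing.assert_allclose(recomputed, trial.true_angle_deg, atol=1e-6)


def test_emg_artifact_exceeds_screen_threshold(cfg_small):
    t = sim.gen_emg_trial("withhold", "hand", cfg_small, 8, artifact=True)
    p = bh.band_power(t.samples, t.fs_hz, (1.0, 14.0))
    # injected 8 Hz sinusoid of amplitude 6 uV: analytic power 18 uV^2
    assert p > 7.0
    assert abs(p - 18.0) < 4.0  # noise contributes a little
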