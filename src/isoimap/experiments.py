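"""End-to-end validation experiments on the synthetic study conditions.

Each function runs one self-contained recovery experiment against the
simulator's hidden truth — null calibration of the pixelwise test,
patch and overlap recovery, registration/exclusion/warp accuracy,
peak-time and ROI structure, condition-contrast ordering, and
behavioral AUC ordering — and returns a flat dict of measured numbers.
They are the computational backbone of the acceptance checks and of
``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from . import behavior as bh
from . import contrast as ct
from . import mapping as mp
from . import preprocess as pp
from . import simulate as sim
from .mapping import FrameWindow, ROISpec
from .workflow import RunConfig, _forelimb_from_sites

__all__ = [
    "run_null_calibration",
    "run_patch_recovery",
    "run_registration_validation",
    "run_condition_contrast",
    "run_behavior_validation",
]


def _cond_index(cond: str) -> int:
    return sim.CONDITIONS.index(cond)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = int((a & b).sum())
    denom = int(a.sum()) + int(b.sum())
    return 2.0 * inter / denom if denom else 0.0


def run_null_calibration(
    seed: int, n_trials: int = 200, size: int = 128, alpha: float = 1e-4
) -> dict:
    """Null calibration of the thresholded-map test on signal-free data.

    A signal-free session (withhold condition: noise only) is
    generated; per-trial baseline and movement frames are compared with
    the left-tailed pixelwise t-test on baseline-normalized, spatially
    unfiltered stacks (spatial filtering correlates neighbours and
    would invalidate the independent-pixel binomial band on the
    significant-pixel count, not the per-pixel calibration itself).
    """
    cfg = dataclasses.replace(
        sim.SimConfig(seed=seed), image_height_px=size, image_width_px=size,
        rigid_jitter_px=0.0, motion_artifact_px=0.0,
        n_trials_per_condition=n_trials,
    )
    gt = sim.make_ground_truth(cfg, seed)
    times = cfg.frame_times
    win_b, win_m = FrameWindow.baseline(), FrameWindow.movement39()
    baselines, movements = [], []
    for k in range(n_trials):
        ts = sim.gen_trial_stack("withhold", gt, cfg, seed * 100_003 + k)
        norm = pp.normalize_to_baseline(ts)
        baselines.append(mp.window_average(norm.frames, times, win_b))
        movements.append(mp.window_average(norm.frames, times, win_m))
    res = mp.pixelwise_ttest_map(
        np.array(movements), np.array(baselines), tail="left", alpha=alpha
    )
    n_px = res.mask.size
    frac = float(res.mask.mean())
    band = 3.0 * float(np.sqrt(alpha * (1 - alpha) / n_px))
    denoised = mp.denoise_components(res.mask & ~gt.vessel_mask)
    forelimb = _forelimb_from_sites(RunConfig(sim=cfg), gt)
    return {
        "alpha": alpha,
        "n_pixels": n_px,
        "raw_significant_fraction": frac,
        "binomial_band_3sd": band,
        "within_band": bool(abs(frac - alpha) <= band),
        "denoised_forelimb_overlap_pct": mp.overlap_percent(denoised, forelimb),
    }


def run_patch_recovery(seed: int, n_trials: int = 50, alpha: float = 1e-4) -> dict:
    """Full-pipeline patch recovery on the default study conditions.

    4 conditions x ``n_trials`` trials at 128 x 128 px are generated,
    registered, screened, normalized and filtered; thresholded maps
    (39-frame movement window, left tail) are compared against the
    hidden patch truth, and the precision-condition average time series
    yields peak-time-class and ROI time-course recovery.
    """
    cfg = dataclasses.replace(sim.SimConfig(seed=seed),
                              n_trials_per_condition=n_trials)
    gt = sim.make_ground_truth(cfg, seed)
    run_cfg = RunConfig(sim=cfg, seed=seed)
    filt = run_cfg.filt
    session = sim.gen_session(cfg, gt, "S1", seed, materialize=False)
    times = cfg.frame_times
    mid = session.manifest.iloc[len(session.manifest) // 2]
    reference = sim.gen_trial_stack(mid.condition, gt, cfg, int(mid.seed)).frames[0]
    win_b, win_m = FrameWindow.baseline(), FrameWindow.movement39()
    acc = {
        c: {"b": [], "m": [], "sum": None, "n": 0} for c in cfg.conditions
    }
    n_excluded = 0
    for ts in session.iter_trials(gt):
        proc = pp.preprocess_trial(ts, reference, filt)
        if proc.excluded:
            n_excluded += 1
            continue
        a = acc[proc.condition]
        a["b"].append(mp.window_average(proc.frames, times, win_b))
        a["m"].append(mp.window_average(proc.frames, times, win_m))
        a["sum"] = proc.frames if a["sum"] is None else a["sum"] + proc.frames
        a["n"] += 1

    forelimb = _forelimb_from_sites(run_cfg, gt)
    out: dict = {"n_excluded": n_excluded, "n_trials": n_trials}
    for cond in cfg.conditions:
        a = acc[cond]
        tm = mp.threshold_map(
            np.array(a["m"]), np.array(a["b"]), tail="left", alpha=alpha,
            vessel_mask=gt.vessel_mask, condition=cond,
        )
        ov = mp.overlap_percent(tm.mask, forelimb)
        active = gt.active_patch_union(cond)
        truth_ov = (
            100.0 * int((active & forelimb.countable()).sum()) / forelimb.n_countable
        )
        out[f"overlap_pct:{cond}"] = ov
        out[f"truth_overlap_pct:{cond}"] = truth_ov
        out[f"dice:{cond}"] = _dice(tm.mask, active)

    # peak-time and ROI structure from the precision average series
    avg = acc["precision"]["sum"] / acc["precision"]["n"]
    pt = mp.peak_time_map(avg, times)
    for p in gt.patches:
        inj = sim.response_timecourse(p.profile, times, "precision")
        true_peak = float(times[np.argmin(inj)])
        sel = p.mask & pt.valid
        out[f"peak_time_true:{p.name}"] = true_peak
        out[f"peak_time_recovered:{p.name}"] = float(np.nanmedian(pt.time_s[sel]))

    hand = gt.patches[0]
    cy, cx = np.argwhere(hand.mask).mean(axis=0)
    roi_px = 0.4 * cfg.px_per_mm  # the study's 0.4-mm circles
    tc_hand = mp.roi_timecourse(
        avg, mp.circle_roi((cy, cx), roi_px, avg.shape[1:]), gt.vessel_mask
    )
    arm = next(p for p in gt.patches if p.zone == "arm" and p.profile.pos_frac > 0)
    ay, ax = np.argwhere(arm.mask).mean(axis=0)
    tc_arm = mp.roi_timecourse(
        avg, mp.circle_roi((ay, ax), roi_px, avg.shape[1:]), gt.vessel_mask
    )
    tc_fl = mp.roi_timecourse(
        avg, ROISpec("forelimb", forelimb.countable()), gt.vessel_mask
    )
    early = (times > 0.8) & (times < 2.0)
    out.update(
        {
            "hand_roi_peak": float(tc_hand.min()),
            "hand_roi_flat_window_max_abs": float(np.abs(tc_hand[early]).max()),
            "arm_roi_positive_max": float(tc_arm[early].max()),
            "arm_roi_peak": float(tc_arm.min()),
            "forelimb_roi_peak": float(tc_fl.min()),
            "forelimb_to_hand_peak_ratio": float(tc_fl.min() / tc_hand.min()),
        }
    )
    return out


def run_registration_validation(seed: int, n_trials: int = 10) -> dict:
    """Rigid-shift recovery, exclusion accuracy, and warp-fit residuals."""
    cfg = dataclasses.replace(sim.SimConfig(seed=seed), rigid_jitter_px=8.0)
    gt = sim.make_ground_truth(cfg, seed)
    worst = 0.0
    for k in range(n_trials):
        ts = sim.gen_trial_stack("power", gt, cfg, seed * 91_003 + k)
        truth = ts.true_shifts_px.copy()
        reg = pp.register_stack(ts, gt.base_image)
        worst = max(worst, float(np.abs(reg.shifts_px + truth).max()))

    # exclusion: half the trials get an injected >10 px excursion; the
    # rest carry only the default jitter (well inside the 10-px limit)
    cfg_screen = dataclasses.replace(cfg, rigid_jitter_px=1.0)
    gt_screen = sim.make_ground_truth(cfg_screen, seed)
    decisions_ok = 0
    n_screen = 12
    for k in range(n_screen):
        ts = sim.gen_trial_stack("power", gt_screen, cfg_screen, seed * 77_003 + k)
        bad = k % 2 == 0
        if bad:
            ts.frames[30] = ndi.shift(
                ts.frames[30], (12.0, 3.0), order=1, mode="nearest"
            )
        reg = pp.register_stack(ts, gt_screen.base_image)
        keep, _ = pp.screen_registration(reg.shifts_px, 10.0)
        decisions_ok += int(keep == (not bad))

    sess = sim.gen_session(cfg, gt, "W", seed, max_warp_px=15.0, n_landmarks=40,
                           materialize=False)
    warp = pp.fit_session_warp(
        sess.landmarks_session, sess.landmarks_reference,
        (cfg.image_height_px, cfg.image_width_px), levels=5,
    )
    return {
        "max_shift_error_px": worst,
        "screen_accuracy": decisions_ok / n_screen,
        "warp_landmark_rms_px": warp.residual_rms_px,
        "warp_jacobian_ok": bool(warp.jacobian_ok()),
    }


def run_condition_contrast(seed: int, n_trials: int = 50) -> dict:
    """Zero-lag correlation ordering across condition pairs, two subjects.

    Trial-averaged series per condition for two simulated subjects,
    correlated frame-by-frame over the forelimb representation in the
    39 post-movement frames: 78 coefficients per pair.  Also the
    precision-vs-reach-only paired t-map against the grasp-patch truth.
    """
    pairs_mm = [("precision", "power"), ("precision", "reach-only"),
                ("power", "reach-only")]
    pairs_wh = [(c, "withhold") for c in sim.MOVEMENT_CONDITIONS]
    rs: dict = {p: [] for p in pairs_mm + pairs_wh}
    paired_dice = None
    for subject in (0, 1):
        sseed = seed + 7919 * subject
        cfg = dataclasses.replace(
            sim.SimConfig(seed=sseed), rigid_jitter_px=0.0,
            motion_artifact_px=0.0, n_trials_per_condition=n_trials,
        )
        gt = sim.make_ground_truth(cfg, sseed)
        forelimb = _forelimb_from_sites(RunConfig(sim=cfg), gt)
        times = cfg.frame_times
        avgs, movs, bases = {}, {}, {}
        for cond in cfg.conditions:
            s = None
            mv, bs = [], []
            for k in range(n_trials):
                ts = sim.gen_trial_stack(cond, gt, cfg, sseed * 59 + 1000 * _cond_index(cond) + k)
                norm = pp.normalize_to_baseline(ts)
                s = norm.frames if s is None else s + norm.frames
                mv.append(mp.window_average(norm.frames, times,
                                            FrameWindow.movement39()))
                bs.append(mp.window_average(norm.frames, times,
                                            FrameWindow.baseline()))
            avgs[cond] = s / n_trials
            movs[cond] = np.array(mv)
        for p in rs:
            rs[p].extend(
                ct.condition_pair_series(avgs[p[0]], avgs[p[1]], times,
                                         forelimb, pair=p).r
            )
        if subject == 0:
            pmap = ct.paired_condition_map(
                movs["precision"], movs["reach-only"], alpha=1e-3,
                vessel_mask=gt.vessel_mask,
            )
            paired_dice = _dice(pmap.mask, gt.grasp_patch_union)

    means = {p: float(np.mean(rs[p])) for p in pairs_mm}
    mm_all = np.concatenate([rs[p] for p in pairs_mm])
    wh_all = np.concatenate([rs[p] for p in pairs_wh])
    anova = ct.anova_posthoc(
        {f"{a}|{b}": np.array(rs[(a, b)]) for a, b in pairs_mm}
    )
    return {
        "n_coeffs_per_pair": len(rs[pairs_mm[0]]),
        "n_withhold_coeffs": int(wh_all.size),
        "mean_r:precision|power": means[("precision", "power")],
        "mean_r:precision|reach-only": means[("precision", "reach-only")],
        "mean_r:power|reach-only": means[("power", "reach-only")],
        "min_pair_is_precision_reach_only": bool(
            min(means, key=means.get) == ("precision", "reach-only")
        ),
        "movement_min_r": float(mm_all.min()),
        "withhold_max_r": float(wh_all.max()),
        "withhold_fully_below_movement": bool(wh_all.max() < mm_all.min()),
        "anova_F": anova.F,
        "anova_p": anova.p,
        "paired_map_grasp_dice": paired_dice,
    }


def run_behavior_validation(seed: int, n_trials: int = 30) -> dict:
    """AUC ordering recovery with ANOVA + corrected post hocs."""
    import pandas as pd

    cfg = sim.SimConfig(seed=seed)
    recs = []
    signals = [("biceps", "arm"), ("FCR", "hand")]
    joints = [("elbow", "arm"), ("wrist", "hand")]
    n_dropped = 0
    for cond in sim.MOVEMENT_CONDITIONS:
        for k in range(n_trials):
            for mus, grp in signals:
                t = sim.gen_emg_trial(
                    cond, grp, cfg,
                    seed * 31 + 1000 * _cond_index(cond) + 10 * k + (grp == "hand"),
                    muscle=mus,
                )
                keep, _ = bh.emg_artifact_screen(t)
                if not keep:
                    n_dropped += 1
                    continue
                env = bh.emg_envelope(t)
                recs.append(
                    {"trial_id": f"e{cond}{k}{mus}", "session": "S1",
                     "signal": f"emg:{mus}", "condition": cond,
                     "auc_raw": bh.auc(env, t.fs_hz, -1.0, 0.0,
                                       t.withdrawal_end_s)}
                )
            for joint, grp in joints:
                t = sim.gen_kin_trial(
                    cond, joint, cfg,
                    seed * 37 + 1000 * _cond_index(cond) + 10 * k + (grp == "hand"),
                )
                keep, _ = bh.kin_dropout_screen(t)
                if not keep:
                    n_dropped += 1
                    continue
                ang = bh.joint_angle(t)
                recs.append(
                    {"trial_id": f"k{cond}{k}{joint}", "session": "S1",
                     "signal": f"kin:{joint}", "condition": cond,
                     "auc_raw": bh.auc(ang, t.fs_hz, -1.0, 0.0,
                                       t.withdrawal_end_s)}
                )
    df = bh.standardize_auc(pd.DataFrame(recs))
    groups_map = {"emg:biceps": "arm", "emg:FCR": "hand",
                  "kin:elbow": "arm", "kin:wrist": "hand"}
    summary, _ = bh.group_summary(df, groups_map)
    combined = summary[summary.group == "combined"].set_index("condition")
    anova = ct.anova_posthoc(
        {c: df.loc[df.condition == c, "auc_z"].to_numpy()
         for c in sim.MOVEMENT_CONDITIONS}
    )
    ordering_ok = (
        combined.loc["precision", "weighted_mean"]
        > combined.loc["power", "weighted_mean"]
        > combined.loc["reach-only", "weighted_mean"]
    )
    return {
        "mean_auc_z:precision": float(combined.loc["precision", "weighted_mean"]),
        "mean_auc_z:power": float(combined.loc["power", "weighted_mean"]),
        "mean_auc_z:reach-only": float(combined.loc["reach-only", "weighted_mean"]),
        "ordering_recovered": bool(ordering_ok),
        "anova_F": anova.F,
        "anova_p": anova.p,
        "n_significant_posthocs": len(anova.significant_pairs(0.01)),
        "n_trials_dropped": n_dropped,
    }
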