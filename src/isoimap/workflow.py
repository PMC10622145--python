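"""End-to-end pipeline: simulate -> preprocess -> map -> contrast -> behavior.

One declarative :class:`RunConfig` drives every stage; all randomness
flows from a single global seed through named substreams, so a rerun
with the same config and seed reproduces every tabular artifact
byte-for-byte.  Each stage writes its artifacts (CSV/TIFF/NPZ) into a
stage directory under ``outdir`` and records itself in the run report;
a completed stage is skipped on rerun unless forced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString

from . import behavior as bh
from . import contrast as ct
from . import mapping as mp
from . import motormap as mm
from . import preprocess as pp
from . import simulate as sim

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "map", "contrast", "behavior", "report")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    filt: pp.FilterConfig = field(
        # kernel sizes are native-acquisition pixels (20 um/px, 50 px/mm);
        # at the simulator's 10 px/mm both scale by the same 1/5 factor:
        # median 250 -> 51 (odd-forced), Gaussian window 5 -> 1
        default_factory=lambda: pp.FilterConfig(
            median_kernel_px=51, gaussian_kernel_px=1.0
        )
    )
    alpha: float = 1e-4
    paired_alpha: float = 1e-3
    tail: str = "left"
    min_component_px: int = 11
    connectivity: int = 8
    movement_window: str = "movement39"   # or "movement5"
    movement5_end_s: float = 4.4
    do_register: bool = True
    do_filter: bool = True
    save_stacks: bool = False
    n_behavior_trials: int = 20
    pm_divide_y_mm: float = 9.0
    stages: tuple[str, ...] = STAGES
    outdir: str = "isoimap_run"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sim"]["conditions"] = list(d["sim"]["conditions"])
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["sim"]["conditions"] = tuple(d["sim"]["conditions"])
        d["sim"] = sim.SimConfig(**d["sim"])
        d["filt"] = pp.FilterConfig(**d["filt"])
        d["stages"] = tuple(d["stages"])
        return cls(**d)


def validate_config(config: RunConfig) -> list[str]:
    """Schema/bounds checks; returns a list of violations (empty = ok)."""
    v: list[str] = []
    c = config
    times = c.sim.frame_times
    # frame stamps mark exposure ends; acquisition starts at t0_s
    span = (float(c.sim.t0_s), float(times[-1]))
    for w in (mp.FrameWindow.baseline(), mp.FrameWindow.movement39(),
              mp.FrameWindow.movement5(c.movement5_end_s)):
        if w.start_s < span[0] - 1e-9 or w.end_s > span[1] + 1e-9:
            v.append(
                f"window {w.label} [{w.start_s}, {w.end_s}] outside "
                f"acquisition span {span}"
            )
    if c.alpha <= 0 or c.alpha >= 1:
        v.append(f"alpha must be in (0, 1), got {c.alpha}")
    if c.paired_alpha <= 0 or c.paired_alpha >= 1:
        v.append(f"paired_alpha must be in (0, 1), got {c.paired_alpha}")
    k = int(c.filt.median_kernel_px) | 1
    if k >= min(c.sim.image_height_px, c.sim.image_width_px):
        v.append(
            f"median kernel ({k} px) must be smaller than the image "
            f"({c.sim.image_height_px}x{c.sim.image_width_px})"
        )
    known = set(sim.CONDITIONS)
    for cond in c.sim.conditions:
        if cond not in known:
            v.append(f"unknown condition {cond!r}")
    for s in c.stages:
        if s not in STAGES:
            v.append(f"unknown stage {s!r}")
    if c.movement_window not in ("movement39", "movement5"):
        v.append(f"unknown movement window {c.movement_window!r}")
    if c.tail not in ("left", "right"):
        v.append(f"tail must be left or right, got {c.tail!r}")
    return v


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    seed: int
    version: str
    stages_run: list[str] = field(default_factory=list)
    n_trials: dict[str, int] = field(default_factory=dict)
    excluded_trials: list[dict] = field(default_factory=list)
    maps: list[dict] = field(default_factory=list)
    overlap_percent: dict[str, float] = field(default_factory=dict)
    contrast: list[dict] = field(default_factory=list)
    anova: dict = field(default_factory=dict)
    behavior_summary: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _done(stage_dir: Path) -> bool:
    return (stage_dir / "_done").exists()


def _mark_done(stage_dir: Path) -> None:
    (stage_dir / "_done").write_text("done\n")


def _forelimb_from_sites(config: RunConfig, gt: sim.GroundTruth) -> mm.ForelimbMask:
    """Reconstruct the forelimb mask from the ICMS site table alone."""
    site_cols = ["x_mm", "y_mm", "joint", "movement", "threshold_uA"]
    mmap = mm.MotorMap.from_site_table(
        gt.sites[site_cols],
        bounds=(0.0, 0.0,
                config.sim.image_width_px / config.sim.px_per_mm,
                config.sim.image_height_px / config.sim.px_per_mm),
    )
    h_mm = config.sim.image_height_px / config.sim.px_per_mm
    cs = LineString([(0.0, 0.0), (0.0, h_mm)])
    mm.delineate_m1_border(mmap, cs, pm_divide_y_mm=config.pm_divide_y_mm)
    return mm.rasterize_forelimb_mask(
        mmap, config.sim.geometry, vessel_mask=gt.vessel_mask
    )


def run_pipeline(config: RunConfig, force: bool = False) -> RunReport:
    """Execute the configured stages in dependency order.

    Identical config + seed produce identical artifacts.  Completed
    stages (marker file present) are skipped unless ``force``.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    from . import __version__

    report = RunReport(seed=config.seed, version=__version__)
    cfg = config.sim
    conditions = list(cfg.conditions)

    # ---- simulate -------------------------------------------------------
    gt = sim.make_ground_truth(cfg, config.seed)
    session = None
    sim_dir = out / "simulate"
    if "simulate" in config.stages:
        sim_dir.mkdir(exist_ok=True)
        session = sim.gen_session(cfg, gt, "S1", config.seed, materialize=False)
        if not _done(sim_dir) or force:
            gt.sites.to_csv(sim_dir / "sites.csv", index=False)
            session.manifest.to_csv(sim_dir / "manifest.csv", index=False)
            np.savez_compressed(
                sim_dir / "ground_truth.npz",
                forelimb_mask=gt.forelimb_mask,
                patch_union=gt.patch_union,
                vessel_mask=gt.vessel_mask,
                base_image=gt.base_image,
            )
            lm = pd.DataFrame(
                np.hstack([session.landmarks_session, session.landmarks_reference]),
                columns=["x_session", "y_session", "x_reference", "y_reference"],
            )
            lm.to_csv(sim_dir / "landmarks.csv", index=False)
            if config.save_stacks:
                for ts in session.iter_trials(gt):
                    sim.write_trial_tiff(sim_dir / f"{ts.trial_id}.tiff", ts)
            _mark_done(sim_dir)
        report.stages_run.append("simulate")
        report.n_trials = {
            c: int((session.manifest["condition"] == c).sum()) for c in conditions
        }

    # ---- preprocess -----------------------------------------------------
    pre_dir = out / "preprocess"
    cond_data: dict[str, dict] = {}
    if "preprocess" in config.stages:
        pre_dir.mkdir(exist_ok=True)
        if _done(pre_dir) and not force:
            for cond in conditions:
                z = np.load(pre_dir / f"cond_{cond}.npz")
                cond_data[cond] = {k: z[k] for k in z.files}
            if (pre_dir / "exclusions.csv").exists():
                report.excluded_trials = pd.read_csv(
                    pre_dir / "exclusions.csv"
                ).to_dict("records")
        else:
            if session is None:
                raise FileNotFoundError(
                    "preprocess stage needs the simulate stage (missing session data)"
                )
            mid = session.manifest.iloc[len(session.manifest) // 2]
            reference = sim.gen_trial_stack(
                mid.condition, gt, cfg, int(mid.seed)
            ).frames[0]
            times = cfg.frame_times
            win_move = (
                mp.FrameWindow.movement39()
                if config.movement_window == "movement39"
                else mp.FrameWindow.movement5(config.movement5_end_s)
            )
            win_base = mp.FrameWindow.baseline()
            win5 = mp.FrameWindow.movement5(config.movement5_end_s)
            acc: dict[str, dict] = {
                c: {"baseline": [], "movement": [], "movement5": [], "sum": None,
                    "n": 0}
                for c in conditions
            }
            exclusions = []
            for ts in session.iter_trials(gt):
                proc = pp.preprocess_trial(
                    ts, reference, config.filt,
                    do_register=config.do_register, do_filter=config.do_filter,
                )
                if proc.excluded:
                    exclusions.append(
                        {"trial_id": ts.trial_id, "condition": ts.condition,
                         "reason": proc.exclusion_reason}
                    )
                    continue
                a = acc[proc.condition]
                a["baseline"].append(mp.window_average(proc.frames, times, win_base))
                a["movement"].append(mp.window_average(proc.frames, times, win_move))
                a["movement5"].append(mp.window_average(proc.frames, times, win5))
                a["sum"] = proc.frames if a["sum"] is None else a["sum"] + proc.frames
                a["n"] += 1
            for cond in conditions:
                a = acc[cond]
                cond_data[cond] = {
                    "baseline": np.array(a["baseline"], dtype=np.float32),
                    "movement": np.array(a["movement"], dtype=np.float32),
                    "movement5": np.array(a["movement5"], dtype=np.float32),
                    "avg_stack": (a["sum"] / max(a["n"], 1)).astype(np.float32),
                    "n_trials": np.array(a["n"]),
                }
                np.savez_compressed(pre_dir / f"cond_{cond}.npz", **cond_data[cond])
            pd.DataFrame(
                exclusions, columns=["trial_id", "condition", "reason"]
            ).to_csv(pre_dir / "exclusions.csv", index=False)
            report.excluded_trials = exclusions
            _mark_done(pre_dir)
        report.stages_run.append("preprocess")

    forelimb = _forelimb_from_sites(config, gt)

    def _need_cond_data(stage: str) -> None:
        if cond_data:
            return
        for cond in conditions:
            f = pre_dir / f"cond_{cond}.npz"
            if not f.exists():
                raise FileNotFoundError(
                    f"stage {stage!r} is missing the upstream preprocess "
                    f"artifact {f}"
                )
            z = np.load(f)
            cond_data[cond] = {k: z[k] for k in z.files}

    # ---- map ------------------------------------------------------------
    if "map" in config.stages:
        _need_cond_data("map")
        import tifffile

        map_dir = out / "map"
        map_dir.mkdir(exist_ok=True)
        rows = []
        for cond in conditions:
            d = cond_data[cond]
            tail = "left"
            tm = mp.threshold_map(
                d["movement"], d["baseline"], tail=tail, alpha=config.alpha,
                min_component_px=config.min_component_px,
                connectivity=config.connectivity, vessel_mask=gt.vessel_mask,
                window_label=config.movement_window, condition=cond,
            )
            tm_bonf = mp.threshold_map(
                d["movement"], d["baseline"], tail=tail, alpha=config.alpha,
                bonferroni_n=forelimb.n_countable,
                min_component_px=config.min_component_px,
                connectivity=config.connectivity, vessel_mask=gt.vessel_mask,
                window_label=config.movement_window, condition=cond,
            )
            ov = mp.overlap_percent(tm.mask, forelimb)
            ov_b = mp.overlap_percent(tm_bonf.mask, forelimb)
            tifffile.imwrite(
                map_dir / f"map_{cond}.tiff", tm.mask.astype(np.uint8) * 255
            )
            rows.append(
                {"condition": cond, "window": config.movement_window,
                 "alpha": config.alpha, "tail": tail,
                 "n_trials": int(d["n_trials"]),
                 "overlap_percent": round(ov, 6),
                 "overlap_percent_bonferroni": round(ov_b, 6)}
            )
            report.overlap_percent[cond] = ov
            report.maps.append(rows[-1])
        pd.DataFrame(rows).to_csv(map_dir / "overlap.csv", index=False)
        report.stages_run.append("map")

    # ---- contrast -------------------------------------------------------
    if "contrast" in config.stages:
        _need_cond_data("contrast")
        con_dir = out / "contrast"
        con_dir.mkdir(exist_ok=True)
        times = cfg.frame_times
        movement = [c for c in conditions if c != "withhold"]
        rows = []
        for i, a in enumerate(movement):
            for b_ in movement[i + 1:] + (["withhold"] if "withhold" in conditions else []):
                res = ct.condition_pair_series(
                    cond_data[a]["avg_stack"].astype(float),
                    cond_data[b_]["avg_stack"].astype(float),
                    times, forelimb, pair=(a, b_),
                )
                for k, r in enumerate(res.r):
                    rows.append({"pair": f"{a}|{b_}", "frame": k, "r": round(float(r), 8)})
                report.contrast.append(
                    {"pair": f"{a}|{b_}", "mean_r": float(np.mean(res.r))}
                )
        pd.DataFrame(rows).to_csv(con_dir / "pair_correlations.csv", index=False)
        if {"precision", "reach-only"} <= set(conditions):
            pmap = ct.paired_condition_map(
                cond_data["precision"]["movement"],
                cond_data["reach-only"]["movement"],
                alpha=config.paired_alpha,
                min_component_px=config.min_component_px,
                connectivity=config.connectivity, vessel_mask=gt.vessel_mask,
            )
            import tifffile

            tifffile.imwrite(
                con_dir / "precision_gt_reach-only.tiff",
                pmap.mask.astype(np.uint8) * 255,
            )
        report.stages_run.append("contrast")

    # ---- behavior -------------------------------------------------------
    if "behavior" in config.stages:
        beh_dir = out / "behavior"
        beh_dir.mkdir(exist_ok=True)
        movement = [c for c in conditions if c != "withhold"]
        signals = [("biceps", "arm"), ("FCR", "hand")]
        joints = [("elbow", "arm"), ("wrist", "hand")]
        recs = []
        for cond in movement:
            for k in range(config.n_behavior_trials):
                for mus, grp in signals:
                    tseed = int(np.random.SeedSequence(
                        (config.seed, 21, conditions.index(cond), k, grp == "hand")
                    ).generate_state(1)[0] % (2**31))
                    t = sim.gen_emg_trial(cond, grp, cfg, tseed, muscle=mus)
                    keep, _ = bh.emg_artifact_screen(t)
                    if not keep:
                        continue
                    env = bh.emg_envelope(t)
                    recs.append(
                        {"trial_id": f"emg-{cond}-{k}-{mus}", "session": "S1",
                         "signal": f"emg:{mus}", "condition": cond,
                         "auc_raw": bh.auc(env, t.fs_hz, -1.0, t.cue_s,
                                           t.withdrawal_end_s)}
                    )
                for joint, grp in joints:
                    tseed = int(np.random.SeedSequence(
                        (config.seed, 22, conditions.index(cond), k, grp == "hand")
                    ).generate_state(1)[0] % (2**31))
                    t = sim.gen_kin_trial(cond, joint, cfg, tseed)
                    keep, _ = bh.kin_dropout_screen(t)
                    if not keep:
                        continue
                    ang = bh.joint_angle(t)
                    recs.append(
                        {"trial_id": f"kin-{cond}-{k}-{joint}", "session": "S1",
                         "signal": f"kin:{joint}", "condition": cond,
                         "auc_raw": bh.auc(ang, t.fs_hz, -1.0, t.cue_s,
                                           t.withdrawal_end_s)}
                    )
        df = pd.DataFrame(recs)
        df = bh.standardize_auc(df)
        groups_map = {"emg:biceps": "arm", "emg:FCR": "hand",
                      "kin:elbow": "arm", "kin:wrist": "hand"}
        summary, per_signal = bh.group_summary(df, groups_map)
        df.to_csv(beh_dir / "auc_records.csv", index=False)
        summary.to_csv(beh_dir / "auc_summary.csv", index=False)
        res = ct.anova_posthoc(
            {c: df.loc[df["condition"] == c, "auc_z"].to_numpy() for c in movement}
        )
        report.anova = {
            "F": res.F, "df": [res.df_between, res.df_within], "p": res.p,
            "group_means": res.group_means,
            "posthoc": {f"{a}|{b}": p for (a, b), p in res.posthoc.items()},
        }
        report.behavior_summary = summary.to_dict("records")
        report.stages_run.append("behavior")

    # ---- report ---------------------------------------------------------
    if "report" in config.stages:
        report.to_json(out / "report.json")
        report.stages_run.append("report")
    return report
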