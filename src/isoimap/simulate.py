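"""Synthetic ISOI sessions with known ground truth.

Generates everything the analysis pipeline consumes — trial image
stacks, ICMS site tables, EMG traces, LED-marker trajectories — with
the statistical structure the pipeline assumes, and emits the hidden
truth (patch masks, amplitudes, peak times, warps, per-frame shifts,
AUC orderings) so every downstream stage has a recovery target.

The emulated study conditions: an instructed reach-to-grasp task with
four conditions (precision grip, power grip, reach-only, withhold);
imaging at 10 frames/s for 7 s starting 1 s before the Cue (70 frames,
12-bit counts); movement from ~+0.5 s; hemodynamic "patches" inside the
forelimb representation whose time courses follow two zone profiles —
arm (positive reflectance during movement/hold, then a negative peak)
and hand (flat until ~+2.5 s, then a negative peak) — plus early
negative vessel dynamics, per-frame rigid jitter, a brief motion
artifact at movement onset, and smooth session-to-session warps.
Forelimb activity amplitude is ordered precision > power > reach-only,
with the withhold condition silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .motormap import ImageGeometry
from .preprocess import TrialStack

__all__ = [
    "CONDITIONS",
    "MOVEMENT_CONDITIONS",
    "SimConfig",
    "ResponseProfile",
    "Patch",
    "GroundTruth",
    "SessionRecord",
    "EMGTrial",
    "KinTrial",
    "response_timecourse",
    "gen_motor_sites",
    "make_ground_truth",
    "gen_trial_stack",
    "gen_session",
    "gen_emg_trial",
    "gen_kin_trial",
    "write_trial_tiff",
    "read_trial_tiff",
]

CONDITIONS = ("precision", "power", "reach-only", "withhold")
MOVEMENT_CONDITIONS = ("precision", "power", "reach-only")


def _sub_rng(seed: int, *key: int) -> np.random.Generator:
    """Named substream: deterministic child generator of ``seed``."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, *key))))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulator.

    Geometry defaults give a 12.8 x 12.8 mm field of view at 10 px/mm —
    coarse enough for desk-scale runs while leaving the motor-map
    geometry (0.75-mm tiles, 0.4-mm ROIs) several pixels wide.
    Amplitudes are peak |dR/R| per condition (the literature-typical
    1e-3 scale); noise_sd is the per-pixel, per-frame reflectance noise.
    """

    image_height_px: int = 128
    image_width_px: int = 128
    px_per_mm: float = 10.0
    frame_rate_hz: float = 10.0
    n_frames: int = 70
    t0_s: float = -1.0
    n_trials_per_condition: int = 50
    conditions: tuple[str, ...] = CONDITIONS
    # Peak |dR/R| of the *shared* (arm-zone) patches per condition.  Arm
    # engagement is nearly equal across the three movement conditions
    # (reach and transport are common to all); the strong condition
    # differences live in the grasp-selective patches (see
    # grasp_amplitude), mirroring the near-identical arm kinematics but
    # divergent digit use across grips.
    condition_amplitude: dict[str, float] = field(
        default_factory=lambda: {
            "precision": 1.2e-3,
            "power": 1.2e-3,
            "reach-only": 1.1e-3,
            "withhold": 0.0,
        }
    )
    # Peak |dR/R| of the grasp-selective patches: strong for precision
    # grip, halved for power grip, nearly silent without a grasp.
    grasp_amplitude: dict[str, float] = field(
        default_factory=lambda: {
            "precision": 1.2e-3,
            "power": 0.6e-3,
            "reach-only": 0.1e-3,
            "withhold": 0.0,
        }
    )
    movement_onset_s: dict[str, float] = field(
        default_factory=lambda: {
            "precision": 0.5, "power": 0.5, "reach-only": 0.5,
        }
    )
    movement_offset_s: dict[str, float] = field(
        default_factory=lambda: {
            "precision": 2.2, "power": 2.0, "reach-only": 1.3,
        }
    )
    noise_sd: float = 1.5e-3
    rigid_jitter_px: float = 1.0
    motion_artifact_px: float = 3.0
    base_counts: float = 2000.0
    site_spacing_mm: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for amp in (self.condition_amplitude, self.grasp_amplitude):
            if amp.get("withhold", 0.0) != 0.0:
                raise ValueError("withhold amplitude must be 0")
            if not (
                amp.get("precision", 0) >= amp.get("power", 0)
                >= amp.get("reach-only", 0)
            ):
                raise ValueError(
                    "amplitudes must be ordered precision >= power >= reach-only"
                )
        if not (0.5 <= self.site_spacing_mm <= 1.0):
            raise ValueError("site grid spacing must be 0.5-1.0 mm")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def frame_times(self) -> np.ndarray:
        """End-of-exposure timestamps: -0.9 ... +6.0 s at defaults."""
        return self.t0_s + self.dt_s * (np.arange(self.n_frames) + 1)

    @property
    def geometry(self) -> ImageGeometry:
        return ImageGeometry(self.image_height_px, self.image_width_px, self.px_per_mm)


@dataclass(frozen=True)
class ResponseProfile:
    """Parameterized dR/R time course for one zone kind.

    * arm: positive lobe during movement/hold, then a negative peak.
    * hand: flat until the negative peak ramps up (~+2.5 s onward).
    * vessel: early negative transient during movement.

    The curve is normalized to a unit negative peak and scaled by the
    per-condition amplitude; it is identically zero before the Cue.
    """

    zone_kind: str  # arm | hand | vessel
    peak_time_s: float = 4.2
    neg_sigma_s: float = 0.9
    pos_time_s: float = 1.7
    pos_sigma_s: float = 0.5
    pos_frac: float = 0.5
    amplitude_by_condition: dict[str, float] = field(default_factory=dict)

    def shape(self, t: np.ndarray) -> np.ndarray:
        """Unit-amplitude curve (negative peak = -1), zero pre-Cue."""
        t = np.asarray(t, dtype=float)
        neg = -np.exp(-((t - self.peak_time_s) ** 2) / (2 * self.neg_sigma_s**2))
        if self.zone_kind == "arm":
            pos = self.pos_frac * np.exp(
                -((t - self.pos_time_s) ** 2) / (2 * self.pos_sigma_s**2)
            )
            out = neg + pos
        elif self.zone_kind == "hand":
            out = neg
        elif self.zone_kind == "vessel":
            out = neg
        else:
            raise ValueError(f"unknown zone_kind: {self.zone_kind!r}")
        # hemodynamics lag the Cue: no response at or before Cue onset
        return np.where(t <= 0, 0.0, out)


def response_timecourse(
    profile: ResponseProfile, t: float | np.ndarray, cond: str
) -> float | np.ndarray:
    """dR/R value(s) of ``profile`` at time(s) ``t`` for a condition.

    Deterministic; scaled by the profile's per-condition amplitude;
    zero for the withhold condition and for any t < 0 (pre-Cue).
    """
    amp = profile.amplitude_by_condition.get(cond, 0.0)
    out = amp * profile.shape(t)
    if np.isscalar(t):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Motor-map geometry of the simulated hemisphere (chamber mm coordinates;
# x grows rostrally from the central sulcus at x=0, y grows laterally).
# ---------------------------------------------------------------------------

_CS_X_MM = 0.0          # central sulcus line (x = const)
_M1_BORDER_X_MM = 4.5   # true M1/premotor border (3-5 mm from CS)
_HAND_CENTER = (2.8, 6.4)
_HAND_R = 1.8
_M1_FL_CENTER = (2.9, 6.4)
_M1_FL_R = 3.4
_PMD_FL_CENTER = (6.4, 5.6)
_PMD_FL_R = 2.2
_PMV_FL_CENTER = (5.8, 10.8)
_PMV_FL_R = 1.1
_PM_DIVIDE_Y_MM = 9.0   # medial(PMd)/lateral(PMv) divide
_TRUNK_Y_MM = 2.3
_FACE_Y_MM = 10.6


def _true_site_class(x: float, y: float) -> tuple[str, str]:
    """(area, class) ground truth for a site at chamber (x, y) mm."""
    in_m1 = x < _M1_BORDER_X_MM
    if in_m1:
        area = "M1"
        if np.hypot(x - _HAND_CENTER[0], y - _HAND_CENTER[1]) < _HAND_R:
            zone = "hand"
        elif np.hypot(x - _M1_FL_CENTER[0], y - _M1_FL_CENTER[1]) < _M1_FL_R:
            zone = "arm"
        elif y < (_TRUNK_Y_MM + 2.0):
            zone = "trunk"
        elif y > (_FACE_Y_MM - 1.2):
            zone = "face"
        else:
            zone = "trunk" if y < 6.4 else "face"
    else:
        if y >= _PM_DIVIDE_Y_MM:
            area = "PMv"
            zone = (
                "arm"
                if np.hypot(x - _PMV_FL_CENTER[0], y - _PMV_FL_CENTER[1]) < _PMV_FL_R
                else "face"
            )
        else:
            area = "PMd"
            if np.hypot(x - _PMD_FL_CENTER[0], y - _PMD_FL_CENTER[1]) < _PMD_FL_R:
                zone = "arm"
            else:
                zone = "trunk"
    return area, zone


def gen_motor_sites(cfg: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """ICMS site table on a jittered grid with nested somatotopy.

    Sites are laid on a 0.5-1.0 mm grid; M1 sites get thresholds below
    30 uA and premotor sites above; the hand class (digits/wrist) forms
    a contiguous core surrounded by arm sites (shoulder/elbow) in M1.
    A small fraction of forelimb sites evoke dual movements.

    Returns a long table: one row per (site, movement) with columns
    x_mm, y_mm, joint, movement, threshold_uA, depth_um, plus the truth
    columns true_area and true_class used only by recovery tests.
    """
    if cfg.site_spacing_mm <= 0:
        raise ValueError("grid spacing must be positive")
    rng = _sub_rng(cfg.seed if seed is None else seed, 101)
    fov_mm_x = cfg.image_width_px / cfg.px_per_mm
    fov_mm_y = cfg.image_height_px / cfg.px_per_mm
    step = cfg.site_spacing_mm
    xs = np.arange(0.8, fov_mm_x - 0.5, step)
    ys = np.arange(0.8, fov_mm_y - 0.5, step)
    rows = []
    flex_ext = ("flexion", "extension")
    for x0 in xs:
        for y0 in ys:
            x = x0 + rng.uniform(-0.08, 0.08)
            y = y0 + rng.uniform(-0.08, 0.08)
            area, zone = _true_site_class(x, y)
            if area == "M1":
                thr = rng.uniform(8.0, 28.0)
            else:
                thr = rng.uniform(35.0, 110.0)
            depth = float(rng.choice([500, 1000, 1500, 2000]))
            if zone == "hand":
                joints = [str(rng.choice(["digits", "wrist"]))]
            elif zone == "arm":
                joints = [str(rng.choice(["shoulder", "elbow"]))]
            else:
                joints = [zone]
            # occasional dual forelimb site inside the forelimb territory
            if zone == "arm" and rng.uniform() < 0.06:
                joints.append("digits")
            for j in joints:
                mv = str(rng.choice(flex_ext)) if j not in ("trunk", "face") else "twitch"
                rows.append(
                    {
                        "x_mm": round(float(x), 4), "y_mm": round(float(y), 4),
                        "joint": j, "movement": mv,
                        "threshold_uA": round(float(thr), 2),
                        "depth_um": depth,
                        "true_area": area, "true_class": zone,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class Patch:
    """One ground-truth activity patch."""

    name: str
    mask: np.ndarray
    zone: str              # arm | hand
    area: str              # M1 | PMd
    peak_time_s: float
    grasp_selective: bool  # silent in reach-only if True
    profile: ResponseProfile


@dataclass
class GroundTruth:
    """The simulator's hidden truth for recovery tests."""

    forelimb_mask: np.ndarray
    m1_forelimb_mask: np.ndarray
    pmd_forelimb_mask: np.ndarray
    patches: list[Patch]
    vessel_mask: np.ndarray
    base_image: np.ndarray
    sites: pd.DataFrame
    vessel_profile: ResponseProfile
    cfg: SimConfig

    @property
    def patch_union(self) -> np.ndarray:
        out = np.zeros_like(self.forelimb_mask)
        for p in self.patches:
            out |= p.mask
        return out

    @property
    def grasp_patch_union(self) -> np.ndarray:
        """Union of grasp-selective patches (the condition-difference locus)."""
        out = np.zeros_like(self.forelimb_mask)
        for p in self.patches:
            if p.grasp_selective:
                out |= p.mask
        return out

    def active_patch_union(self, cond: str) -> np.ndarray:
        """Union of the patches actually driven in one condition.

        Grasp-selective patches are silent in reach-only, so the
        recovery target differs between conditions.
        """
        out = np.zeros_like(self.forelimb_mask)
        for p in self.patches:
            if self.patch_amplitude(p, cond) > 0:
                out |= p.mask
        return out

    def patch_amplitude(self, patch: Patch, cond: str) -> float:
        return patch.profile.amplitude_by_condition.get(cond, 0.0)


def _disc_mask(shape: tuple[int, int], center_mm, r_mm, px_per_mm) -> np.ndarray:
    h, w = shape
    X, Y = np.meshgrid(np.arange(w), np.arange(h))
    cx, cy = center_mm
    return (X / px_per_mm - cx) ** 2 + (Y / px_per_mm - cy) ** 2 < r_mm**2


def _vessel_mask(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """A few meandering vessel tracks of ~3 px width."""
    h, w = cfg.image_height_px, cfg.image_width_px
    mask = np.zeros((h, w), dtype=bool)
    for x_frac, amp, period in ((0.08, 4.0, 0.9), (0.5, 6.0, 1.4), (0.93, 4.0, 1.1)):
        y = np.arange(h)
        x = x_frac * w + amp * np.sin(2 * np.pi * y / (period * h) + rng.uniform(0, 6))
        xi = np.clip(np.round(x).astype(int), 0, w - 1)
        for dxo in (-1, 0, 1):
            mask[y, np.clip(xi + dxo, 0, w - 1)] = True
    return mask


def _amplitudes(cfg: SimConfig, grasp_selective: bool) -> dict[str, float]:
    """Per-condition peak amplitudes for one patch.

    Shared (arm-zone) patches follow ``condition_amplitude``; grasp-
    selective patches follow ``grasp_amplitude``.  The condition
    differences are thereby confined to the grasp patches, and the
    grasp/shared amplitude ratio (1.0, 0.5, ~0.09 for precision, power,
    reach-only) makes precision x reach-only the most dissimilar
    movement pair in every frame's spatial pattern while keeping all
    patches active in all movement conditions.
    """
    if grasp_selective:
        return dict(cfg.grasp_amplitude)
    return dict(cfg.condition_amplitude)


def make_ground_truth(cfg: SimConfig, seed: int | None = None) -> GroundTruth:
    """Build the hidden truth: masks, patches, vessels, base image, sites.

    Patches cover ~30% of the forelimb representation and span the
    three peak-time classes (early ~2.0 s, intermediate ~3.5 s, late
    ~5.5 s).  Two patches (the M1 hand patch and one M1 arm patch) are
    grasp-selective: silent in reach-only, making precision x reach-only
    the most dissimilar movement pair by construction.
    """
    seed = cfg.seed if seed is None else seed
    rng = _sub_rng(seed, 1)
    shape = (cfg.image_height_px, cfg.image_width_px)
    ppm = cfg.px_per_mm

    sites = gen_motor_sites(cfg, seed)

    m1_fl = _disc_mask(shape, _M1_FL_CENTER, _M1_FL_R, ppm)
    X = np.meshgrid(np.arange(shape[1]), np.arange(shape[0]))[0] / ppm
    m1_fl &= (X >= 0.5) & (X < _M1_BORDER_X_MM)
    pmd_fl = _disc_mask(shape, _PMD_FL_CENTER, _PMD_FL_R, ppm) & (X >= _M1_BORDER_X_MM)
    forelimb = m1_fl | pmd_fl

    specs = [
        # name, center, r_mm, zone, area, peak, grasp-selective
        ("m1_hand", _HAND_CENTER, 1.0, "hand", "M1", 3.5, True),
        ("m1_arm_early", (1.35, 6.1), 0.6, "arm", "M1", 2.0, False),
        ("m1_arm_med", (2.2, 4.3), 0.85, "arm", "M1", 5.5, False),
        ("m1_arm_lat", (3.3, 8.5), 0.85, "arm", "M1", 3.5, True),
        ("pmd_arm", (6.3, 5.3), 1.0, "arm", "PMd", 5.5, False),
    ]
    patches = []
    for name, c, r, zone, area, peak, grasp in specs:
        mask = _disc_mask(shape, c, r, ppm) & forelimb
        profile = ResponseProfile(
            zone_kind=zone,
            peak_time_s=peak,
            neg_sigma_s=0.8 if zone == "hand" else 0.9,
            # an early negative peak overlapping the positive lobe would
            # drag the observable minimum later; the early class is a
            # pure dip so its true peak time is its nominal one
            pos_frac=0.0 if peak <= 2.5 else 0.5,
            amplitude_by_condition=_amplitudes(cfg, grasp),
        )
        patches.append(Patch(name, mask, zone, area, peak, grasp, profile))

    vessels = _vessel_mask(cfg, rng)
    vessels[np.logical_or.reduce([p.mask for p in patches])] = False

    # smooth texture: enough contrast for registration to lock onto,
    # without gradients steep enough for resampling error to rival dR/R
    texture = ndi.gaussian_filter(rng.normal(0, 1, shape), 5.0)
    texture /= max(texture.std(), 1e-12)
    base = cfg.base_counts * (1.0 + 0.05 * texture)
    base[vessels] *= 0.65  # vessels are dark under red illumination
    base = ndi.gaussian_filter(base, 0.7)  # optical blur softens vessel edges
    base = np.clip(base, 200.0, 4095.0)

    vessel_profile = ResponseProfile(
        zone_kind="vessel", peak_time_s=1.2, neg_sigma_s=0.4,
        amplitude_by_condition={
            c: (1.5e-3 if c != "withhold" else 0.0) for c in cfg.conditions
        },
    )
    return GroundTruth(
        forelimb_mask=forelimb, m1_forelimb_mask=m1_fl, pmd_forelimb_mask=pmd_fl,
        patches=patches, vessel_mask=vessels, base_image=base, sites=sites,
        vessel_profile=vessel_profile, cfg=cfg,
    )


def _response_stack(gt: GroundTruth, cond: str, times: np.ndarray) -> np.ndarray:
    """Noise-free fractional response, shape (n_frames, H, W)."""
    resp = np.zeros((len(times),) + gt.forelimb_mask.shape)
    for p in gt.patches:
        curve = response_timecourse(p.profile, times, cond)
        resp[:, p.mask] += curve[:, None]
    vcurve = response_timecourse(gt.vessel_profile, times, cond)
    resp[:, gt.vessel_mask] += vcurve[:, None]
    return resp


def gen_trial_stack(
    cond: str, gt: GroundTruth, cfg: SimConfig, seed: int
) -> TrialStack:
    """One trial's raw-count stack with jitter, artifact, and noise.

    counts = base x (1 + sum of patch/vessel responses) + Gaussian noise
    (SD = noise_sd x base, i.e. noise_sd in reflectance units), with a
    per-frame rigid jitter and a ~0.2-s motion-artifact shift (<= 3 px)
    at movement onset.  The applied shifts are recorded as ground truth.
    """
    if gt.forelimb_mask.shape != (cfg.image_height_px, cfg.image_width_px):
        raise ValueError("ground truth and config disagree on image size")
    rng = _sub_rng(seed, 2)
    times = cfg.frame_times
    resp = _response_stack(gt, cond, times)
    if (1.0 + resp).min() <= 0:
        raise ValueError("response amplitude drives counts negative")

    n = cfg.n_frames
    shifts = rng.uniform(-cfg.rigid_jitter_px, cfg.rigid_jitter_px, size=(n, 2))
    if cfg.rigid_jitter_px == 0:
        shifts[:] = 0.0
    onset = cfg.movement_onset_s.get(cond)
    if onset is not None and cfg.motion_artifact_px > 0:
        theta = rng.uniform(0, 2 * np.pi)
        vec = cfg.motion_artifact_px * np.array([np.cos(theta), np.sin(theta)])
        art = (times > onset) & (times <= onset + 0.2 + 1e-9)
        shifts[art] += vec

    frames = np.empty((n,) + gt.base_image.shape)
    for k in range(n):
        clean = gt.base_image * (1.0 + resp[k])
        dx, dy = shifts[k]
        if dx != 0.0 or dy != 0.0:
            clean = ndi.shift(clean, (dy, dx), order=3, mode="nearest")
        frames[k] = clean
    frames += rng.normal(0.0, 1.0, frames.shape) * (cfg.noise_sd * gt.base_image)
    return TrialStack(
        frames=frames, t0_s=cfg.t0_s, dt_s=cfg.dt_s, condition=cond,
        true_shifts_px=shifts,
    )


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

def _session_warp_field(
    shape: tuple[int, int], rng: np.random.Generator, max_disp_px: float
) -> callable:
    """Smooth low-order polynomial displacement field w(x, y) -> (dx, dy)."""
    h, w = shape
    coef = rng.uniform(-1, 1, size=(2, 6))  # 1, x, y, xy, x^2, y^2
    # normalize so the max displacement over the frame corners/centre is known
    probe = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1],
                      [w / 2, h / 2]])
    x = probe[:, 0] / w
    y = probe[:, 1] / h
    basis = np.stack([np.ones_like(x), x, y, x * y, x**2, y**2], axis=1)
    scale = np.abs(basis @ coef.T).max()
    amp = max_disp_px * rng.uniform(0.5, 1.0)

    def frozen(xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        x = xy[:, 0] / w
        y = xy[:, 1] / h
        basis = np.stack([np.ones_like(x), x, y, x * y, x**2, y**2], axis=1)
        return basis @ coef.T / scale * amp

    return frozen


@dataclass
class SessionRecord:
    """One simulated imaging session: trials plus registration truth.

    ``trials`` is populated only for materialized sessions; large
    sessions keep it empty and regenerate trials on demand from the
    manifest's per-trial seeds via :meth:`iter_trials`.
    """

    session_id: str
    trials: list[TrialStack]
    landmarks_session: np.ndarray
    landmarks_reference: np.ndarray
    warp_fn: object  # callable xy -> displacement, the hidden truth
    manifest: pd.DataFrame
    cfg: SimConfig | None = None

    def iter_trials(self, gt: "GroundTruth"):
        """Regenerate the session's trials one at a time (low memory)."""
        if self.trials:
            yield from self.trials
            return
        for row in self.manifest.itertuples():
            ts = gen_trial_stack(row.condition, gt, self.cfg, int(row.seed))
            ts.session_id = self.session_id
            ts.trial_id = row.trial_id
            yield ts


def gen_session(
    cfg: SimConfig,
    gt: GroundTruth,
    session_id: str = "S1",
    seed: int | None = None,
    max_warp_px: float = 6.0,
    n_landmarks: int = 40,
    apply_warp_to_frames: bool = False,
    materialize: bool = True,
) -> SessionRecord:
    """Simulate a full session: randomized blocks, warp, landmarks.

    Trials come in randomized blocks with exactly one successful trial
    per condition per block.  A session-specific smooth warp (max
    displacement ``max_warp_px`` <= 15) relates the session to the
    common reference; 25-60 control-point landmark pairs are exported
    (reference landmark = session landmark + warp(session landmark)).
    Warping every frame is optional (off by default) since cross-session
    alignment is exercised through the exported landmarks.
    """
    if not (25 <= n_landmarks <= 60):
        raise ValueError("n_landmarks must be within the study's 25-60 range")
    if max_warp_px > 15:
        raise ValueError("session warps are capped at 15 px")
    seed = cfg.seed if seed is None else seed
    sid_key = int(np.frombuffer(
        session_id.encode()[:8].ljust(8, b"\0"), dtype="<u8"
    )[0] % (2**31))
    rng = _sub_rng(seed, 3, sid_key)
    shape = (cfg.image_height_px, cfg.image_width_px)
    warp_fn = (
        (lambda xy: np.zeros((len(np.atleast_2d(xy)), 2)))
        if max_warp_px == 0
        else _session_warp_field(shape, rng, max_warp_px)
    )
    lm_s = np.column_stack(
        [
            rng.uniform(8, shape[1] - 9, n_landmarks),
            rng.uniform(8, shape[0] - 9, n_landmarks),
        ]
    )
    lm_r = lm_s + warp_fn(lm_s)

    rows = []
    trial_counter = 0
    for block in range(cfg.n_trials_per_condition):
        order = list(rng.permutation(list(cfg.conditions)))
        for cond in order:
            tseed = int(
                np.random.SeedSequence(
                    (seed, 7, sid_key, block, CONDITIONS.index(cond))
                ).generate_state(1)[0] % (2**31)
            )
            rows.append(
                {
                    "trial_id": f"{session_id}-t{trial_counter:04d}",
                    "session": session_id, "block": block,
                    "condition": cond, "cue_time_s": 0.0,
                    "movement_onset_s": cfg.movement_onset_s.get(cond, np.nan),
                    "movement_offset_s": cfg.movement_offset_s.get(cond, np.nan),
                    "seed": tseed,
                }
            )
            trial_counter += 1
    record = SessionRecord(
        session_id=session_id, trials=[],
        landmarks_session=lm_s, landmarks_reference=lm_r,
        warp_fn=warp_fn, manifest=pd.DataFrame(rows), cfg=cfg,
    )
    if materialize:
        trials = []
        for ts in record.iter_trials(gt):
            if apply_warp_to_frames and max_warp_px > 0:
                X, Y = np.meshgrid(
                    np.arange(shape[1], dtype=float),
                    np.arange(shape[0], dtype=float),
                )
                d = warp_fn(np.column_stack([X.ravel(), Y.ravel()]))
                cy = Y + d[:, 1].reshape(shape)
                cx = X + d[:, 0].reshape(shape)
                for k in range(ts.frames.shape[0]):
                    ts.frames[k] = ndi.map_coordinates(
                        ts.frames[k], np.stack([cy, cx]), order=1, mode="nearest"
                    )
            trials.append(ts)
        record.trials = trials
    return record


# ---------------------------------------------------------------------------
# Behavior: EMG and kinematics
# ---------------------------------------------------------------------------

#: Relative burst amplitude per condition (precision > power > reach-only).
_EMG_AMP = {"precision": 40.0, "power": 30.0, "reach-only": 15.0, "withhold": 0.0}
_KIN_PEAK_DEG = {"precision": 95.0, "power": 80.0, "reach-only": 55.0, "withhold": 30.0}


@dataclass
class EMGTrial:
    """One EMG trial: 2-kHz voltage trace plus event times."""

    samples: np.ndarray
    fs_hz: float
    muscle: str
    group: str  # arm | hand
    condition: str
    cue_s: float = 0.0
    withdrawal_end_s: float = 3.0
    true_burst_center_s: float | None = None
    has_artifact: bool = False


@dataclass
class KinTrial:
    """One kinematics trial: two LED triads at 480 Hz plus the truth angle."""

    markers: np.ndarray  # (n_samples, 6, 3); triad 0 = proximal, 1 = distal
    fs_hz: float
    joint: str
    dof: str  # flexion/extension | pronation/supination
    condition: str
    cue_s: float = 0.0
    withdrawal_end_s: float = 3.0
    true_angle_deg: np.ndarray | None = None
    dropout_fraction: float = 0.0


def gen_emg_trial(
    cond: str,
    muscle_group: str,
    cfg: SimConfig,
    seed: int,
    fs_hz: float = 2000.0,
    duration_s: float = 7.0,
    t0_s: float = -1.0,
    artifact: bool = False,
    muscle: str | None = None,
) -> EMGTrial:
    """EMG = burst envelope x white-noise carrier during the movement epoch.

    The burst amplitude is ordered precision > power > reach-only and
    slightly favours the muscle group engaged by the condition; the
    withhold condition is noise floor only.  An optional 8-Hz artifact
    injects low-frequency power above the 7-uV^2 screen threshold.
    """
    if muscle_group not in ("arm", "hand"):
        raise ValueError("muscle_group must be 'arm' or 'hand'")
    rng = _sub_rng(seed, 11)
    n = int(round(duration_s * fs_hz))
    t = t0_s + np.arange(n) / fs_hz
    onset = cfg.movement_onset_s.get(cond)
    offset = cfg.movement_offset_s.get(cond)
    floor = 2.0  # uV noise floor
    env = np.full(n, floor)
    center = None
    if onset is not None and _EMG_AMP[cond] > 0:
        center = 0.5 * (onset + offset)
        width = max(0.18, (offset - onset) / 4)
        a = _EMG_AMP[cond]
        if cond == "reach-only" and muscle_group == "hand":
            a *= 0.4  # little hand-muscle drive without a grasp
        env = floor + a * np.exp(-((t - center) ** 2) / (2 * width**2))
    samples = env * rng.normal(0.0, 1.0, n)
    if artifact:
        samples = samples + 6.0 * np.sin(2 * np.pi * 8.0 * t)
    default_muscle = {"arm": "biceps", "hand": "FCR"}[muscle_group]
    return EMGTrial(
        samples=samples, fs_hz=fs_hz,
        muscle=muscle or default_muscle, group=muscle_group, condition=cond,
        withdrawal_end_s=(offset + 0.8) if offset is not None else 3.0,
        true_burst_center_s=center, has_artifact=artifact,
    )


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def programmed_angle_curve(
    cond: str, t: np.ndarray, cfg: SimConfig, baseline_deg: float = 30.0
) -> np.ndarray:
    """Smooth joint-angle sweep peaking mid-movement, per condition."""
    onset = cfg.movement_onset_s.get(cond)
    if onset is None:
        return np.full_like(t, baseline_deg)
    offset = cfg.movement_offset_s[cond]
    center = 0.5 * (onset + offset)
    width = max(0.25, (offset - onset) / 3)
    peak = _KIN_PEAK_DEG[cond]
    return baseline_deg + (peak - baseline_deg) * np.exp(
        -((t - center) ** 2) / (2 * width**2)
    )


def gen_kin_trial(
    cond: str,
    joint: str,
    cfg: SimConfig,
    seed: int,
    dof: str = "flexion/extension",
    fs_hz: float = 480.0,
    duration_s: float = 7.0,
    t0_s: float = -1.0,
    dropout_fraction: float = 0.0,
    angle_curve_deg: np.ndarray | None = None,
) -> KinTrial:
    """LED-triad trajectories realizing a known joint-angle time course.

    The proximal triad is fixed; the distal triad is rotated about the
    z axis by the programmed angle, so the vector angle (and the
    plane-normal angle) recomputed from the markers equals the
    programmed curve exactly.  Optional dropout marks runs of samples
    as missing (NaN) on one distal LED.
    """
    rng = _sub_rng(seed, 12)
    n = int(round(duration_s * fs_hz))
    t = t0_s + np.arange(n) / fs_hz
    angle = (
        np.asarray(angle_curve_deg, dtype=float)
        if angle_curve_deg is not None
        else programmed_angle_curve(cond, t, cfg)
    )
    if angle.shape != t.shape:
        raise ValueError("angle curve length must match the sample count")
    proximal = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0], [0.0, 80.0, 0.0]])
    distal0 = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0], [0.0, 80.0, 0.0]])
    markers = np.empty((n, 6, 3))
    markers[:, :3] = proximal
    # flexion-type DOFs rotate the distal segment vector (about z);
    # pronation rotates the distal plane about the segment axis (x)
    axis = (
        np.array([1.0, 0.0, 0.0])
        if dof == "pronation/supination"
        else np.array([0.0, 0.0, 1.0])
    )
    for i, a in enumerate(np.deg2rad(angle)):
        R = _rotation(axis, a)
        markers[i, 3:] = distal0 @ R.T
    if dropout_fraction > 0:
        n_drop = int(round(dropout_fraction * n))
        start = int(rng.integers(0, max(1, n - n_drop)))
        markers[start : start + n_drop, 4, :] = np.nan
    offset = cfg.movement_offset_s.get(cond)
    return KinTrial(
        markers=markers, fs_hz=fs_hz, joint=joint, dof=dof, condition=cond,
        withdrawal_end_s=(offset + 0.8) if offset is not None else 3.0,
        true_angle_deg=angle,
        dropout_fraction=float(dropout_fraction),
    )


# ---------------------------------------------------------------------------
# Stack I/O (TIFF per trial + CSV manifest)
# ---------------------------------------------------------------------------

def write_trial_tiff(path, stack: TrialStack) -> None:
    import tifffile

    tifffile.imwrite(path, stack.frames.astype(np.float32))


def read_trial_tiff(path, **meta) -> TrialStack:
    import tifffile

    return TrialStack(frames=tifffile.imread(path).astype(float), **meta)
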