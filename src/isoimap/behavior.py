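"""Forelimb-use quantification: EMG envelopes, joint angles, AUC.

EMG trials (2 kHz) are screened for low-frequency artifact (discrete-
Fourier power > 7 uV^2 in the 1-14 Hz band excludes the trial),
rectified, and smoothed with a zero-phase 100-ms sliding window.
Joint angles come from LED marker triads (480 Hz): flexion/extension-
type degrees of freedom are the angle between the two segment vectors,
pronation/supination the angle between the segment plane normals;
trials missing marker data for more than 2% of their duration are
dropped.  Each trace is reduced to its trapezoidal area under the
curve (AUC) from Cue to the end of forelimb withdrawal, standardized
within session (z-score across all of that session's trials, pooled
across conditions), summarized per condition by the median across
trials, and aggregated over signals by a trial-count-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .simulate import EMGTrial, KinTrial

__all__ = [
    "AUCRecord",
    "band_power",
    "emg_artifact_screen",
    "emg_envelope",
    "joint_angle",
    "kin_dropout_screen",
    "auc",
    "standardize_auc",
    "group_summary",
]

ARM_MUSCLES = frozenset({"deltoid", "biceps", "triceps"})
HAND_MUSCLES = frozenset({"ECRB", "FCR", "ED4-5", "FDS"})


def band_power(
    samples: np.ndarray, fs_hz: float, band_hz: tuple[float, float] = (1.0, 14.0)
) -> float:
    """One-sided periodogram power summed over the band (signal units^2).

    Rectangular window; bins whose centre frequency falls in
    [band_hz[0], band_hz[1]] are summed.  Normalized so a pure
    sinusoid of amplitude A on an exact bin contributes A^2/2.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    power = 2.0 * np.abs(spec) ** 2 / n**2
    power[0] /= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    return float(power[sel].sum())


def emg_artifact_screen(
    trial: EMGTrial,
    band_hz: tuple[float, float] = (1.0, 14.0),
    limit_uv2: float = 7.0,
    fs_hz: float = 2000.0,
) -> tuple[bool, float]:
    """Keep/drop decision from low-frequency spectral power.

    Trials with power above ``limit_uv2`` (7 uV^2) in the 1-14 Hz band
    are presumed to carry movement/cable artifact and are dropped.
    Returns (keep, band power).
    """
    if trial.fs_hz != fs_hz:
        raise ValueError(f"expected {fs_hz} Hz sampling, got {trial.fs_hz}")
    if len(trial.samples) < fs_hz:
        raise ValueError("need >=1 s of samples")
    p = band_power(trial.samples, trial.fs_hz, band_hz)
    return p <= limit_uv2, p


def emg_envelope(trial: EMGTrial, window_ms: float = 100.0) -> np.ndarray:
    """Rectify and smooth with a zero-phase 100-ms sliding window.

    The centred moving average is run forward then backward (the
    zero-phase contract of a filtfilt-style smoother); the window is
    rounded to an odd sample count (201 samples at 2 kHz).  Length is
    preserved.
    """
    rect = np.abs(np.asarray(trial.samples, dtype=float))
    w = int(round(window_ms * 1e-3 * trial.fs_hz)) | 1
    smoothed = ndi.uniform_filter1d(rect, w, mode="nearest")
    return ndi.uniform_filter1d(smoothed, w, mode="nearest")


def _angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.einsum("...i,...i->...", u, v) / (nu * nv)
    c = np.clip(c, -1.0, 1.0)
    out = np.degrees(np.arccos(c))
    out[(nu == 0) | (nv == 0)] = np.nan
    return out


def joint_angle(trial: KinTrial) -> np.ndarray:
    """Angle series (degrees, [0, 180]) from the two LED triads.

    Flexion/extension-type DOFs use the angle between the proximal and
    distal segment vectors (LED0->LED1 of each triad);
    pronation/supination uses the angle between the triad plane
    normals.  Samples with missing LEDs or degenerate (collinear)
    triads are NaN.
    """
    m = np.asarray(trial.markers, dtype=float)
    prox, dist = m[:, :3], m[:, 3:]
    if trial.dof == "pronation/supination":
        u = np.cross(prox[:, 1] - prox[:, 0], prox[:, 2] - prox[:, 0])
        v = np.cross(dist[:, 1] - dist[:, 0], dist[:, 2] - dist[:, 0])
    else:
        u = prox[:, 1] - prox[:, 0]
        v = dist[:, 1] - dist[:, 0]
    return _angle_between(u, v)


def kin_dropout_screen(trial: KinTrial, limit: float = 0.02) -> tuple[bool, float]:
    """Drop the trial if any required LED is missing for >2% of samples.

    Returns (keep, worst missing fraction).
    """
    m = np.asarray(trial.markers, dtype=float)
    missing = np.isnan(m).any(axis=2)         # (n_samples, 6)
    frac = missing.mean(axis=0)
    worst = float(frac.max())
    return worst <= limit + 1e-12, worst


def auc(
    trace: np.ndarray,
    fs_hz: float,
    t0_s: float,
    t_start_s: float,
    t_end_s: float,
) -> float:
    """Trapezoidal area under the trace over [t_start, t_end].

    The window runs from the Cue to the end of forelimb withdrawal;
    both ends must lie inside the trace.
    """
    if t_start_s >= t_end_s:
        raise ValueError("t_start must precede t_end")
    t = t0_s + np.arange(len(trace)) / fs_hz
    if t_start_s < t[0] - 1e-9 or t_end_s > t[-1] + 1e-9:
        raise ValueError(
            f"window [{t_start_s}, {t_end_s}] outside trace span [{t[0]}, {t[-1]}]"
        )
    sel = (t >= t_start_s - 1e-9) & (t <= t_end_s + 1e-9)
    return float(np.trapezoid(np.asarray(trace, float)[sel], t[sel]))


@dataclass
class AUCRecord:
    """Per-trial AUC for one signal (muscle or joint DOF)."""

    trial_id: str
    session: str
    signal: str
    condition: str
    auc_raw: float
    auc_z: float | None = None
    n_trials_weight: int = 1


def standardize_auc(records: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score AUC within (session x signal) across all trials.

    Standardization pools that session's trials across conditions, so
    condition differences survive while session gain/offset variation
    is removed.  ``ddof=1`` (sample SD) by default; ``ddof=0`` gives
    the population-SD variant.
    """
    required = {"session", "signal", "condition", "auc_raw"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    out = records.copy()
    zs = np.empty(len(out))
    for (sess, sig), grp in out.groupby(["session", "signal"], sort=False):
        v = grp["auc_raw"].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"session {sess!r} signal {sig!r}: <2 trials")
        sd = v.std(ddof=ddof)
        if sd == 0:
            raise ValueError(
                f"session {sess!r} signal {sig!r}: zero within-session variance"
            )
        zs[grp.index.to_numpy()] = (v - v.mean()) / sd
    out["auc_z"] = zs
    return out


def group_summary(
    records: pd.DataFrame,
    signal_groups: dict[str, str] | None = None,
    value: str = "auc_z",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition summaries: median per signal, trial-weighted means.

    The per-condition average for one signal is the median of its
    trials; signals are then aggregated into groups (e.g. arm/hand
    muscles) — and into a combined row — by a mean weighted by the
    number of trials behind each signal.
    """
    rows = []
    for (cond, sig), grp in records.groupby(["condition", "signal"], sort=True):
        rows.append(
            {
                "condition": cond, "signal": sig,
                "group": (signal_groups or {}).get(sig, "all"),
                "median": float(grp[value].median()),
                "n_trials": int(len(grp)),
            }
        )
    per_signal = pd.DataFrame(rows)
    out = []
    for cond, grp in per_signal.groupby("condition", sort=True):
        for gname, gg in grp.groupby("group", sort=True):
            w = gg["n_trials"].to_numpy(float)
            out.append(
                {
                    "condition": cond, "group": gname,
                    "weighted_mean": float(np.average(gg["median"], weights=w)),
                    "n_trials": int(w.sum()),
                }
            )
        w = grp["n_trials"].to_numpy(float)
        out.append(
            {
                "condition": cond, "group": "combined",
                "weighted_mean": float(np.average(grp["median"], weights=w)),
                "n_trials": int(w.sum()),
            }
        )
    return pd.DataFrame(out), per_signal
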