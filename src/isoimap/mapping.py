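"""Thresholded activity maps and time-course analyses.

Every trial contributes one baseline frame (mean of the 10 pre-Cue
frames) and one movement frame (mean over a post-movement window — the
full 39-frame +2.2...+6.0 s window or a 5-frame window near the
negative peak).  A pixelwise two-sample t-test (pooled variance,
Welch optional) compares movement against baseline frames across
trials; tailed p-values below alpha (1e-4, or Bonferroni-corrected by
the number of forelimb pixels) flag significant pixels, and connected
components of 10 or fewer pixels are removed as noise.  Map sizes are
expressed as the percentage of the forelimb representation they
overlap.  ROI time courses, per-frame map-size series, and per-pixel
peak-time (maximal darkening) maps summarize the temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage import measure

from .motormap import ForelimbMask

__all__ = [
    "FrameWindow",
    "ThresholdedMap",
    "PixelTestResult",
    "ROISpec",
    "PeakTimeMap",
    "window_average",
    "pixelwise_ttest_map",
    "bonferroni_alpha",
    "denoise_components",
    "threshold_map",
    "overlap_percent",
    "map_size_timecourse",
    "circle_roi",
    "roi_timecourse",
    "peak_time_map",
]


@dataclass(frozen=True)
class FrameWindow:
    """A frame-selection window in seconds from Cue (inclusive ends)."""

    label: str
    start_s: float
    end_s: float

    @classmethod
    def baseline(cls) -> "FrameWindow":
        """The 10 pre-Cue frames (-1.0 to 0 s)."""
        return cls("baseline", -1.0, 0.0)

    @classmethod
    def movement39(cls) -> "FrameWindow":
        """All 39 frames captured from end of movement, +2.2 to +6.0 s."""
        return cls("movement39", 2.2, 6.0)

    @classmethod
    def movement5(cls, end_s: float = 4.4) -> "FrameWindow":
        """5 consecutive frames near the negative peak, ending at end_s."""
        return cls("movement5", end_s - 0.4, end_s)

    def select(self, times: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(
            (times >= self.start_s - 1e-9) & (times <= self.end_s + 1e-9)
        )
        if len(idx) == 0:
            raise ValueError(
                f"window {self.label} [{self.start_s}, {self.end_s}] selects no frames"
            )
        return idx


def window_average(frames: np.ndarray, times: np.ndarray, window: FrameWindow) -> np.ndarray:
    """Per-pixel mean over the window's frames of one trial stack.

    Frame timestamps mark the end of each exposure, so a window's
    nominal start may precede the first stamp by up to one frame
    period (e.g. the -1.0 to 0 s baseline selects stamps -0.9 ... 0).
    """
    dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
    if times[0] - dt - 1e-9 > window.start_s or times[-1] + 1e-9 < window.end_s:
        raise ValueError(
            f"window {window.label} [{window.start_s}, {window.end_s}] outside "
            f"acquisition span [{times[0] - dt}, {times[-1]}]"
        )
    return frames[window.select(times)].mean(axis=0)


@dataclass
class PixelTestResult:
    """Per-pixel t statistics and tailed p-values."""

    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray           # tailed p < alpha, before denoising
    tail: str
    alpha: float
    df: int
    n_undefined: int           # zero-variance pixels forced non-significant
    undefined_px: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))


def pixelwise_ttest_map(
    movement_frames: np.ndarray,
    baseline_frames: np.ndarray,
    tail: str = "left",
    alpha: float = 1e-4,
    welch: bool = False,
) -> PixelTestResult:
    """Pixel-by-pixel two-sample t-test of movement vs baseline frames.

    ``movement_frames`` and ``baseline_frames`` are (n_trials, H, W)
    per-trial window averages.  The left tail flags pixels that
    *darkened* significantly (movement < baseline); the right tail
    flags brightening.  Pooled-variance by default (the study's
    parametric checks justify it); ``welch=True`` drops the equal-
    variance assumption.  Pixels with zero variance in both groups have
    no defined p and are set non-significant and logged.
    """
    if tail not in ("left", "right"):
        raise ValueError("tail must be 'left' or 'right'")
    a = np.asarray(movement_frames, dtype=float)
    b = np.asarray(baseline_frames, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >=2 trials per group")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if welch:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df_px = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        df = float(np.nanmedian(df_px))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = na + nb - 2
    undefined = se2 <= 0
    se = np.sqrt(np.where(undefined, 1.0, se2))
    t = (ma - mb) / se
    t[undefined] = 0.0
    if welch:
        p = stats.t.cdf(t, df_px) if tail == "left" else stats.t.sf(t, df_px)
    else:
        p = stats.t.cdf(t, df) if tail == "left" else stats.t.sf(t, df)
    p = np.where(undefined, 1.0, p)
    mask = p < alpha
    return PixelTestResult(
        t=t, p=p, mask=mask, tail=tail, alpha=alpha, df=int(round(df)),
        n_undefined=int(undefined.sum()),
        undefined_px=np.argwhere(undefined),
    )


def bonferroni_alpha(base_alpha: float, n_forelimb_pixels: int) -> float:
    """Corrected alpha = base_alpha / number of (non-vessel) forelimb pixels."""
    if n_forelimb_pixels <= 0:
        raise ValueError("pixel count must be positive")
    return base_alpha / n_forelimb_pixels


def denoise_components(
    mask: np.ndarray, min_size: int = 11, connectivity: int = 8
) -> np.ndarray:
    """Drop connected components of fewer than ``min_size`` pixels.

    The default keeps groups with >10 connected significant pixels
    (8-connected; 4-connected selectable).  Never adds pixels.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(mask.astype(bool), connectivity=1 if connectivity == 4 else 2)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


@dataclass
class ThresholdedMap:
    """Binary map of significant reflectance change, with provenance."""

    mask: np.ndarray
    tail: str
    alpha: float
    bonferroni: bool
    min_component_px: int
    window_label: str
    condition: str = ""
    n_trials: int = 0
    test: PixelTestResult | None = None


def threshold_map(
    movement_frames: np.ndarray,
    baseline_frames: np.ndarray,
    tail: str = "left",
    alpha: float = 1e-4,
    bonferroni_n: int | None = None,
    min_component_px: int = 11,
    connectivity: int = 8,
    vessel_mask: np.ndarray | None = None,
    window_label: str = "",
    condition: str = "",
    welch: bool = False,
) -> ThresholdedMap:
    """Full thresholding: t-test, optional Bonferroni, vessel removal, denoise."""
    eff_alpha = alpha if bonferroni_n is None else bonferroni_alpha(alpha, bonferroni_n)
    res = pixelwise_ttest_map(
        movement_frames, baseline_frames, tail=tail, alpha=eff_alpha, welch=welch
    )
    mask = res.mask.copy()
    if vessel_mask is not None:
        mask &= ~vessel_mask
    mask = denoise_components(mask, min_size=min_component_px, connectivity=connectivity)
    return ThresholdedMap(
        mask=mask, tail=tail, alpha=eff_alpha, bonferroni=bonferroni_n is not None,
        min_component_px=min_component_px, window_label=window_label,
        condition=condition, n_trials=movement_frames.shape[0], test=res,
    )


def overlap_percent(map_mask: np.ndarray, forelimb: ForelimbMask) -> float:
    """Map size as % of the (vessel-excluded) forelimb representation."""
    countable = forelimb.countable()
    denom = int(countable.sum())
    if denom == 0:
        raise ValueError("forelimb mask is empty")
    num = int((map_mask & countable).sum())
    return 100.0 * num / denom


def map_size_timecourse(
    trial_stacks: np.ndarray,
    baseline_frames: np.ndarray,
    forelimb: ForelimbMask,
    tail: str = "left",
    alpha: float = 1e-4,
    min_component_px: int = 11,
    connectivity: int = 8,
    vessel_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Thresholded-map overlap % generated at every time point (0.1 s).

    ``trial_stacks`` is (n_trials, n_frames, H, W) of dR/R; each frame
    index is t-tested against the per-trial baseline frames, denoised,
    and its forelimb overlap recorded, giving one value per frame.
    """
    n_frames = trial_stacks.shape[1]
    out = np.empty(n_frames)
    for k in range(n_frames):
        res = pixelwise_ttest_map(
            trial_stacks[:, k], baseline_frames, tail=tail, alpha=alpha
        )
        mask = res.mask
        if vessel_mask is not None:
            mask = mask & ~vessel_mask
        mask = denoise_components(mask, min_size=min_component_px,
                                  connectivity=connectivity)
        out[k] = overlap_percent(mask, forelimb)
    return out


@dataclass
class ROISpec:
    """Region of interest: a small circle (0.4 mm) or the forelimb outline."""

    kind: str  # circle | forelimb
    mask: np.ndarray
    center_px: tuple[float, float] | None = None
    radius_px: float = 20.0


def circle_roi(
    center_px: tuple[float, float], radius_px: float, shape: tuple[int, int]
) -> ROISpec:
    """Circular ROI mask (pixel centres within the radius)."""
    cy, cx = center_px
    Y, X = np.ogrid[: shape[0], : shape[1]]
    mask = (X - cx) ** 2 + (Y - cy) ** 2 <= radius_px**2
    return ROISpec(kind="circle", mask=mask, center_px=center_px, radius_px=radius_px)


def roi_timecourse(
    time_series: np.ndarray, roi: ROISpec, vessel_mask: np.ndarray | None = None
) -> np.ndarray:
    """Mean dR/R per frame over the ROI's non-vessel pixels.

    ``time_series`` is the trial-averaged stack (n_frames, H, W).
    """
    mask = roi.mask if vessel_mask is None else roi.mask & ~vessel_mask
    if not mask.any():
        raise ValueError("ROI is empty after vessel exclusion")
    return time_series[:, mask].mean(axis=1)


@dataclass
class PeakTimeMap:
    """Per-pixel time of maximal negative reflectance."""

    time_s: np.ndarray
    valid: np.ndarray
    window: FrameWindow


def peak_time_map(
    time_series: np.ndarray,
    times: np.ndarray,
    search_window: FrameWindow | None = None,
    smooth_frames: int = 0,
) -> PeakTimeMap:
    """Time (s from Cue) at which each pixel reaches maximal darkening.

    The per-pixel argmin of the trial-averaged dR/R within the search
    window (default: all post-Cue frames); ties break to the earliest
    time; pixels whose time course never goes negative in the window
    are marked invalid.  Optional boxcar temporal smoothing (off by
    default) can be applied before the argmin.
    """
    if search_window is None:
        search_window = FrameWindow("post-cue", 0.0, float(times[-1]))
    idx = search_window.select(times)
    sub = time_series[idx]
    if smooth_frames > 1:
        sub = ndi.uniform_filter1d(sub, smooth_frames, axis=0, mode="nearest")
    amin = np.argmin(sub, axis=0)  # first occurrence = earliest time
    tmin = np.take_along_axis(sub, amin[None], axis=0)[0]
    valid = tmin < 0
    time_s = times[idx][amin].astype(float)
    time_s[~valid] = np.nan
    return PeakTimeMap(time_s=time_s, valid=valid, window=search_window)
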