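"""Between-condition comparisons of cortical activity.

Two complementary comparisons: (1) paired t-test maps flagging pixels
darker in one movement condition than another (threshold relaxed to
p < 0.001, then the same >10-pixel component denoising); (2) zero-lag
cross-correlation of trial-averaged frames at matched time points,
restricted to the forelimb representation, focusing on the 39
post-movement frames.  Pooling the coefficients across subjects gives
78 points per movement pair (39 frames x 2 subjects) and 234 for the
three movement-vs-withhold comparisons; a one-way ANOVA with
Bonferroni-corrected follow-up t-tests compares the pair distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .mapping import FrameWindow, ThresholdedMap, threshold_map
from .motormap import ForelimbMask

__all__ = [
    "ConditionPairResult",
    "AnovaResult",
    "paired_condition_map",
    "frame_correlation",
    "condition_pair_series",
    "anova_posthoc",
]


def paired_condition_map(
    frames_a: np.ndarray,
    frames_b: np.ndarray,
    alpha: float = 1e-3,
    min_component_px: int = 11,
    connectivity: int = 8,
    vessel_mask: np.ndarray | None = None,
) -> ThresholdedMap:
    """Pixels significantly darker in condition A than condition B.

    Pixelwise two-sample t-test on per-trial movement frames, left tail
    (A darker), denoised with the >10-connected-pixel rule.
    """
    return threshold_map(
        frames_a, frames_b, tail="left", alpha=alpha,
        min_component_px=min_component_px, connectivity=connectivity,
        vessel_mask=vessel_mask, window_label="paired",
    )


def frame_correlation(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    mask: ForelimbMask | np.ndarray,
    centered: bool = True,
) -> float:
    """Zero-lag correlation of two frames over the forelimb pixels.

    Frames are flattened over the mask's non-vessel pixels and
    correlated: Pearson (centered, the default) or an uncentered
    cosine-similarity variant.  Zero variance in either frame leaves r
    undefined (NaN).
    """
    m = mask.countable() if isinstance(mask, ForelimbMask) else np.asarray(mask, bool)
    if int(m.sum()) < 3:
        raise ValueError("need >=3 mask pixels")
    a = frame_a[m].astype(float)
    b = frame_b[m].astype(float)
    if centered:
        a = a - a.mean()
        b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass
class ConditionPairResult:
    """Correlation series (and optional contrast mask) for one pair."""

    pair: tuple[str, str]
    r: np.ndarray                       # one r per matched post-movement frame
    contrast: ThresholdedMap | None = None


def condition_pair_series(
    series_a: np.ndarray,
    series_b: np.ndarray,
    times: np.ndarray,
    mask: ForelimbMask | np.ndarray,
    window: FrameWindow | None = None,
    centered: bool = True,
    pair: tuple[str, str] = ("A", "B"),
) -> ConditionPairResult:
    """r_1..r_39: per-frame zero-lag correlations of two average series.

    ``series_a``/``series_b`` are time-aligned trial-averaged stacks
    (n_frames, H, W); only the post-movement frames (default +2.2 to
    +6.0 s, n = 39) are correlated.
    """
    if series_a.shape != series_b.shape:
        raise ValueError("series must be time-aligned with equal shapes")
    window = window or FrameWindow.movement39()
    idx = window.select(times)
    r = np.array(
        [frame_correlation(series_a[k], series_b[k], mask, centered) for k in idx]
    )
    return ConditionPairResult(pair=pair, r=r)


@dataclass
class AnovaResult:
    """One-way ANOVA with Bonferroni-corrected pairwise post hocs."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    posthoc: dict[tuple[str, str], float]    # corrected p-values
    correction_factor: int
    variance_check_p: float                  # Bartlett
    skewness: dict[str, float]
    kurtosis: dict[str, float]               # excess (Fisher)

    def significant_pairs(self, alpha: float = 0.01) -> list[tuple[str, str]]:
        return [pair for pair, p in self.posthoc.items() if p < alpha]


def anova_posthoc(groups: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA across groups plus corrected follow-up t-tests.

    Parametric screens (variance comparability via Bartlett, skewness
    and excess kurtosis nominally within [-1, +1]) are evaluated and
    reported, not enforced.  Post hoc pairwise t-tests are Bonferroni-
    corrected by the number of comparisons C(k, 2).
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    names = list(arrays)
    values = [arrays[k] for k in names]
    F, p = stats.f_oneway(*values)
    n_total = sum(len(v) for v in values)
    pairs = list(combinations(names, 2))
    posthoc = {}
    for x, y in pairs:
        _, pp = stats.ttest_ind(arrays[x], arrays[y])
        posthoc[(x, y)] = min(1.0, float(pp) * len(pairs))
    try:
        _, var_p = stats.bartlett(*values)
    except ValueError:
        var_p = float("nan")
    return AnovaResult(
        F=float(F), df_between=len(names) - 1, df_within=n_total - len(names),
        p=float(p),
        group_means={k: float(v.mean()) for k, v in arrays.items()},
        posthoc=posthoc, correction_factor=len(pairs),
        variance_check_p=float(var_p),
        skewness={k: float(stats.skew(v)) for k, v in arrays.items()},
        kurtosis={k: float(stats.kurtosis(v)) for k, v in arrays.items()},
    )
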