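"""Thresholded maps: t-tests, denoising, overlap, time courses."""

import numpy as np
import pytest
from scipy import stats

from isoimap import mapping as mp
from isoimap.motormap import ForelimbMask, ImageGeometry


def _times():
    return -1.0 + 0.1 * (np.arange(70) + 1)


def _forelimb(mask: np.ndarray, vessel=None) -> ForelimbMask:
    geom = ImageGeometry(*mask.shape, 10.0)
    countable = mask if vessel is None else mask & ~vessel
    return ForelimbMask(
        per_area={"M1": mask}, combined=mask, geometry=geom,
        n_countable=int(countable.sum()), vessel_mask=vessel,
    )


# ---------------------------------------------------------------------------
# frame windows and averaging
# ---------------------------------------------------------------------------

def test_window_frame_counts():
    t = _times()
    assert len(mp.FrameWindow.baseline().select(t)) == 10
    assert len(mp.FrameWindow.movement39().select(t)) == 39
    assert len(mp.FrameWindow.movement5().select(t)) == 5


def test_window_average_constant_and_out_of_span():
    frames = np.full((70, 4, 4), 2.5)
    out = mp.window_average(frames, _times(), mp.FrameWindow.movement39())
    np.testing.assert_array_equal(out, 2.5)
    with pytest.raises(ValueError, match="outside"):
        mp.window_average(frames, _times(), mp.FrameWindow("bad", 5.0, 8.0))


def test_window_average_of_movement39_matches_profile_integral():
    t = _times()
    curve = -np.exp(-((t - 4.0) ** 2) / 2.0)
    frames = np.broadcast_to(curve[:, None, None], (70, 3, 3)).copy()
    out = mp.window_average(frames, t, mp.FrameWindow.movement39())
    expected = curve[(t >= 2.2 - 1e-9) & (t <= 6.0 + 1e-9)].mean()
    np.testing.assert_allclose(out, expected)


# ---------------------------------------------------------------------------
# pixelwise t-test
# ---------------------------------------------------------------------------

def test_t_statistic_matches_scalar_oracle(rng):
    mov = rng.normal(0.0, 1.0, (14, 8, 8))
    base = rng.normal(0.2, 1.3, (11, 8, 8))
    res = mp.pixelwise_ttest_map(mov, base, tail="left", alpha=1e-4)
    for _ in range(10):
        iy, ix = rng.integers(0, 8, 2)
        t_ref, p_ref = stats.ttest_ind(
            mov[:, iy, ix], base[:, iy, ix], alternative="less"
        )
        assert abs(res.t[iy, ix] - t_ref) <= 1e-10 * max(1, abs(t_ref))
        assert abs(res.p[iy, ix] - p_ref) <= 1e-10


def test_extreme_shift_all_significant(rng):
    base = rng.normal(0.0, 1.0, (10, 6, 6))
    mov = rng.normal(-10.0, 1.0, (10, 6, 6))
    res = mp.pixelwise_ttest_map(mov, base, tail="left", alpha=1e-4)
    assert res.mask.all()


def test_zero_variance_pixel_logged_nonsignificant():
    mov = np.zeros((5, 3, 3))
    base = np.zeros((5, 3, 3))
    base[:, 0, 0] = [0.1, -0.1, 0.2, -0.2, 0.0]
    res = mp.pixelwise_ttest_map(mov, base)
    assert not res.mask[1, 1]
    assert res.n_undefined == 8
    assert res.p[1, 1] == 1.0


def test_welch_variant_runs(rng):
    mov = rng.normal(-1, 2.0, (20, 4, 4))
    base = rng.normal(0, 0.5, (20, 4, 4))
    res = mp.pixelwise_ttest_map(mov, base, welch=True, alpha=0.01)
    assert res.mask.any()
    assert ((res.p >= 0) & (res.p <= 1)).all()


def test_needs_two_trials():
    with pytest.raises(ValueError, match=">=2"):
        mp.pixelwise_ttest_map(np.zeros((1, 3, 3)), np.zeros((5, 3, 3)))


def test_null_calibration_small():
    """On signal-free data the significant fraction tracks alpha."""
    g = np.random.default_rng(77)
    mov = g.normal(0, 1, (120, 48, 48))
    base = g.normal(0, 1, (120, 48, 48))
    alpha = 1e-3
    res = mp.pixelwise_ttest_map(mov, base, tail="left", alpha=alpha)
    n = res.mask.size
    frac = res.mask.mean()
    band = 3 * np.sqrt(alpha * (1 - alpha) / n)
    assert abs(frac - alpha) <= band
    # denoising pushes the signal-free map to (almost) nothing
    den = mp.denoise_components(res.mask)
    assert den.sum() <= res.mask.sum()
    assert den.mean() < alpha


# ---------------------------------------------------------------------------
# Bonferroni and denoising
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "base, n, expected",
    [(0.05, 500_000, 1e-7), (0.05, 1, 0.05), (0.01, 100, 1e-4)],
)
def test_bonferroni_arithmetic(base, n, expected):
    assert np.isclose(mp.bonferroni_alpha(base, n), expected)


def test_bonferroni_requires_positive_count():
    with pytest.raises(ValueError):
        mp.bonferroni_alpha(0.05, 0)


def test_denoise_component_size_rule():
    mask = np.zeros((30, 30), dtype=bool)
    mask[1, 1] = True                       # isolated pixel -> removed
    mask[5, 5:15] = True                    # 10 pixels -> removed
    mask[20, 3:14] = True                   # 11 pixels -> kept
    out = mp.denoise_components(mask, min_size=11)
    assert not out[1, 1]
    assert not out[5, 5:15].any()
    assert out[20, 3:14].all()


def _flood_fill_components(mask, connectivity=8):
    """Brute-force flood-fill labelling (test oracle)."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack, comp = [(sy, sx)], []
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy, dx in nbrs:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            comps.append(comp)
    return comps


@pytest.mark.parametrize("connectivity", [4, 8])
def test_denoise_matches_flood_fill_oracle(connectivity):
    g = np.random.default_rng(123)
    for _ in range(100):
        mask = g.random((20, 20)) < 0.35
        out = mp.denoise_components(mask, min_size=11, connectivity=connectivity)
        expected = np.zeros_like(mask)
        for comp in _flood_fill_components(mask, connectivity):
            if len(comp) >= 11:
                for y, x in comp:
                    expected[y, x] = True
        np.testing.assert_array_equal(out, expected)


def test_denoise_never_adds_pixels(rng):
    mask = rng.random((40, 40)) < 0.3
    out = mp.denoise_components(mask)
    assert not (out & ~mask).any()


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def test_overlap_identity_and_disjoint():
    fl_mask = np.zeros((20, 20), dtype=bool)
    fl_mask[5:15, 5:15] = True
    fl = _forelimb(fl_mask)
    assert mp.overlap_percent(fl_mask, fl) == 100.0
    assert mp.overlap_percent(~fl_mask, fl) == 0.0
    with pytest.raises(ValueError, match="empty"):
        mp.overlap_percent(fl_mask, _forelimb(np.zeros((20, 20), bool)))


def test_overlap_excludes_vessels():
    fl_mask = np.zeros((10, 10), dtype=bool)
    fl_mask[2:8, 2:8] = True
    vessel = np.zeros((10, 10), dtype=bool)
    vessel[4, :] = True
    fl = _forelimb(fl_mask, vessel)
    # a map equal to the forelimb is still 100%: vessels drop from both sides
    assert mp.overlap_percent(fl_mask, fl) == 100.0
    half = fl_mask.copy()
    half[:, :5] = False
    expected = 100.0 * (half & fl_mask & ~vessel).sum() / (fl_mask & ~vessel).sum()
    assert np.isclose(mp.overlap_percent(half, fl), expected)


def test_bonferroni_map_is_subset_and_denoise_shrinks_overlap(rng):
    base = rng.normal(0, 1, (30, 32, 32))
    mov = rng.normal(0, 1, (30, 32, 32))
    mov[:, 8:20, 8:20] -= 1.2
    raw = mp.pixelwise_ttest_map(mov, base, alpha=1e-4)
    bonf = mp.pixelwise_ttest_map(mov, base, alpha=mp.bonferroni_alpha(1e-4, 1024))
    assert not (bonf.mask & ~raw.mask).any()
    fl = _forelimb(np.ones((32, 32), dtype=bool))
    den = mp.denoise_components(raw.mask)
    assert mp.overlap_percent(den, fl) <= mp.overlap_percent(raw.mask, fl)


# ---------------------------------------------------------------------------
# ROI time courses and peak-time maps
# ---------------------------------------------------------------------------

def test_roi_timecourse_uniform_and_vessel_exclusion():
    series = np.full((70, 10, 10), 0.5)
    roi = mp.circle_roi((5, 5), 3, (10, 10))
    np.testing.assert_array_equal(
        mp.roi_timecourse(series, roi), np.full(70, 0.5)
    )
    vessel = np.ones((10, 10), dtype=bool)
    with pytest.raises(ValueError, match="empty"):
        mp.roi_timecourse(series, roi, vessel)


def test_peak_time_single_minimum():
    t = _times()
    series = np.zeros((70, 4, 4))
    curve = -np.exp(-((t - 4.0) ** 2) / (2 * 0.6**2))
    series[:, 1, 2] = curve
    out = mp.peak_time_map(series, t)
    assert out.valid[1, 2]
    assert abs(out.time_s[1, 2] - 4.0) <= 0.1 + 1e-9


def test_peak_time_never_negative_is_invalid():
    t = _times()
    series = np.zeros((70, 2, 2))
    series[:, 0, 0] = np.linspace(0, 1, 70)  # monotone increasing
    out = mp.peak_time_map(series, t)
    assert not out.valid[0, 0]
    assert np.isnan(out.time_s[0, 0])


def test_peak_time_tie_breaks_earliest():
    t = _times()
    series = np.zeros((70, 1, 1))
    series[30, 0, 0] = -1.0
    series[50, 0, 0] = -1.0
    out = mp.peak_time_map(series, t)
    assert np.isclose(out.time_s[0, 0], t[30])


# ---------------------------------------------------------------------------
# per-frame map-size series
# ---------------------------------------------------------------------------

def test_map_size_timecourse_null_and_signal():
    g = np.random.default_rng(9)
    n_tr, H = 30, 24
    t = _times()
    stacks = g.normal(0, 1, (n_tr, 70, H, H))
    sig = -4.0 * np.exp(-((t - 4.0) ** 2) / 2.0)
    stacks[:, :, 6:18, 6:18] += sig[None, :, None, None]
    baseline = stacks[:, :10].mean(axis=1)
    fl = _forelimb(np.ones((H, H), dtype=bool))
    series = mp.map_size_timecourse(stacks, baseline, fl, alpha=1e-4)
    assert series.shape == (70,)
    assert series[:10].max() <= 1.0          # pre-Cue ~ nothing
    # the series rises with the injected response and is maximal at its
    # peak (a plateau is fine: the whole signal region saturates)
    assert series[np.argmin(np.abs(t - 4.0))] == series.max()
    assert series[t < 1.5].max() < series.max() / 5
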