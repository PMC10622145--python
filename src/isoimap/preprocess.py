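"""ISOI preprocessing: registration, baseline normalization, filtering.

Raw trial stacks (70 frames at 10 frames/s, acquisition starting 1 s
before the Cue) are rigid-aligned frame by frame, screened for
misregistration (>10 px excludes the trial), converted to fractional
reflectance change dR/R against the 10 pre-Cue frames, high-pass
filtered with a large median kernel (illumination / residual-motion
correction) and smoothed with a small Gaussian.  Sessions are brought
into a common reference frame with a landmark-based non-rigid warp
(global affine + multilevel B-spline approximation of the residual
displacement field).

Coordinate convention: row-major pixel grid, origin top-left, 0-based,
pixel centres at integer coordinates; displacements are (dx = columns,
dy = rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

__all__ = [
    "TrialStack",
    "FilterConfig",
    "SessionWarp",
    "estimate_rigid_shift",
    "register_stack",
    "screen_registration",
    "normalize_to_baseline",
    "spatial_filter",
    "fit_session_warp",
    "estimate_vessel_mask",
    "apply_warp",
    "clip_for_display",
    "preprocess_trial",
]


@dataclass
class TrialStack:
    """One trial's image time series with frame timing relative to Cue.

    ``frames`` holds raw counts or fractional dR/R, shape (n, H, W).
    Frame timestamps mark the *end* of each 0.1-s exposure, so a stack
    acquired from -1.0 s spans -0.9 ... +6.0 s and the 10 baseline
    frames are exactly those with t <= 0.
    """

    frames: np.ndarray
    t0_s: float = -1.0
    dt_s: float = 0.1
    condition: str = ""
    session_id: str = ""
    trial_id: str = ""
    shifts_px: np.ndarray | None = None  # (n, 2) estimated (dx, dy)
    true_shifts_px: np.ndarray | None = None  # simulator ground truth
    excluded: bool = False
    exclusion_reason: str = ""
    normalized: bool = False

    @property
    def times(self) -> np.ndarray:
        n = self.frames.shape[0]
        return self.t0_s + self.dt_s * (np.arange(n) + 1)

    @property
    def n_baseline(self) -> int:
        return int(np.count_nonzero(self.times <= 1e-9))


@dataclass
class FilterConfig:
    """Spatial filtering parameters (native pixels).

    ``median_kernel_px`` is the side of the square high-pass median
    window (forced odd), ``gaussian_kernel_px`` the smoothing window
    (sigma = window / 3), ``downsample_factor`` accelerates the median
    by running it on a downsampled image, and
    ``misregistration_limit_px`` is the trial-exclusion limit.
    """

    median_kernel_px: int = 250
    gaussian_kernel_px: float = 5.0
    downsample_factor: int = 4
    misregistration_limit_px: float = 10.0

    def __post_init__(self) -> None:
        if self.median_kernel_px <= 0 or self.gaussian_kernel_px <= 0:
            raise ValueError("kernel sizes must be positive")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.misregistration_limit_px <= 0:
            raise ValueError("misregistration limit must be positive")


def estimate_rigid_shift(
    frame: np.ndarray, reference_frame: np.ndarray, upsample_factor: int = 50
) -> tuple[float, float]:
    """Translation (dx, dy) that best aligns ``frame`` onto the reference.

    Phase correlation with subpixel refinement; applying the returned
    correction (shift the frame by +dx columns, +dy rows) registers it
    to the reference.  A blank (zero-variance) frame has no defined
    shift and raises.
    """
    if frame.shape != reference_frame.shape:
        raise ValueError("frame and reference must have the same shape")
    if float(np.ptp(frame)) == 0.0 or float(np.ptp(reference_frame)) == 0.0:
        raise ValueError("blank (zero-variance) frame: shift undefined")
    # Mean removal + Hann window suppress the DC term and the wrap-around
    # edge bias of the FFT correlation.  The window multiplicatively
    # shrinks the estimate by a few percent of the shift, so a second
    # pass re-estimates the residual after correcting the first guess.
    win = np.outer(np.hanning(frame.shape[0]), np.hanning(frame.shape[1]))
    ref = (reference_frame - reference_frame.mean()) * win
    dx = dy = 0.0
    moving = frame
    for _ in range(2):
        mov = (moving - moving.mean()) * win
        (sy, sx), _, _ = phase_cross_correlation(
            ref, mov, upsample_factor=upsample_factor, normalization=None,
        )
        dx += float(sx)
        dy += float(sy)
        if sx == 0.0 and sy == 0.0:
            break
        moving = ndi.shift(frame, (dy, dx), order=3, mode="nearest")
    return dx, dy


def register_stack(
    stack: TrialStack, reference_frame: np.ndarray, upsample_factor: int = 50
) -> TrialStack:
    """Rigid-align every frame to the reference, recording the shifts.

    Frames are resampled (cubic spline) by the estimated correction; the
    per-frame corrections are stored in ``shifts_px`` for screening.
    """
    n = stack.frames.shape[0]
    shifts = np.zeros((n, 2))
    out = np.empty_like(stack.frames)
    for k in range(n):
        dx, dy = estimate_rigid_shift(
            stack.frames[k], reference_frame, upsample_factor
        )
        shifts[k] = (dx, dy)
        if dx == 0.0 and dy == 0.0:
            out[k] = stack.frames[k]
        else:
            out[k] = ndi.shift(
                stack.frames[k], (dy, dx), order=3, mode="nearest"
            )
    stack.frames = out
    stack.shifts_px = shifts
    return stack


def screen_registration(
    shifts_px: np.ndarray, limit_px: float = 10.0
) -> tuple[bool, str]:
    """Keep/exclude decision from per-frame shift magnitudes.

    A trial is excluded iff any frame is out of register by more than
    ``limit_px``; the reason names the worst frame.
    """
    shifts = np.asarray(shifts_px, dtype=float)
    mags = np.hypot(shifts[:, 0], shifts[:, 1])
    worst = int(np.argmax(mags))
    if mags[worst] > limit_px:
        return False, (
            f"out of register by {mags[worst]:.2f} px at frame {worst} "
            f"(limit {limit_px:g} px)"
        )
    return True, ""


def normalize_to_baseline(stack: TrialStack, fractional: bool = True) -> TrialStack:
    """Convert raw counts to reflectance change against the pre-Cue mean.

    The pre-Cue frames (t <= 0) are averaged per pixel and subtracted;
    with ``fractional`` (the standard ISOI dR/R convention) the result
    is also divided by the baseline mean.  ``fractional=False`` keeps
    the plain subtraction.
    """
    nb = stack.n_baseline
    if nb < 10:
        raise ValueError(f"need >=10 pre-Cue frames, found {nb}")
    baseline = stack.frames[:nb].mean(axis=0)
    if fractional:
        bad = np.argwhere(baseline <= 0)
        if len(bad):
            raise ValueError(
                f"non-positive baseline at pixel(s) {bad[:5].tolist()}"
            )
        frames = (stack.frames - baseline) / baseline
    else:
        frames = stack.frames - baseline
    return TrialStack(
        frames=frames, t0_s=stack.t0_s, dt_s=stack.dt_s,
        condition=stack.condition, session_id=stack.session_id,
        trial_id=stack.trial_id, shifts_px=stack.shifts_px,
        true_shifts_px=stack.true_shifts_px, normalized=True,
    )


def spatial_filter(frame: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """High-pass median filter then low-pass Gaussian smoothing.

    The high-pass subtracts a large-kernel median (computed on a
    ``downsample_factor``-times downsampled image purely as a
    computation accelerator, then upsampled); the Gaussian smoothing is
    applied last.  Reflect padding at the boundary for both filters.
    """
    h, w = frame.shape
    k = int(cfg.median_kernel_px) | 1  # force odd
    if k >= min(h, w):
        raise ValueError(
            f"median kernel ({k} px) must be smaller than the image ({h}x{w})"
        )
    f = cfg.downsample_factor
    if f > 1:
        small = ndi.zoom(frame, 1.0 / f, order=1, mode="reflect", grid_mode=True)
        ks = max(3, int(round(k / f)) | 1)
        med_small = ndi.median_filter(small, size=ks, mode="reflect")
        med = ndi.zoom(med_small, np.array(frame.shape) / np.array(small.shape),
                       order=1, mode="reflect", grid_mode=True)
        med = med[:h, :w]
    else:
        med = ndi.median_filter(frame, size=k, mode="reflect")
    highpassed = frame - med
    sigma = cfg.gaussian_kernel_px / 3.0
    return ndi.gaussian_filter(highpassed, sigma=sigma, mode="reflect")


def estimate_vessel_mask(
    reference_frame: np.ndarray, k_sd: float = 1.0, min_size_px: int = 20
) -> np.ndarray:
    """Crude vessel mask: dark pixels of the reference surface image.

    Major vessels absorb strongly and appear as dark tracks; pixels
    below median - k_sd * SD are flagged and specks removed.  This is a
    convenience starting point only — vessel masks are normally curated
    by hand and supplied as input to the ROI/overlap analyses.
    """
    from skimage import morphology

    med = float(np.median(reference_frame))
    sd = float(reference_frame.std())
    mask = reference_frame < med - k_sd * sd
    return morphology.remove_small_objects(mask, min_size=min_size_px)


def clip_for_display(frame: np.ndarray, k_sd: float = 0.3) -> np.ndarray:
    """Clip pixel values to median +/- k_sd * SD (rendering only).

    Display clipping never feeds statistics: thresholded maps and time
    courses are computed from unclipped values.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    med = float(np.median(frame))
    sd = float(frame.std())
    return np.clip(frame, med - k_sd * sd, med + k_sd * sd)


# ---------------------------------------------------------------------------
# Landmark-based non-rigid session registration
# ---------------------------------------------------------------------------

def _bspline_basis(t: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values B_0..B_3 at local t in [0,1)."""
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


class _BSplineLattice:
    """One level of scattered-data B-spline approximation (BA algorithm).

    A (m+3) x (n+3) control lattice over [0, W] x [0, H]; control values
    chosen in the least-squares-like closed form of the BA algorithm,
    which minimizes a local proximity criterion per control point.
    """

    def __init__(self, shape_hw: tuple[float, float], n_cells: int):
        self.h, self.w = shape_hw
        self.n_cells = n_cells
        self.phi = np.zeros((n_cells + 3, n_cells + 3, 2))

    def _locate(self, xy: np.ndarray):
        sx = xy[:, 0] / self.w * self.n_cells
        sy = xy[:, 1] / self.h * self.n_cells
        sx = np.clip(sx, 0, self.n_cells - 1e-9)
        sy = np.clip(sy, 0, self.n_cells - 1e-9)
        ix, iy = np.floor(sx).astype(int), np.floor(sy).astype(int)
        return ix, iy, _bspline_basis(sx - ix), _bspline_basis(sy - iy)

    def fit(self, xy: np.ndarray, d: np.ndarray) -> None:
        ix, iy, bx, by = self._locate(xy)
        num = np.zeros_like(self.phi)
        den = np.zeros(self.phi.shape[:2])
        for p in range(len(xy)):
            w = np.outer(by[p], bx[p])  # (4, 4) row=y, col=x
            s = float((w * w).sum())
            phi_p = w[..., None] * d[p] / s  # per-point optimal control values
            sl = (slice(iy[p], iy[p] + 4), slice(ix[p], ix[p] + 4))
            num[sl] += (w * w)[..., None] * phi_p
            den[sl] += w * w
        nz = den > 0
        self.phi[nz] = num[nz] / den[nz][:, None]

    def evaluate(self, xy: np.ndarray) -> np.ndarray:
        ix, iy, bx, by = self._locate(xy)
        out = np.zeros((len(xy), 2))
        for a in range(4):
            for b in range(4):
                out += (by[:, a] * bx[:, b])[:, None] * self.phi[iy + a, ix + b]
        return out


@dataclass
class SessionWarp:
    """Fitted session -> reference displacement field.

    ``affine`` is a (3, 2) matrix ([x, y, 1] @ affine = displacement) and
    ``levels`` the hierarchy of B-spline lattices fitted to the affine
    residuals.  ``residual_px`` holds per-landmark fitting residuals.
    """

    shape_hw: tuple[int, int]
    affine: np.ndarray
    levels: list[_BSplineLattice]
    landmarks_session: np.ndarray
    landmarks_reference: np.ndarray
    residual_px: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def residual_rms_px(self) -> float:
        return float(np.sqrt(np.mean(self.residual_px**2))) if len(self.residual_px) else 0.0

    def displacement(self, xy: np.ndarray) -> np.ndarray:
        """Displacement vectors (dx, dy) at points ``xy`` (x, y columns)."""
        xy = np.asarray(xy, dtype=float)
        ones = np.ones((len(xy), 1))
        d = np.hstack([xy, ones]) @ self.affine
        for lat in self.levels:
            d = d + lat.evaluate(xy)
        return d

    def displacement_field(self) -> np.ndarray:
        """Dense (H, W, 2) field of (dx, dy) on the pixel grid."""
        h, w = self.shape_hw
        X, Y = np.meshgrid(np.arange(w), np.arange(h))
        d = self.displacement(np.column_stack([X.ravel(), Y.ravel()]))
        return d.reshape(h, w, 2)

    def jacobian_ok(self, step: int = 4) -> bool:
        """True if det(I + grad d) > 0 on a test grid (no folding)."""
        f = self.displacement_field()[::step, ::step]
        dudx = np.gradient(f[..., 0], step, axis=1)
        dudy = np.gradient(f[..., 0], step, axis=0)
        dvdx = np.gradient(f[..., 1], step, axis=1)
        dvdy = np.gradient(f[..., 1], step, axis=0)
        det = (1 + dudx) * (1 + dvdy) - dudy * dvdx
        return bool((det > 0).all())


def fit_session_warp(
    landmarks_session: np.ndarray,
    landmarks_reference: np.ndarray,
    shape_hw: tuple[int, int],
    levels: int = 5,
) -> SessionWarp:
    """Fit the session -> reference displacement field from landmarks.

    A global affine component is estimated by least squares, then a
    multilevel B-spline approximation (control lattices refined from 1
    cell up, ``levels`` levels) absorbs the residual scattered
    displacements.  Needs >= 4 non-collinear landmark pairs.
    """
    s = np.asarray(landmarks_session, dtype=float)
    r = np.asarray(landmarks_reference, dtype=float)
    if s.shape != r.shape or s.ndim != 2 or s.shape[1] != 2:
        raise ValueError("landmark arrays must both be (n, 2)")
    if len(s) < 4:
        raise ValueError(f"need >=4 landmark pairs, got {len(s)}")
    A = np.hstack([s, np.ones((len(s), 1))])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("landmarks are collinear: warp fit is degenerate")
    d = r - s
    affine, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = d - A @ affine
    lattices: list[_BSplineLattice] = []
    for lv in range(levels):
        lat = _BSplineLattice(shape_hw, 2**lv)
        lat.fit(s, resid)
        resid = resid - lat.evaluate(s)
        lattices.append(lat)
    warp = SessionWarp(
        shape_hw=shape_hw, affine=affine, levels=lattices,
        landmarks_session=s, landmarks_reference=r,
        residual_px=np.linalg.norm(resid, axis=1),
    )
    return warp


def apply_warp(frame: np.ndarray, warp: SessionWarp, order: int = 1) -> np.ndarray:
    """Resample a session frame into the reference coordinate frame.

    The output at reference pixel p samples the session frame at
    p - d(p), the first-order inverse of the fitted session->reference
    displacement d (valid for the smooth, small-magnitude warps this
    pipeline registers).
    """
    h, w = frame.shape
    f = warp.displacement_field()
    X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    coords = np.stack([Y - f[..., 1], X - f[..., 0]])
    return ndi.map_coordinates(frame, coords, order=order, mode="nearest")


def preprocess_trial(
    stack: TrialStack,
    reference_frame: np.ndarray | None,
    cfg: FilterConfig,
    do_register: bool = True,
    do_filter: bool = True,
    fractional: bool = True,
) -> TrialStack:
    """Full per-trial preprocessing: register, screen, normalize, filter.

    Returns the processed dR/R stack; an excluded trial comes back with
    ``excluded=True`` and its frames untouched past registration.
    """
    if do_register:
        if reference_frame is None:
            raise ValueError("registration requested without a reference frame")
        stack = register_stack(stack, reference_frame)
        keep, reason = screen_registration(
            stack.shifts_px, cfg.misregistration_limit_px
        )
        if not keep:
            stack.excluded = True
            stack.exclusion_reason = reason
            return stack
    out = normalize_to_baseline(stack, fractional=fractional)
    if do_filter:
        frames = np.empty_like(out.frames)
        for k in range(out.frames.shape[0]):
            frames[k] = spatial_filter(out.frames[k], cfg)
        out.frames = frames
    return out
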