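"""Raw-trace preprocessing for two-photon SCN recordings.

The processing chain mirrors a standard GRIN-endoscope calcium-imaging
workflow:

1. rigid (translation-only) motion correction of each frame against the
   first frame of the session, scored with a histogram mutual-information
   metric;
2. ROI trace extraction as the per-frame mean over mask voxels;
3. subtraction of an out-of-endoscope background trace;
4. removal of the photobleaching trend by fitting a mono-exponential
   decay ``a·exp(-t/tau) + c`` with a trust-region nonlinear
   least-squares solver (the fitted constant ``c`` is retained);
5. Z-normalization in which the *median* of the 30-s dark baseline is
   mapped to zero and the scale is the standard deviation of the full
   120-s trace:

   ``z(t) = (F(t) - F_baseline) / F_std``

Each trial is a 120-s series: 30 s of darkness followed by 90 s of light
to the eyes, sampled at 23 Hz (2760 frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TraceRecording",
    "NormalizedTrace",
    "TranslationEstimate",
    "DetrendReport",
    "mattes_mi",
    "register_translation",
    "register_stack",
    "apply_translation",
    "extract_trace",
    "subtract_background",
    "detrend",
    "fit_baseline_trend",
    "evaluate_decay",
    "normalize_trace",
    "preprocess_trace",
]

FRAME_RATE = 23.0
BASELINE_S = 30.0
LIGHT_S = 90.0
TRIAL_S = BASELINE_S + LIGHT_S


@dataclass
class TraceRecording:
    """One 120-s fluorescence series with its trial metadata.

    ``zt`` is the zeitgeber time of the session (8, 16 or 22), ``day``
    and ``trial`` index the 3 x 3 repeats at that ZT, ``z_plane`` is the
    focal plane ('ventral' or 'dorsal') and ``centroid`` the ROI centre
    in micrometres.
    """

    neuron_id: int
    zt: int
    day: int
    trial: int
    values: np.ndarray
    frame_rate: float = FRAME_RATE
    z_plane: str = "ventral"
    vip: bool = False
    centroid: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds relative to light onset (t=0)."""
        return np.arange(self.values.size) / self.frame_rate - BASELINE_S


@dataclass
class NormalizedTrace:
    """Z-scored trace with baseline median pinned to zero."""

    z: np.ndarray
    f_baseline: float
    f_std: float
    frame_rate: float = FRAME_RATE
    baseline_window: tuple[float, float] = (-BASELINE_S, 0.0)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.z.size) / self.frame_rate + self.baseline_window[0]


@dataclass
class TranslationEstimate:
    """Estimated in-plane displacement of a moving frame vs a reference."""

    t_x: int
    t_y: int
    metric_value: float
    degenerate: bool = False


@dataclass
class DetrendReport:
    """Fitted bleaching trend: exponential (a, tau, c) or, when the
    baseline shows no resolvable curvature, a linear slope."""

    a: float
    tau: float
    c: float
    residual_norm: float
    fallback_linear: bool = False
    slope: float = 0.0


# ---------------------------------------------------------------------------
# mutual-information registration
# ---------------------------------------------------------------------------

def _quantize(image: np.ndarray, n_bins: int) -> np.ndarray:
    """Map intensities to integer bin indices over the image's own range."""
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros(image.shape, dtype=np.intp)
    idx = ((image - lo) * (n_bins / (hi - lo))).astype(np.intp)
    return np.clip(idx, 0, n_bins - 1)


def _mi_from_joint(joint: np.ndarray) -> float:
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    return float(
        np.sum(p[nz] * np.log(p[nz]))
        - np.sum(px[px > 0] * np.log(px[px > 0]))
        - np.sum(py[py > 0] * np.log(py[py > 0]))
    )


def mattes_mi(image_a: np.ndarray, image_b: np.ndarray, n_bins: int = 32) -> float:
    """Histogram mutual information (nats) of two equal-shape images.

    Intensities are binned into ``n_bins`` levels over each image's own
    range and MI is computed from the joint histogram.  Used (negated)
    as the registration cost.  A constant image has a zero-entropy
    marginal; that degenerate case returns 0 with a warning.
    """
    image_a = np.asarray(image_a, dtype=float)
    image_b = np.asarray(image_b, dtype=float)
    if image_a.shape != image_b.shape:
        raise ValueError("images must have equal shape")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if image_a.max() == image_a.min() or image_b.max() == image_b.min():
        warnings.warn("constant image: mutual information undefined, returning 0")
        return 0.0
    qa = _quantize(image_a, n_bins)
    qb = _quantize(image_b, n_bins)
    joint = np.bincount(
        (qa * n_bins + qb).ravel(), minlength=n_bins * n_bins
    ).reshape(n_bins, n_bins)
    return _mi_from_joint(joint)


def _overlap_slices(shape: tuple[int, int], t_x: int, t_y: int):
    """Index slices pairing reference pixels with moving pixels for a
    candidate shift, where moving[r, c] = reference[r - t_y, c - t_x]."""
    h, w = shape
    ref_rows = slice(max(0, -t_y), h - max(0, t_y))
    ref_cols = slice(max(0, -t_x), w - max(0, t_x))
    mov_rows = slice(max(0, t_y), h + min(0, t_y))
    mov_cols = slice(max(0, t_x), w + min(0, t_x))
    return (ref_rows, ref_cols), (mov_rows, mov_cols)


def register_translation(
    moving: np.ndarray,
    reference: np.ndarray,
    search_bound: int = 20,
    n_bins: int = 32,
    strategy: Literal["exhaustive", "coarse_to_fine"] = "exhaustive",
) -> TranslationEstimate:
    """Estimate the integer translation that maps ``reference`` onto
    ``moving`` by maximizing mutual information over the overlap.

    The returned ``(t_x, t_y)`` is the displacement of the moving frame:
    ``moving[r, c] ~= reference[r - t_y, c - t_x]``.  Shifting the moving
    frame back by the estimate aligns it with the reference.  Only
    overlapping pixels are scored.

    ``strategy='exhaustive'`` scans every integer shift within
    ``search_bound`` (exact by construction); ``'coarse_to_fine'`` scans
    a stride-4 grid then refines locally and is faster but can in
    principle miss a narrow optimum.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("images must have equal shape")
    if search_bound >= min(moving.shape) // 4:
        raise ValueError("search_bound must be < min(dim)/4")
    if moving.max() == moving.min() or reference.max() == reference.min():
        warnings.warn("degenerate (constant) image: returning zero shift")
        return TranslationEstimate(0, 0, 0.0, degenerate=True)

    q_ref = _quantize(reference, n_bins)
    q_mov = _quantize(moving, n_bins)

    def score(t_x: int, t_y: int) -> float:
        (rr, rc), (mr, mc) = _overlap_slices(moving.shape, t_x, t_y)
        idx = q_ref[rr, rc] * n_bins + q_mov[mr, mc]
        joint = np.bincount(idx.ravel(), minlength=n_bins * n_bins).reshape(
            n_bins, n_bins
        )
        return _mi_from_joint(joint)

    b = int(search_bound)
    if strategy == "exhaustive":
        candidates = [(tx, ty) for ty in range(-b, b + 1) for tx in range(-b, b + 1)]
        best = max(candidates, key=lambda s: score(*s))
    else:
        coarse = [(tx, ty) for ty in range(-b, b + 1, 4) for tx in range(-b, b + 1, 4)]
        cx, cy = max(coarse, key=lambda s: score(*s))
        local = [
            (tx, ty)
            for ty in range(max(-b, cy - 3), min(b, cy + 3) + 1)
            for tx in range(max(-b, cx - 3), min(b, cx + 3) + 1)
        ]
        best = max(local, key=lambda s: score(*s))
    return TranslationEstimate(best[0], best[1], score(*best))


def apply_translation(image: np.ndarray, t_x: int, t_y: int) -> np.ndarray:
    """Shift an image by integer ``(t_x, t_y)``; exposed pixels take the
    image edge value (no wrap-around)."""
    out = np.empty_like(image)
    h, w = image.shape
    rows = np.clip(np.arange(h) - t_y, 0, h - 1)
    cols = np.clip(np.arange(w) - t_x, 0, w - 1)
    out[:] = image[np.ix_(rows, cols)]
    return out


def register_stack(
    stack: np.ndarray,
    search_bound: int = 20,
    qc_shift_px: float = 10.0,
    strategy: Literal["exhaustive", "coarse_to_fine"] = "coarse_to_fine",
) -> tuple[np.ndarray, list[TranslationEstimate], bool]:
    """Motion-correct a stack against its first frame.

    Returns the corrected stack, per-frame estimates, and an
    "excessive motion" QC flag raised when any frame's estimated shift
    exceeds ``qc_shift_px`` (such trials are typically excluded).
    """
    stack = np.asarray(stack, dtype=float)
    reference = stack[0]
    corrected = np.empty_like(stack)
    corrected[0] = reference
    estimates = [TranslationEstimate(0, 0, mattes_mi(reference, reference))]
    for k in range(1, stack.shape[0]):
        est = register_translation(stack[k], reference, search_bound, strategy=strategy)
        corrected[k] = apply_translation(stack[k], -est.t_x, -est.t_y)
        estimates.append(est)
    excessive = any(max(abs(e.t_x), abs(e.t_y)) > qc_shift_px for e in estimates)
    return corrected, estimates, excessive


# ---------------------------------------------------------------------------
# trace extraction and normalization
# ---------------------------------------------------------------------------

def extract_trace(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-frame mean fluorescence over the voxels of one ROI mask."""
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape[1:]:
        raise ValueError("mask shape must match frame shape")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return stack[:, mask].mean(axis=1)


def subtract_background(trace: np.ndarray, background_trace: np.ndarray) -> np.ndarray:
    """Remove the out-of-endoscope background trace (elementwise)."""
    trace = np.asarray(trace, dtype=float)
    background_trace = np.asarray(background_trace, dtype=float)
    if trace.shape != background_trace.shape:
        raise ValueError("trace and background length mismatch")
    return trace - background_trace


def detrend(
    trace: np.ndarray,
    frame_rate: float = FRAME_RATE,
    baseline_s: float = BASELINE_S,
) -> tuple[np.ndarray, DetrendReport]:
    """Remove the photobleaching trend from a trace.

    The trend model is a mono-exponential decay ``a·exp(-t/tau) + c``
    fitted by trust-region nonlinear least squares; the decaying part
    is subtracted and the constant ``c`` retained so absolute intensity
    offsets survive for background bookkeeping.

    Identifiability dictates *where* the trend is estimated.  A fit
    over the whole trial is not identifiable in the presence of slow
    stimulus-evoked components: over the 90-s light window a sustained
    late response and a bleaching trend are interchangeable to the
    fitter, which silently absorbs part of the response.  The trend is
    therefore estimated on the dark pre-stimulus baseline only — the
    one window guaranteed response-free — and extrapolated across the
    trial:

    * if the baseline shows resolvable exponential curvature (the
      exponential fit at least halves the straight line's residual sum
      of squares), the fitted exponential is subtracted — this recovers a
      strong decay exactly;
    * otherwise the decay is in its quasi-linear regime, where ``a``
      and ``tau`` are not separately identified but their product
      (the slope) is; the robust Theil-Sen baseline slope is
      subtracted instead.  Subtracting the Theil-Sen line makes this
      path exactly idempotent.

    ``a`` is bounded below by zero (photobleaching is a decay).  If the
    exponential solver fails the linear path is used and the report is
    flagged.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 100:
        raise ValueError("trace too short to detrend (need >= 100 frames)")
    n_base = int(round(frame_rate * baseline_s))
    n_base = min(max(n_base, 10), trace.size)
    report = fit_baseline_trend(trace[:n_base], frame_rate)
    t = np.arange(trace.size) / frame_rate
    return trace - evaluate_decay(report, t), report


def fit_baseline_trend(baseline: np.ndarray, frame_rate: float = FRAME_RATE) -> DetrendReport:
    """Fit the bleaching-trend model to a response-free baseline window.

    Compares the mono-exponential against the straight line (see
    :func:`detrend`); the report describes the winner.  The baseline
    may be a single trial's dark window or — better, when available —
    the mean of many trials' dark windows from the same neuron, which
    cancels trial-specific noise before the slope is extrapolated.
    """
    yb = np.asarray(baseline, dtype=float)
    n_base = yb.size
    tb = np.arange(n_base) / frame_rate
    baseline_s = tb[-1]

    # linear candidate: robust baseline slope (decay only, never a rise);
    # Theil-Sen is O(n^2) pairs, so decimate — every 3rd frame is still
    # ~230 points over 30 s
    ts = stats.theilslopes(yb[::3], tb[::3])
    slope_lin = min(float(ts.slope), 0.0)
    intercept = float(np.median(yb) - slope_lin * np.median(tb))
    resid_lin = yb - (slope_lin * tb + intercept)
    sse_lin = float(np.sum(resid_lin**2))

    def resid_exp(p: np.ndarray) -> np.ndarray:
        a, tau, c = p
        return a * np.exp(-tb / tau) + c - yb

    best = None
    try:
        a0 = max(yb[: n_base // 5].mean() - yb[-n_base // 5 :].mean(), 0.0)
        for tau0 in (baseline_s / 3.0, baseline_s, 10.0 * baseline_s):
            sol = optimize.least_squares(
                resid_exp,
                x0=[max(a0, 1e-9), tau0, float(yb[-n_base // 5 :].mean())],
                method="trf",
                bounds=([0.0, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
                max_nfev=200,
            )
            if np.all(np.isfinite(sol.x)) and (best is None or sol.cost < best.cost):
                best = sol
    except Exception:
        best = None

    if best is not None and 2.0 * best.cost < 0.5 * sse_lin:
        a, tau, c = best.x
        return DetrendReport(float(a), float(tau), float(c), float(np.sqrt(2.0 * best.cost)))
    if best is None:
        warnings.warn("exponential trend fit failed to converge; linear trend used")
    return DetrendReport(
        0.0, np.inf, intercept, float(np.sqrt(sse_lin)),
        fallback_linear=True, slope=slope_lin,
    )


def evaluate_decay(report: DetrendReport, t: np.ndarray) -> np.ndarray:
    """The subtractable (decaying) part of a fitted trend at times ``t``."""
    if report.fallback_linear:
        return report.slope * np.asarray(t, dtype=float)
    return report.a * np.exp(-np.asarray(t, dtype=float) / report.tau)


def normalize_trace(
    trace: np.ndarray,
    frame_rate: float = FRAME_RATE,
    baseline_s: float = BASELINE_S,
) -> NormalizedTrace:
    """Z-normalize a detrended trace.

    ``F_baseline`` is the *median* over the dark baseline (first
    ``baseline_s`` seconds) rather than the whole-trace mean, so that
    zero marks the pre-stimulus level; ``F_std`` is the population
    standard deviation over the entire 120-s trace.
    """
    trace = np.asarray(trace, dtype=float)
    n_base = int(round(frame_rate * baseline_s))
    if n_base < 1 or n_base > trace.size:
        raise ValueError("baseline window empty or longer than trace")
    f_std = float(trace.std())  # population (n) denominator
    if f_std == 0.0:
        raise ValueError("zero-variance trace: Z-score undefined")
    f_baseline = float(np.median(trace[:n_base]))
    z = (trace - f_baseline) / f_std
    return NormalizedTrace(
        z, f_baseline, f_std, frame_rate, (-baseline_s, 0.0)
    )


def preprocess_trace(
    raw: np.ndarray,
    frame_rate: float = FRAME_RATE,
    background: np.ndarray | None = None,
) -> NormalizedTrace:
    """Full chain: background subtraction -> detrend -> Z-normalize."""
    trace = np.asarray(raw, dtype=float)
    if background is not None:
        trace = subtract_background(trace, background)
    trace, _ = detrend(trace, frame_rate)
    return normalize_trace(trace, frame_rate)
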