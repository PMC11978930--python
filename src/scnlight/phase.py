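"""Behavioral circadian phase-shift estimation from wheel-running actograms.

Two estimators are provided, both referenced to a regression line fitted
to the days immediately before a drug injection:

* **Activity-onset regression** — daily activity onsets are detected
  (first sustained crossing of an activity threshold after a quiescent
  interval), unwrapped across midnight, and regressed on day number over
  3-5 pre-injection days.  The phase shift is the gap between the
  extrapolated line and the observed post-injection onsets; the
  injection day itself is excluded.
* **Cosinor acrophase** — a 24-h cosinor (mesor + amplitude·cos) is fit
  per day and the fitted peak time replaces the onset in the same
  pre-trend-versus-post comparison.

Sign convention: phase delays are negative, advances positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .synthetic import ActogramRecord

__all__ = [
    "OnsetSeries",
    "PhaseShiftEstimate",
    "detect_onsets",
    "fit_onset_regression",
    "estimate_phase_shift",
    "acrophase",
    "estimate_phase_shift_acrophase",
]


@dataclass
class OnsetSeries:
    """Detected activity onset per qualifying day (hours within the day)."""

    onsets: dict[int, float]
    threshold: float
    params: dict = field(default_factory=dict)

    def days(self) -> list[int]:
        return sorted(self.onsets)


@dataclass
class PhaseShiftEstimate:
    shift: float  # hours; delays negative
    pre_period: float  # hours (slope + 24)
    pre_days_used: int
    method: str
    pre_slope: float = 0.0
    pre_intercept: float = 0.0


def _counts(actogram: ActogramRecord | np.ndarray) -> np.ndarray:
    if isinstance(actogram, ActogramRecord):
        return np.asarray(actogram.counts, dtype=float)
    return np.asarray(actogram, dtype=float)


def detect_onsets(
    actogram: ActogramRecord | np.ndarray,
    threshold_quantile: float = 0.75,
    quiescence_min: int = 360,
    active_min: int = 30,
    smooth_min: int = 15,
) -> OnsetSeries:
    """Detect one activity onset per day.

    The minute-binned counts are smoothed with a ``smooth_min`` moving
    average.  The activity threshold is *half* the
    ``threshold_quantile`` quantile of the nonzero raw counts — i.e.
    half the typical within-bout count — which places it midway between
    the quiescent and active levels so that bout-internal Poisson
    fluctuations cannot dip below it.  A bin is an onset when the
    smoothed series exceeds the threshold, at least 90% of the
    preceding ``quiescence_min`` minutes were below it, and at least
    80% of the following ``active_min`` minutes stay above it.  Days
    with no qualifying bin are skipped with a warning.
    """
    counts = _counts(actogram)
    n_days = counts.size // 1440
    if n_days < 3:
        raise ValueError("need at least 3 days of counts")
    smoothed = uniform_filter1d(counts, size=smooth_min, mode="nearest")
    nz = counts[counts > 0]
    if nz.size == 0:
        raise ValueError("no activity in record")
    thr = 0.5 * float(np.quantile(nz, threshold_quantile))
    above = smoothed >= thr

    onsets: dict[int, float] = {}
    for d in range(n_days):
        lo, hi = d * 1440, (d + 1) * 1440
        found = None
        for m in range(lo, hi):
            if not above[m]:
                continue
            q0 = m - quiescence_min
            if q0 < 0:
                continue
            if above[q0:m].mean() > 0.10:
                continue
            a1 = min(m + active_min, counts.size)
            if a1 - m < active_min or above[m:a1].mean() < 0.80:
                continue
            found = m
            break
        if found is None:
            warnings.warn(f"day {d}: no qualifying onset")
        else:
            onsets[d] = (found - lo) / 60.0
    return OnsetSeries(
        onsets,
        thr,
        {
            "threshold_quantile": threshold_quantile,
            "quiescence_min": quiescence_min,
            "active_min": active_min,
            "smooth_min": smooth_min,
        },
    )


def _unwrap(days: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Unwrap within-day times across midnight by minimizing day-to-day
    jumps (free-running drift is well under 12 h/day)."""
    out = times.astype(float).copy()
    for k in range(1, out.size):
        step = out[k] - out[k - 1]
        out[k] -= 24.0 * np.round(step / 24.0)
    return out


def fit_onset_regression(
    onsets: OnsetSeries | dict[int, float], days: list[int] | None = None
):
    """OLS line through unwrapped onset times.

    Returns ``(slope h/day, intercept h)``; slope + 24 is the
    free-running period.  Requires at least 3 onsets.
    """
    data = onsets.onsets if isinstance(onsets, OnsetSeries) else dict(onsets)
    use = sorted(data) if days is None else [d for d in sorted(days) if d in data]
    if len(use) < 3:
        raise ValueError("need at least 3 onsets for the regression")
    x = np.asarray(use, dtype=float)
    y = _unwrap(x, np.asarray([data[d] for d in use]))
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def estimate_phase_shift(
    actogram: ActogramRecord | np.ndarray,
    injection_day: int,
    pre_days: int = 5,
    post_days: int = 1,
    exclude_injection_day: bool = True,
    onset_kwargs: dict | None = None,
) -> PhaseShiftEstimate:
    """Onset-regression phase shift around an injection.

    The pre-injection line is fit on up to ``pre_days`` (3-5) onsets
    before the injection day; the shift is the mean of (extrapolated -
    observed) onset over the first ``post_days`` valid days after the
    (excluded) injection day.  Observed-later-than-predicted therefore
    yields a negative value: a phase delay.
    """
    series = detect_onsets(actogram, **(onset_kwargs or {}))
    pre_days = int(np.clip(pre_days, 3, 5))
    pre = [d for d in series.days() if d < injection_day][-pre_days:]
    slope, intercept = fit_onset_regression(series, pre)
    first_post = injection_day + 1 if exclude_injection_day else injection_day
    post = [d for d in series.days() if d >= first_post][:post_days]
    if not post:
        raise ValueError("no valid post-injection onset")
    # anchor unwrapping of post onsets to the pre-line prediction
    diffs = []
    for d in post:
        predicted = slope * d + intercept
        observed = series.onsets[d]
        observed -= 24.0 * np.round((observed - predicted) / 24.0)
        diffs.append(predicted - observed)
    return PhaseShiftEstimate(
        shift=float(np.mean(diffs)),
        pre_period=float(slope + 24.0),
        pre_days_used=len(pre),
        method="onset_regression",
        pre_slope=slope,
        pre_intercept=intercept,
    )


def acrophase(actogram: ActogramRecord | np.ndarray, window_days: list[int] | None = None) -> dict[int, float]:
    """Per-day cosinor acrophase (fitted 24-h peak time, hours).

    Fits ``counts ~ mesor + a·cos(wt) + b·sin(wt)`` per day by least
    squares; the acrophase is ``atan2(b, a)/w``.  Flat days are skipped
    with a warning.
    """
    counts = _counts(actogram)
    n_days = counts.size // 1440
    days = range(n_days) if window_days is None else window_days
    w = 2.0 * np.pi / 24.0
    t = np.arange(1440) / 60.0
    cos_t, sin_t = np.cos(w * t), np.sin(w * t)
    X = np.column_stack([np.ones_like(t), cos_t, sin_t])
    out: dict[int, float] = {}
    for d in days:
        y = counts[d * 1440 : (d + 1) * 1440]
        if y.size < 1440:
            continue
        if np.ptp(y) == 0:
            warnings.warn(f"day {d}: flat counts, acrophase undefined")
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        _, a, b = beta
        out[d] = float(np.arctan2(b, a) / w % 24.0)
    return out


def estimate_phase_shift_acrophase(
    actogram: ActogramRecord | np.ndarray,
    injection_day: int,
    pre_days: int = 5,
    post_days: int = 1,
    skip_days: int = 2,
) -> PhaseShiftEstimate:
    """Acrophase-based phase shift, mirroring the onset-regression logic.

    Because activity bouts cross midnight, the calendar day after the
    injection still contains morning activity from the last
    pre-injection cycle, which dilutes its cosinor acrophase.  The
    default therefore skips the injection day and that transition day
    (``skip_days=2``) and reads the first fully post-injection
    acrophase.
    """
    acro = acrophase(actogram)
    pre_days = int(np.clip(pre_days, 3, 5))
    pre = [d for d in sorted(acro) if d < injection_day][-pre_days:]
    if len(pre) < 3:
        raise ValueError("need at least 3 pre-injection acrophases")
    x = np.asarray(pre, dtype=float)
    y = _unwrap(x, np.asarray([acro[d] for d in pre]))
    res = stats.linregress(x, y)
    first_post = injection_day + skip_days
    post = [d for d in sorted(acro) if d >= first_post][:post_days]
    if not post:
        raise ValueError("no valid post-injection acrophase")
    diffs = []
    for d in post:
        predicted = res.slope * d + res.intercept
        observed = acro[d]
        observed -= 24.0 * np.round((observed - predicted) / 24.0)
        diffs.append(predicted - observed)
    return PhaseShiftEstimate(
        shift=float(np.mean(diffs)),
        pre_period=float(res.slope + 24.0),
        pre_days_used=len(pre),
        method="acrophase",
        pre_slope=float(res.slope),
        pre_intercept=float(res.intercept),
    )
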