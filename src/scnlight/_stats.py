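"""One-way ANOVA with Tukey HSD comparisons against a control level.

The per-bin significance coding used throughout the pipeline asks one
question many times: is the mean of a light bin above or below the
baseline bin?  This helper runs the omnibus one-way ANOVA across all
levels and, when it rejects at ``alpha``, applies the Tukey-Kramer
honestly-significant-difference criterion for each level against the
control level only, returning a trinary code per non-control level.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["anova_tukey_vs_control", "tukey_all_pairs"]


def _pooled(samples: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float, int]:
    means = np.array([s.mean() for s in samples])
    ns = np.array([s.size for s in samples])
    df = int(ns.sum() - len(samples))
    if df <= 0:
        raise ValueError("need more observations than levels")
    sse = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    mse = sse / df
    return means, ns, mse, df


def anova_tukey_vs_control(
    samples: list[np.ndarray], control: int = 0, alpha: float = 0.05
) -> np.ndarray:
    """Trinary codes (+1 above, -1 below, 0 not significant) for each
    non-control level versus the control level.

    Gate: the Tukey comparisons are only evaluated when the omnibus
    one-way ANOVA across all ``k`` levels rejects at ``alpha``; the
    Tukey critical value uses the studentized range for ``k`` groups so
    the family-wise error over the comparisons is controlled.
    """
    samples = [np.asarray(s, dtype=float).ravel() for s in samples]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two levels")
    out = np.zeros(k - 1, dtype=int)
    means, ns, mse, df = _pooled(samples)
    if mse == 0.0:
        # all-identical data within levels: any mean difference is exact
        diff = np.delete(means, control) - means[control]
        return np.sign(diff).astype(int)
    _, p = stats.f_oneway(*samples)
    if not np.isfinite(p) or p >= alpha:
        return out
    qcrit = stats.studentized_range.ppf(1.0 - alpha, k, df)
    idx = [i for i in range(k) if i != control]
    for j, i in enumerate(idx):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[control]))
        q = abs(means[i] - means[control]) / se
        if q > qcrit:
            out[j] = 1 if means[i] > means[control] else -1
    return out


def tukey_all_pairs(
    samples: list[np.ndarray], alpha: float = 0.05
) -> list[tuple[int, int, float, bool]]:
    """All-pairs Tukey-Kramer comparisons: (i, j, mean_i - mean_j, significant)."""
    samples = [np.asarray(s, dtype=float).ravel() for s in samples]
    k = len(samples)
    means, ns, mse, df = _pooled(samples)
    qcrit = stats.studentized_range.ppf(1.0 - alpha, k, df)
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if mse == 0.0:
                sig = diff != 0.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                sig = abs(diff) / se > qcrit
            results.append((i, j, float(diff), bool(sig)))
    return results
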