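"""Time-gated neuron-group classification from trinary significance patterns.

For each neuron and each ZT, the 18 light bins are compared to the
-5..0 s baseline bin across the nine trials at that ZT (one-way ANOVA
over 19 bins with Tukey post hoc), producing a trinary code per bin:
+1 significantly above baseline, -1 below, 0 unchanged.  Concatenated
over (ZT 16, ZT 22, ZT 8) this gives a length-54 significance pattern.
k-means (k = 3) on these patterns separates:

* group 1 — persistent positive light response at ZT 16,
* group 2 — consistent inhibition at ZT 22,
* group 3 — the stochastic majority with no consistent response.

Haar features compress each ZT's 18-bin trinary series (zero-padded to
32) through the orthonormal Haar wavelet transform; the leading
coefficients carry the dominant polarity trends.  The 50-75 s response
AUC provides an independent scalar contrast between the groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from sklearn.cluster import KMeans

from ._stats import anova_tukey_vs_control, tukey_all_pairs
from .clustering import N_BASELINE_BINS, N_LIGHT_BINS

__all__ = [
    "ZT_ORDER",
    "SignificancePattern",
    "GroupAssignment",
    "HaarFeatures",
    "significance_pattern",
    "classify_groups",
    "haar_features",
    "haar_inverse",
    "response_auc",
    "group_composition",
]

ZT_ORDER: tuple[int, int, int] = (16, 22, 8)
PATTERN_LEN = len(ZT_ORDER) * N_LIGHT_BINS  # 54
_HAAR_PAD = 32
ACTIVATION_CLUSTERS = (1, 2, 3, 4)  # C1-4 counted as activation-side
INHIBITION_CLUSTERS = (5, 6)  # C5-6 counted as consistent inhibition


@dataclass
class SignificancePattern:
    """Length-54 trinary vector over (ZT 16, ZT 22, ZT 8) x 18 bins."""

    values: np.ndarray
    alpha: float = 0.05
    incomplete: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (PATTERN_LEN,):
            raise ValueError(f"pattern must have length {PATTERN_LEN}")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("pattern entries must be in {-1, 0, +1}")

    def block(self, zt: int) -> np.ndarray:
        i = ZT_ORDER.index(zt)
        return self.values[i * N_LIGHT_BINS : (i + 1) * N_LIGHT_BINS]


@dataclass
class GroupAssignment:
    group: int  # 1, 2 or 3
    centroid_scores: dict[int, float]  # per-ZT summed block of own centroid


@dataclass
class HaarFeatures:
    coefficients: np.ndarray  # full length-32 orthonormal Haar coefficients
    kept: np.ndarray
    kept_coefficients: int


def significance_pattern(
    trial_bins_by_zt: dict[int, np.ndarray], alpha: float = 0.05
) -> SignificancePattern:
    """Trinary per-bin light-response code for one neuron.

    ``trial_bins_by_zt`` maps each ZT to that neuron's (n_trials, 24)
    binned responses.  Per ZT the samples are per-trial bin means; a
    one-way ANOVA over 19 levels (baseline bin plus 18 light bins) with
    Tukey post hoc marks each light bin +1/-1/0 against baseline.  A
    missing ZT (or fewer than 3 trials) leaves its block at zero and
    flags the pattern incomplete.
    """
    values = np.zeros(PATTERN_LEN, dtype=int)
    incomplete = False
    for i, zt in enumerate(ZT_ORDER):
        bins = trial_bins_by_zt.get(zt)
        if bins is None or np.asarray(bins).shape[0] < 3:
            incomplete = True
            continue
        bins = np.asarray(bins, dtype=float)
        base = bins[:, N_BASELINE_BINS - 1]
        samples = [base] + [bins[:, N_BASELINE_BINS + b] for b in range(N_LIGHT_BINS)]
        values[i * N_LIGHT_BINS : (i + 1) * N_LIGHT_BINS] = anova_tukey_vs_control(
            samples, control=0, alpha=alpha
        )
    if incomplete:
        warnings.warn("missing trials: incomplete significance pattern")
    return SignificancePattern(values, alpha, incomplete)


def classify_groups(
    patterns: list[SignificancePattern] | np.ndarray, k: int = 3, seed: int = 0
) -> tuple[np.ndarray, list[GroupAssignment]]:
    """k-means the 54-bin trinary patterns into the three semantic groups.

    The centroid with the largest summed ZT-16 block becomes group 1
    (ZT-16 activated); of the rest, the centroid with the smallest
    summed ZT-22 block becomes group 2 (ZT-22 inhibited); all remaining
    centroids map to group 3.  The mapping is invariant to k-means label
    permutation.  Degenerate all-equal patterns go to group 3, flagged.
    """
    if isinstance(patterns, np.ndarray):
        X = np.asarray(patterns, dtype=float)
    else:
        X = np.stack([p.values for p in patterns]).astype(float)
    if X.ndim != 2 or X.shape[1] != PATTERN_LEN:
        raise ValueError(f"patterns must be (n, {PATTERN_LEN})")
    if X.shape[0] < k:
        raise ValueError("fewer neurons than clusters")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct == 1:
        warnings.warn("all patterns identical; assigning every neuron to group 3")
        scores = {zt: 0.0 for zt in ZT_ORDER}
        return (
            np.full(X.shape[0], 3, dtype=int),
            [GroupAssignment(3, scores) for _ in range(X.shape[0])],
        )
    k_eff = min(k, n_distinct)
    km = KMeans(n_clusters=k_eff, init="k-means++", n_init=25, random_state=seed)
    raw = km.fit_predict(X)

    def block_sum(centroid: np.ndarray, zt: int) -> float:
        i = ZT_ORDER.index(zt)
        return float(centroid[i * N_LIGHT_BINS : (i + 1) * N_LIGHT_BINS].sum())

    centroids = km.cluster_centers_
    mapping: dict[int, int] = {}
    group1 = int(np.argmax([block_sum(c, 16) for c in centroids]))
    mapping[group1] = 1
    rest = [i for i in range(k_eff) if i != group1]
    if rest:
        group2 = min(rest, key=lambda i: block_sum(centroids[i], 22))
        mapping[group2] = 2
    for i in range(k_eff):
        mapping.setdefault(i, 3)

    groups = np.array([mapping[r] for r in raw])
    assignments = [
        GroupAssignment(
            int(mapping[r]),
            {zt: block_sum(centroids[r], zt) for zt in ZT_ORDER},
        )
        for r in raw
    ]
    return groups, assignments


def haar_features(series: np.ndarray, kept_coefficients: int = 8) -> HaarFeatures:
    """Orthonormal Haar transform of one 18-bin trinary series.

    The series is zero-padded to 32 (power of two), decomposed with the
    orthonormal Haar wavelet to full depth, and the coefficients are
    ordered coarse-to-fine (approximation first).  The leading
    ``kept_coefficients`` (default 8) serve as the feature vector; the
    full coefficient set reconstructs the padded input exactly.
    """
    s = np.asarray(series, dtype=float)
    if s.shape != (N_LIGHT_BINS,):
        raise ValueError(f"series must have length {N_LIGHT_BINS}")
    if not np.isin(s, (-1.0, 0.0, 1.0)).all():
        raise ValueError("series entries must be in {-1, 0, +1}")
    padded = np.zeros(_HAAR_PAD)
    padded[: s.size] = s
    levels = pywt.wavedec(padded, "haar", level=5)
    coeffs = np.concatenate(levels)
    return HaarFeatures(coeffs, coeffs[:kept_coefficients], kept_coefficients)


def haar_inverse(coefficients: np.ndarray) -> np.ndarray:
    """Invert a full length-32 coefficient vector back to the padded series."""
    c = np.asarray(coefficients, dtype=float)
    if c.shape != (_HAAR_PAD,):
        raise ValueError(f"need the full {_HAAR_PAD} coefficients")
    sizes = [1, 1, 2, 4, 8, 16]
    levels, pos = [], 0
    for n in sizes:
        levels.append(c[pos : pos + n])
        pos += n
    return pywt.waverec(levels, "haar")


def response_auc(
    z: np.ndarray,
    frame_rate: float = 23.0,
    window: tuple[float, float] = (50.0, 75.0),
    baseline_s: float = 30.0,
) -> float:
    """Signed trapezoidal AUC (z·s) of a normalized trace over a window
    given in seconds from light onset (default 50-75 s, where the light
    response has stabilized)."""
    z = np.asarray(z, dtype=float)
    t = np.arange(z.size) / frame_rate - baseline_s
    lo, hi = window
    if lo < t[0] or hi > t[-1]:
        raise ValueError("window outside recording")
    sel = (t >= lo) & (t <= hi)
    return float(np.trapezoid(z[sel], t[sel]))


def group_composition(
    labels: pd.DataFrame, groups: np.ndarray, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group activation/inhibition cluster fractions with tests.

    ``labels`` needs columns ``neuron_id``, ``zt`` and ``label`` (the
    semantic cluster 1..7 per trial); ``groups`` is the group (1..3) per
    neuron id.  For each group x ZT the fraction of trials falling in
    the activation clusters (C1-4) and the consistent-inhibition
    clusters (C5-6) is computed per neuron, and groups are compared per
    ZT with a one-way ANOVA plus Tukey post hoc on the per-neuron
    fractions.  Returns ``(fractions, tests)`` DataFrames.  Empty groups
    are omitted with a warning.
    """
    groups = np.asarray(groups)
    df = labels.copy()
    df["group"] = groups[df["neuron_id"].to_numpy()]
    df["is_act"] = df["label"].isin(ACTIVATION_CLUSTERS)
    df["is_inh"] = df["label"].isin(INHIBITION_CLUSTERS)
    per_neuron = (
        df.groupby(["group", "zt", "neuron_id"])[["is_act", "is_inh"]]
        .mean()
        .rename(columns={"is_act": "activation_frac", "is_inh": "inhibition_frac"})
        .reset_index()
    )
    fractions = (
        per_neuron.groupby(["group", "zt"])[["activation_frac", "inhibition_frac"]]
        .mean()
        .reset_index()
    )
    present = sorted(per_neuron["group"].unique())
    for g in (1, 2, 3):
        if g not in present:
            warnings.warn(f"group {g} empty; omitted from composition tests")
    rows = []
    for zt in sorted(per_neuron["zt"].unique()):
        for col in ("activation_frac", "inhibition_frac"):
            samples = [
                per_neuron.loc[
                    (per_neuron["group"] == g) & (per_neuron["zt"] == zt), col
                ].to_numpy()
                for g in present
            ]
            samples = [s for s in samples if s.size > 0]
            if len(samples) < 2 or any(s.size < 2 for s in samples):
                continue
            for i, j, diff, sig in tukey_all_pairs(samples, alpha=alpha):
                rows.append(
                    {
                        "zt": zt,
                        "measure": col,
                        "group_a": present[i],
                        "group_b": present[j],
                        "mean_diff": diff,
                        "significant": sig,
                    }
                )
    return fractions, pd.DataFrame(rows)
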