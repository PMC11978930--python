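"""Single-trial light-response clustering.

Normalized traces are averaged in 5-s bins (6 baseline bins over
-30..0 s, 18 light bins over 0..90 s).  PCA is run on the 18 light bins
of every trial, k-means (k = 7) partitions the trials in PC space, and
the resulting clusters are named semantically from their back-projected
mean waveforms: activations and inhibitions split by polarity, ordered
transient < sustained < delayed by time-to-half-extremum, with the
smallest-amplitude cluster labelled the marginal response.  Per-cluster
significance versus the -5..0 s baseline bin is assessed with a one-way
ANOVA plus Tukey post hoc per bin, and per-neuron response diversity is
the number of distinct cluster labels across a neuron's 27 trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._stats import anova_tukey_vs_control
from .preprocess import NormalizedTrace
from .synthetic import ARCHETYPE_NAMES

__all__ = [
    "BinnedResponse",
    "ResponseClusterModel",
    "bin_trace",
    "bin_matrix",
    "fit_cluster_model",
    "assign_clusters",
    "cluster_significance",
    "response_diversity",
]

BIN_S = 5.0
N_BASELINE_BINS = 6
N_LIGHT_BINS = 18
N_BINS = N_BASELINE_BINS + N_LIGHT_BINS


@dataclass
class BinnedResponse:
    """Mean z per contiguous half-open 5-s bin; 24 bins spanning -30..90 s."""

    bins: np.ndarray
    n_baseline_bins: int = N_BASELINE_BINS
    n_light_bins: int = N_LIGHT_BINS

    @property
    def light_bins(self) -> np.ndarray:
        return self.bins[self.n_baseline_bins :]

    @property
    def baseline_bin(self) -> float:
        """The -5..0 s bin used as the significance reference."""
        return float(self.bins[self.n_baseline_bins - 1])


def bin_trace(normalized: NormalizedTrace | np.ndarray, frame_rate: float = 23.0) -> BinnedResponse:
    """Average a normalized trace into 5-s bins.

    Bins are half-open ``[start, end)`` in seconds from light onset
    (115 frames each at 23 Hz); the last bin absorbs any remainder
    frames.
    """
    z = normalized.z if isinstance(normalized, NormalizedTrace) else np.asarray(normalized, float)
    if isinstance(normalized, NormalizedTrace):
        frame_rate = normalized.frame_rate
    per_bin = int(round(frame_rate * BIN_S))
    if z.size < per_bin:
        raise ValueError("trace shorter than one bin")
    edges = [min(b * per_bin, z.size) for b in range(N_BINS)] + [z.size]
    bins = np.array([z[edges[b] : edges[b + 1]].mean() for b in range(N_BINS)])
    return BinnedResponse(bins)


def bin_matrix(z_matrix: np.ndarray, frame_rate: float = 23.0) -> np.ndarray:
    """Vectorized ``bin_trace`` over rows; returns (n, 24)."""
    z_matrix = np.asarray(z_matrix, dtype=float)
    per_bin = int(round(frame_rate * BIN_S))
    usable = per_bin * N_BINS
    head = z_matrix[:, :usable].reshape(z_matrix.shape[0], N_BINS, per_bin).mean(axis=2)
    if z_matrix.shape[1] > usable:  # remainder frames fold into the last bin
        tail = z_matrix[:, (N_BINS - 1) * per_bin :].mean(axis=1)
        head[:, -1] = tail
    return head


@dataclass
class ResponseClusterModel:
    """Fitted PCA + k-means model over single-trial light responses."""

    pca: PCA
    kmeans: KMeans
    semantic_map: dict[int, int]  # raw k-means label -> semantic cluster 1..7
    seed: int
    degenerate: bool = False

    @property
    def cluster_names(self) -> dict[int, str]:
        return {c: ARCHETYPE_NAMES[c] for c in sorted(self.semantic_map.values())}

    def centroid_waveforms(self) -> dict[int, np.ndarray]:
        """Back-projected 18-bin mean waveform per semantic cluster."""
        back = self.pca.inverse_transform(self.kmeans.cluster_centers_)
        return {self.semantic_map[i]: back[i] for i in range(back.shape[0])}


def _time_to_half_extremum(waveform: np.ndarray, polarity: int) -> float:
    """First bin time (s, bin centres) where the waveform reaches half
    its extremum *in the polarity direction*.

    Restricting to the polarity direction keeps the timing estimate
    robust to the small opposite-sign tilt that exponential detrending
    imprints on late-onset responses.
    """
    w = np.asarray(waveform) * polarity
    peak = w.max()
    if peak <= 0:
        return np.inf
    idx = int(np.argmax(w >= 0.5 * peak))
    return (idx + 0.5) * BIN_S


def _semantic_map(back_projected: np.ndarray) -> dict[int, int]:
    """Name k-means centroids by polarity and timing.

    The smallest-amplitude centroid is the marginal response (4).
    The rest split into activations and inhibitions by the sign of the
    waveform at its absolute extremum — the overall mean would misread
    transient responses, whose late window sits near zero by shape.
    Within a polarity, sorting by time to half the polarity-direction
    extremum orders transient < sustained < delayed, filling slots
    1, 2, 3 (or 7, 6, 5 mirrored).  If the polarity split is uneven the
    overflow takes the remaining slots in timing order so the map is
    always a bijection.
    """
    k = back_projected.shape[0]
    extreme = back_projected[
        np.arange(k), np.abs(back_projected).argmax(axis=1)
    ]
    order: dict[int, int] = {}
    remaining = list(range(k))
    if k == 7:
        marginal = int(np.argmin(np.abs(back_projected).max(axis=1)))
        order[marginal] = 4
        remaining.remove(marginal)
    def _order(idxs: list[int], polarity: int) -> list[int]:
        """[transient, sustained, delayed] for one polarity.

        The delayed response is the one reaching half-extremum last; at
        5-s binning both transient and sustained cross it in the first
        bin, so the remaining pair is split by persistence — the ratio
        of the late-window mean to the peak (transient returns toward
        baseline, sustained does not)."""
        idxs = sorted(
            idxs, key=lambda i: _time_to_half_extremum(back_projected[i], polarity)
        )
        if len(idxs) != 3:
            return idxs
        early, delayed = idxs[:2], idxs[2]

        def persistence(i: int) -> float:
            w = back_projected[i] * polarity
            peak = w.max()
            return w[N_LIGHT_BINS // 2 :].mean() / peak if peak > 0 else 0.0

        early.sort(key=persistence)
        return [early[0], early[1], delayed]

    pos = _order([i for i in remaining if extreme[i] >= 0], +1)
    neg = _order([i for i in remaining if extreme[i] < 0], -1)
    pos_slots = [1, 2, 3]
    neg_slots = [7, 6, 5]
    for i in pos[:3]:
        order[i] = pos_slots.pop(0)
    for i in neg[:3]:
        order[i] = neg_slots.pop(0)
    leftovers = pos[3:] + neg[3:]
    free = sorted(set(range(1, 8)) - set(order.values()))
    for i, slot in zip(leftovers, free):
        order[i] = slot
        warnings.warn("uneven polarity split: cluster naming is approximate")
    return order


def fit_cluster_model(
    light_responses: np.ndarray,
    k: int = 7,
    variance_kept: float = 0.90,
    seed: int = 0,
    n_init: int = 25,
) -> ResponseClusterModel:
    """PCA + k-means over (n_trials, 18) binned light responses.

    PCA keeps the leading components explaining ``variance_kept`` of the
    variance; k-means uses k-means++ with ``n_init`` restarts at a fixed
    seed.  If the data contain fewer distinct responses than ``k`` the
    model degrades to the number of distinct rows and is flagged.
    """
    X = np.asarray(light_responses, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_LIGHT_BINS:
        raise ValueError(f"expected (n, {N_LIGHT_BINS}) light-bin matrix")
    if X.shape[0] < k:
        raise ValueError("fewer responses than clusters")
    degenerate = False
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct responses; fitting {n_distinct} clusters"
        )
        k = n_distinct
        degenerate = True
    n_comp = min(variance_kept if 0 < variance_kept < 1 else int(variance_kept), X.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(X)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    km.fit(scores)
    back = pca.inverse_transform(km.cluster_centers_)
    if k == 7:
        mapping = _semantic_map(back)
    else:
        mapping = {i: i + 1 for i in range(k)}
    return ResponseClusterModel(pca, km, mapping, seed, degenerate)


def assign_clusters(model: ResponseClusterModel, light_responses: np.ndarray) -> np.ndarray:
    """Nearest-centroid semantic labels (1..7) in PC space; deterministic."""
    X = np.asarray(light_responses, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.pca.n_features_in_:
        raise ValueError("dimensionality mismatch with fitted model")
    raw = model.kmeans.predict(model.pca.transform(X))
    return np.array([model.semantic_map[r] for r in raw])


def cluster_significance(
    binned: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> dict[int, np.ndarray]:
    """Per-cluster, per-light-bin significance stars versus baseline.

    For each cluster, each of the 18 light bins is compared to the
    -5..0 s baseline bin across the cluster's member trials (one-way
    ANOVA over the 19 bins, Tukey post hoc).  Returns a length-18
    trinary array per cluster: +1 = significantly above baseline
    (star above), -1 = below, 0 = n.s.  Single-member clusters are
    skipped with a warning.
    """
    binned = np.asarray(binned, dtype=float)
    labels = np.asarray(labels)
    out: dict[int, np.ndarray] = {}
    for c in np.unique(labels):
        members = binned[labels == c]
        if members.shape[0] < 2:
            warnings.warn(f"cluster {c} has a single member; significance skipped")
            continue
        base = members[:, N_BASELINE_BINS - 1]
        samples = [base] + [members[:, N_BASELINE_BINS + b] for b in range(N_LIGHT_BINS)]
        out[int(c)] = anova_tukey_vs_control(samples, control=0, alpha=alpha)
    return out


def response_diversity(labels: pd.DataFrame | np.ndarray, neuron_ids: np.ndarray | None = None):
    """Distinct response types per neuron plus the cohort mean ± SD.

    Accepts either a DataFrame with ``neuron_id`` and ``label`` columns
    or a label array plus a parallel ``neuron_ids`` array.  Returns
    ``(per_neuron: Series, mean, sd)`` with the sample SD.
    """
    if isinstance(labels, pd.DataFrame):
        df = labels[["neuron_id", "label"]]
    else:
        if neuron_ids is None:
            raise ValueError("neuron_ids required when labels is an array")
        df = pd.DataFrame({"neuron_id": np.asarray(neuron_ids), "label": np.asarray(labels)})
    per_neuron = df.groupby("neuron_id")["label"].nunique()
    mean = float(per_neuron.mean())
    sd = float(per_neuron.std(ddof=1)) if per_neuron.size > 1 else 0.0
    return per_neuron, mean, sd
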