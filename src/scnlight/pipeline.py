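"""End-to-end helpers chaining preprocessing with the analysis stages.

These wrappers operate on a whole cohort (synthetic or loaded from a
trace table) and return tidy arrays/DataFrames, so each analysis module
can stay focused on a single operation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clustering, groups
from .preprocess import evaluate_decay, fit_baseline_trend, normalize_trace
from .synthetic import SyntheticCohort

__all__ = [
    "normalize_cohort",
    "label_cohort",
    "pattern_matrix",
]


def normalize_cohort(cohort: SyntheticCohort, do_detrend: bool = True) -> np.ndarray:
    """Detrend + Z-normalize every trace; returns (n_traces, n_frames).

    Photobleaching is a property of the preparation, not of a single
    trial, so the bleaching trend is fitted per *neuron* on the mean of
    that neuron's dark-baseline windows across all its trials.
    Averaging the response-free baselines cancels trial-specific noise
    (spontaneous transients, within-trial synchrony) before the slope
    is extrapolated over the light window, which a single 30-s baseline
    cannot do.  The fitted decay is then subtracted from each of the
    neuron's trials and each trial is Z-normalized.
    """
    cfg = cohort.config
    fr = cfg.frame_rate
    n_base = int(round(fr * cfg.baseline_s))
    values = cohort.values
    out = np.empty_like(values)
    neuron_ids = np.array([tr.neuron_id for tr in cohort.traces])
    t = np.arange(values.shape[1]) / fr
    for neuron in np.unique(neuron_ids):
        idx = np.flatnonzero(neuron_ids == neuron)
        if do_detrend:
            mean_baseline = values[idx, :n_base].mean(axis=0)
            trend = fit_baseline_trend(mean_baseline, fr)
            decay = evaluate_decay(trend, t)
        else:
            decay = 0.0
        for i in idx:
            out[i] = normalize_trace(values[i] - decay, fr, cfg.baseline_s).z
    return out


def label_cohort(
    cohort: SyntheticCohort,
    z_matrix: np.ndarray | None = None,
    k: int = 7,
    seed: int = 0,
) -> tuple[pd.DataFrame, clustering.ResponseClusterModel, np.ndarray]:
    """Cluster every trial of a cohort into the 7 semantic responses.

    Returns ``(labels_df, model, binned)`` where ``labels_df`` carries
    neuron_id / zt / day / trial / label and ``binned`` is the (n, 24)
    bin matrix aligned with the cohort's traces.
    """
    if z_matrix is None:
        z_matrix = normalize_cohort(cohort)
    binned = clustering.bin_matrix(z_matrix, cohort.config.frame_rate)
    light = binned[:, clustering.N_BASELINE_BINS :]
    model = clustering.fit_cluster_model(light, k=k, seed=seed)
    labels = clustering.assign_clusters(model, light)
    df = cohort.meta()
    df["label"] = labels
    return df, model, binned


def pattern_matrix(
    cohort: SyntheticCohort, binned: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Per-neuron length-54 trinary significance patterns, (n_neurons, 54)."""
    meta = cohort.meta()
    patterns = []
    for neuron in range(cohort.config.n_neurons):
        by_zt = {}
        for zt in groups.ZT_ORDER:
            idx = meta.index[(meta["neuron_id"] == neuron) & (meta["zt"] == zt)]
            if len(idx):
                by_zt[zt] = binned[np.asarray(idx)]
        patterns.append(groups.significance_pattern(by_zt, alpha=alpha).values)
    return np.stack(patterns)
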