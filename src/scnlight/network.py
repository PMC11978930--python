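"""Pairwise-correlation structure of light-window responses.

All correlations are Pearson r between normalized (detrended,
Z-scored) traces restricted to the 90-s light window.  Three contrasts
are provided:

* **R-same vs R-cross** — between-neuron correlation within a single
  trial versus same-neuron correlation across trials at different ZTs.
  A time-stable network predicts high R-cross; a dynamic one predicts
  R-cross near zero with R-same elevated by within-trial synchrony.
* **VIP in/out-group contrasts** — distributions of r for VIP-/VIP-,
  VIP+/VIP- and VIP+/VIP+ pairs within the same trial, compared per ZT
  with ANOVA/Tukey on Fisher-z values (raw r is reported).
* **Connectivity maps and distance regression** — edges where the mean
  r over the nine repeats of a ZT exceeds a threshold (default 0.5),
  and an OLS regression of pairwise r on inter-neuronal distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import tukey_all_pairs

__all__ = [
    "CorrelationSet",
    "ConnectivityGraph",
    "light_window_slice",
    "pairwise_correlation",
    "r_same_vs_r_cross",
    "vip_group_correlation",
    "connectivity_graph",
    "regress_r_on_distance",
    "distance_correlation_regression",
]


def light_window_slice(
    n_frames: int, frame_rate: float = 23.0, baseline_s: float = 30.0,
    window: tuple[float, float] = (0.0, 90.0),
) -> slice:
    """Frame slice for a window given in seconds from light onset."""
    lo = int(round((window[0] + baseline_s) * frame_rate))
    hi = int(round((window[1] + baseline_s) * frame_rate))
    return slice(max(lo, 0), min(hi, n_frames))


@dataclass
class CorrelationSet:
    """Pairwise Pearson r values with their pairing context.

    ``entries`` has columns i, j (trace indices), neuron_i, neuron_j,
    zt/day/trial context and ``r``; ``kind`` states how pairs were
    formed.
    """

    entries: pd.DataFrame
    kind: str
    n_omitted: int = 0

    @property
    def r(self) -> np.ndarray:
        return self.entries["r"].to_numpy()


@dataclass
class ConnectivityGraph:
    """Thresholded functional-connectivity graph for one ZT."""

    zt: int
    nodes: pd.DataFrame  # neuron_id, x, y
    edges: pd.DataFrame  # neuron_i, neuron_j, mean_r
    threshold: float


def _corr_matrix(z_window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix across rows; flags zero-variance rows."""
    sd = z_window.std(axis=1)
    ok = sd > 0
    r = np.full((z_window.shape[0],) * 2, np.nan)
    if ok.sum() >= 2:
        r_ok = np.corrcoef(z_window[ok])
        r[np.ix_(ok, ok)] = r_ok
    return r, ok


def pairwise_correlation(
    z_matrix: np.ndarray,
    meta: pd.DataFrame,
    window: tuple[float, float] = (0.0, 90.0),
    frame_rate: float = 23.0,
) -> CorrelationSet:
    """Between-neuron Pearson r within each trial, over the light window.

    ``meta`` needs columns neuron_id, zt, day, trial aligned with the
    rows of ``z_matrix``.  Zero-variance traces are omitted (counted in
    ``n_omitted``).
    """
    z_matrix = np.asarray(z_matrix, dtype=float)
    if z_matrix.shape[0] < 2:
        raise ValueError("need at least two traces")
    sl = light_window_slice(z_matrix.shape[1], frame_rate, window=window)
    rows, omitted = [], 0
    for (zt, day, trial), idx in meta.groupby(["zt", "day", "trial"]).groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            continue
        r, ok = _corr_matrix(z_matrix[idx][:, sl])
        omitted += int((~ok).sum())
        nid = meta["neuron_id"].to_numpy()[idx]
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                if np.isnan(r[a, b]):
                    continue
                rows.append((idx[a], idx[b], nid[a], nid[b], zt, day, trial, r[a, b]))
    if omitted:
        warnings.warn(f"{omitted} zero-variance traces omitted from correlations")
    entries = pd.DataFrame(
        rows, columns=["i", "j", "neuron_i", "neuron_j", "zt", "day", "trial", "r"]
    )
    return CorrelationSet(entries, "same_trial_between_neurons", omitted)


def r_same_vs_r_cross(
    z_matrix: np.ndarray,
    meta: pd.DataFrame,
    frame_rate: float = 23.0,
) -> dict:
    """R-same (between neurons, same trial) vs R-cross (same neuron,
    trials at different ZTs), both over the light window.

    Returns the two r distributions, their medians, and a Welch t-test
    on Fisher-z values as the two-group comparison.
    """
    same = pairwise_correlation(z_matrix, meta, frame_rate=frame_rate).r
    sl = light_window_slice(z_matrix.shape[1], frame_rate)
    cross = []
    nid = meta["neuron_id"].to_numpy()
    zt = meta["zt"].to_numpy()
    for neuron in np.unique(nid):
        idx = np.flatnonzero(nid == neuron)
        if idx.size < 2:
            continue
        r, ok = _corr_matrix(z_matrix[idx][:, sl])
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                if zt[idx[a]] != zt[idx[b]] and not np.isnan(r[a, b]):
                    cross.append(r[a, b])
    if same.size == 0:
        raise ValueError("R-same undefined: need at least two neurons")
    cross = np.asarray(cross)
    zs = np.arctanh(np.clip(same, -0.999999, 0.999999))
    zc = np.arctanh(np.clip(cross, -0.999999, 0.999999))
    if np.ptp(zs) == 0 and np.ptp(zc) == 0 and zs.mean() == zc.mean():
        t, p = 0.0, 1.0  # fully degenerate (e.g. all traces identical)
    else:
        t, p = stats.ttest_ind(zs, zc, equal_var=False)
    return {
        "r_same": same,
        "r_cross": cross,
        "median_same": float(np.median(same)),
        "median_cross": float(np.median(cross)) if cross.size else np.nan,
        "t": float(t),
        "p": float(p),
    }


def vip_group_correlation(
    corr: CorrelationSet, vip_labels: np.ndarray, alpha: float = 0.05
) -> dict:
    """VIP-/VIP-, VIP+/VIP- and VIP+/VIP+ same-trial r distributions
    per ZT, with ANOVA/Tukey on Fisher-z values."""
    vip_labels = np.asarray(vip_labels, dtype=bool)
    df = corr.entries.copy()
    vi = vip_labels[df["neuron_i"].to_numpy()]
    vj = vip_labels[df["neuron_j"].to_numpy()]
    df["pair"] = np.where(vi & vj, "pp", np.where(vi ^ vj, "pm", "mm"))
    out: dict = {}
    for zt, sub in df.groupby("zt"):
        dists = {p: sub.loc[sub["pair"] == p, "r"].to_numpy() for p in ("mm", "pm", "pp")}
        if any(v.size == 0 for v in dists.values()):
            warnings.warn(f"ZT {zt}: a VIP pair class is empty; comparison skipped")
            out[zt] = {"distributions": dists, "tests": None}
            continue
        fz = [np.arctanh(np.clip(v, -0.999999, 0.999999)) for v in dists.values()]
        try:
            _, p_omni = stats.f_oneway(*fz)
        except Exception:
            p_omni = np.nan
        pairs = tukey_all_pairs(fz, alpha=alpha)
        names = list(dists)
        tests = [
            {"a": names[i], "b": names[j], "mean_diff_z": d, "significant": s}
            for i, j, d, s in pairs
        ]
        out[zt] = {"distributions": dists, "p_omnibus": float(p_omni), "tests": tests}
    return out


def connectivity_graph(
    z_matrix: np.ndarray,
    meta: pd.DataFrame,
    coordinates: np.ndarray,
    threshold: float = 0.5,
    frame_rate: float = 23.0,
    expected_repeats: int = 9,
) -> dict[int, ConnectivityGraph]:
    """Per-ZT graphs with edges where mean r over the repeats > threshold.

    The nine repeats of a ZT are its 3 days x 3 trials; each repeat
    contributes one between-neuron r and the edge criterion uses the
    mean across repeats.  Pairs with missing repeats use the mean over
    the available ones, with a warning.
    """
    corr = pairwise_correlation(z_matrix, meta, frame_rate=frame_rate)
    coordinates = np.asarray(coordinates, dtype=float)
    graphs: dict[int, ConnectivityGraph] = {}
    for zt, sub in corr.entries.groupby("zt"):
        agg = sub.groupby(["neuron_i", "neuron_j"])["r"].agg(["mean", "count"]).reset_index()
        if (agg["count"] < expected_repeats).any():
            warnings.warn(f"ZT {zt}: some pairs have fewer than {expected_repeats} repeats")
        edges = agg.loc[agg["mean"] > threshold, ["neuron_i", "neuron_j", "mean"]]
        edges = edges.rename(columns={"mean": "mean_r"}).reset_index(drop=True)
        neurons = np.unique(sub[["neuron_i", "neuron_j"]].to_numpy())
        nodes = pd.DataFrame(
            {
                "neuron_id": neurons,
                "x": coordinates[neurons, 0],
                "y": coordinates[neurons, 1],
            }
        )
        graphs[int(zt)] = ConnectivityGraph(int(zt), nodes, edges, threshold)
    return graphs


def regress_r_on_distance(r: np.ndarray, distances: np.ndarray) -> dict:
    """OLS of pairwise correlation on inter-neuronal distance (µm).

    Returns slope (per µm), intercept, r² and the slope's standard
    error.  Raises on degenerate all-equal distances.
    """
    r = np.asarray(r, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if np.ptp(distances) == 0:
        raise ValueError("all pairs at identical distance; slope undefined")
    res = stats.linregress(distances, r)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "stderr": float(res.stderr),
    }


def distance_correlation_regression(
    z_matrix: np.ndarray,
    meta: pd.DataFrame,
    coordinates: np.ndarray,
    frame_rate: float = 23.0,
    um_per_px: float = 1.0,
) -> pd.DataFrame:
    """OLS of pairwise mean r on inter-neuronal distance, per ZT.

    Correlations are the per-pair mean over a ZT's repeats; distance is
    the Euclidean separation of the ROI centroids in µm.  Returns slope
    (per µm), intercept and r² per ZT plus their across-ZT mean row.
    """
    corr = pairwise_correlation(z_matrix, meta, frame_rate=frame_rate)
    coordinates = np.asarray(coordinates, dtype=float) * um_per_px
    rows = []
    for zt, sub in corr.entries.groupby("zt"):
        agg = sub.groupby(["neuron_i", "neuron_j"])["r"].mean().reset_index()
        d = np.linalg.norm(
            coordinates[agg["neuron_i"].to_numpy()] - coordinates[agg["neuron_j"].to_numpy()],
            axis=1,
        )
        if np.ptp(d) == 0:
            warnings.warn(f"ZT {zt}: all pairs at identical distance; slope undefined")
            rows.append({"zt": zt, "slope": np.nan, "intercept": np.nan, "r2": np.nan})
            continue
        res = regress_r_on_distance(agg["r"].to_numpy(), d)
        rows.append({"zt": zt, **{k: res[k] for k in ("slope", "intercept", "r2")}})
    out = pd.DataFrame(rows)
    mean_row = {"zt": "mean", "slope": out["slope"].mean(), "intercept": out["intercept"].mean(), "r2": out["r2"].mean()}
    return pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)
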