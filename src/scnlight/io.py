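"""Delimited-text and TIFF I/O for traces, cohorts, stacks and actograms.

Trace tables are long-format CSV (one row per frame per ROI) with the
trial metadata repeated per row, matching how bench acquisition
software commonly exports ROI traces.  Ground truth for synthetic
cohorts travels in a JSON sidecar.  Image stacks and labelled ROI masks
use multi-page / single-page TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .preprocess import TraceRecording
from .synthetic import ActogramRecord, CohortConfig, SyntheticCohort

__all__ = [
    "write_traces",
    "read_traces",
    "write_cohort",
    "read_cohort",
    "write_actogram",
    "read_actogram",
    "write_stack",
    "read_stack",
    "load_cohort_config",
]

_META_COLS = ["neuron_id", "zt", "day", "trial", "z_plane", "vip", "x_um", "y_um"]


def write_traces(traces: list[TraceRecording], path: str | Path) -> None:
    """Write recordings as a long-format CSV trace table."""
    frames = []
    for tr in traces:
        df = pd.DataFrame({"frame": np.arange(tr.values.size), "value": tr.values})
        df["neuron_id"] = tr.neuron_id
        df["zt"] = tr.zt
        df["day"] = tr.day
        df["trial"] = tr.trial
        df["z_plane"] = tr.z_plane
        df["vip"] = tr.vip
        df["x_um"], df["y_um"] = tr.centroid
        df["frame_rate"] = tr.frame_rate
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[TraceRecording]:
    df = pd.read_csv(path)
    traces = []
    for key, sub in df.groupby(["neuron_id", "zt", "day", "trial"], sort=True):
        sub = sub.sort_values("frame")
        traces.append(
            TraceRecording(
                neuron_id=int(key[0]),
                zt=int(key[1]),
                day=int(key[2]),
                trial=int(key[3]),
                values=sub["value"].to_numpy(),
                frame_rate=float(sub["frame_rate"].iloc[0]),
                z_plane=str(sub["z_plane"].iloc[0]),
                vip=bool(sub["vip"].iloc[0]),
                centroid=(float(sub["x_um"].iloc[0]), float(sub["y_um"].iloc[0])),
            )
        )
    return traces


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Trace table plus JSON ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_traces(cohort.traces, directory / "traces.csv")
    truth = {
        "config": dataclasses.asdict(cohort.config),
        "truth_groups": cohort.truth_groups.tolist(),
        "truth_trial_clusters": cohort.truth_trial_clusters.tolist(),
        "coordinates": cohort.coordinates.tolist(),
        "z_planes": cohort.z_planes.tolist(),
        "vip_labels": cohort.vip_labels.tolist(),
    }
    (directory / "truth.json").write_text(json.dumps(truth))


def read_cohort(directory: str | Path) -> SyntheticCohort:
    directory = Path(directory)
    truth = json.loads((directory / "truth.json").read_text())
    cfg_dict = truth["config"]
    for key in ("group_fractions", "zts", "cluster_mix"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = CohortConfig(**cfg_dict)
    return SyntheticCohort(
        config=cfg,
        traces=read_traces(directory / "traces.csv"),
        truth_groups=np.asarray(truth["truth_groups"]),
        truth_trial_clusters=np.asarray(truth["truth_trial_clusters"]),
        coordinates=np.asarray(truth["coordinates"]),
        z_planes=np.asarray(truth["z_planes"]),
        vip_labels=np.asarray(truth["vip_labels"], dtype=bool),
    )


def write_actogram(record: ActogramRecord, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "day": np.repeat(np.arange(record.n_days), 1440),
            "minute": np.tile(np.arange(1440), record.n_days),
            "count": record.counts,
        }
    )
    df.to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "n_days": record.n_days,
                "free_running_period": record.free_running_period,
                "injection_day": record.injection_day,
                "true_shift": record.true_shift,
            }
        )
    )


def read_actogram(path: str | Path) -> ActogramRecord:
    df = pd.read_csv(path).sort_values(["day", "minute"])
    sidecar = Path(path).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    n_days = int(meta.get("n_days", df["day"].nunique()))
    return ActogramRecord(
        counts=df["count"].to_numpy(),
        n_days=n_days,
        free_running_period=float(meta.get("free_running_period", 24.0) or 24.0),
        injection_day=meta.get("injection_day"),
        true_shift=meta.get("true_shift"),
    )


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(
        path, np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def load_cohort_config(path: str | Path) -> CohortConfig:
    """CohortConfig from a YAML or JSON mapping of field names."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    for key in ("group_fractions", "zts", "cluster_mix"):
        if key in data:
            data[key] = tuple(data[key])
    return CohortConfig(**data)
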