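"""Synthetic cohorts, image stacks and actograms with known ground truth.

The cohort generator emulates an awake two-photon SCN recording
paradigm: each trial is a 120-s series at 23 Hz — a 30-s dark baseline
followed by 90 s of blue light to the eyes — repeated 3 trials x 3 days
at each of ZT 16, 22 and 8 (27 trials per neuron).  A cohort of ~113
neurons, ~40% of them VIP-labelled, is imaged across two focal planes.

A raw trace is composed additively:

    F(t) = B·exp(-t/tau_bleach)                photobleaching decay
         + spontaneous calcium transients      Poisson events convolved
                                               with a rise/decay kernel
         + gain·s·archetype(t - 30 s)          light-evoked response,
                                               light window only
         + shared per-trial latent factor      within-trial population
                                               synchrony
         + white measurement noise

Seven light-response archetypes are modelled (transient / sustained /
delayed activation, marginal, and the three mirrored inhibitions).
Three planted neuron groups define the ground truth for the group
classifier: group 1 receives a sustained activation archetype in every
ZT-16 trial, group 2 a sustained inhibition archetype in every ZT-22
trial, and group 3 draws an archetype per trial from ``cluster_mix``.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .preprocess import TraceRecording

__all__ = [
    "ARCHETYPE_NAMES",
    "CohortConfig",
    "SyntheticCohort",
    "ActogramRecord",
    "archetype_waveform",
    "generate_cohort",
    "generate_image_stack",
    "generate_actogram",
]

ARCHETYPE_NAMES: dict[int, str] = {
    1: "transient activation",
    2: "sustained activation",
    3: "delayed activation",
    4: "marginal response",
    5: "delayed inhibition",
    6: "sustained inhibition",
    7: "transient inhibition",
}

#: archetype id used for the consistent group-1 / group-2 responses
GROUP1_ARCHETYPE = 2  # sustained activation
GROUP2_ARCHETYPE = 6  # sustained inhibition

# reference single-trial cluster composition (normalized to sum 1)
_DEFAULT_MIX = np.array([0.0748, 0.0501, 0.147, 0.355, 0.161, 0.0442, 0.168])
_DEFAULT_MIX = tuple(_DEFAULT_MIX / _DEFAULT_MIX.sum())


def archetype_waveform(archetype: int, t_light: np.ndarray) -> np.ndarray:
    """Unit-amplitude response waveform over the light window.

    ``t_light`` is time in seconds since light onset.  Shapes are
    parameterized ramps/exponentials: transient = fast on, slow return;
    sustained = saturating step; delayed = sigmoidal onset near 40 s;
    marginal = flat zero; inhibitions are sign-mirrored.
    """
    t = np.asarray(t_light, dtype=float)
    if archetype in (1, 7):
        w = (1.0 - np.exp(-t / 1.0)) * np.exp(-t / 18.0)
        w = w / w.max() if w.max() > 0 else w
    elif archetype in (2, 6):
        w = 1.0 - np.exp(-t / 6.0)
    elif archetype in (3, 5):
        w = 1.0 / (1.0 + np.exp(-(t - 40.0) / 6.0))
    elif archetype == 4:
        w = np.zeros_like(t)
    else:
        raise ValueError(f"unknown archetype {archetype}")
    return w if archetype <= 4 else -w


@dataclass
class CohortConfig:
    """Generation parameters for a synthetic recording cohort.

    Defaults reproduce the study conditions: 113 neurons with 46 of
    them VIP-labelled, 3 trials x 3 days at ZT 16/22/8, 23-Hz frames,
    30 s baseline + 90 s light, group mixture 11.5/4.4/84.1% and the
    reported seven-cluster trial mixture.  ``response_gain`` is in
    Z-like units of ``signal_scale`` fluorescence counts; the default
    of 3 plants ±3 SD effects for the consistent groups.
    """

    n_neurons: int = 113
    vip_fraction: float = 46 / 113
    group_fractions: tuple[float, float, float] = (0.115, 0.044, 0.841)
    frame_rate: float = 23.0
    baseline_s: float = 30.0
    light_s: float = 90.0
    zts: tuple[int, ...] = (16, 22, 8)
    days_per_zt: int = 3
    trials_per_day: int = 3
    baseline_level: float = 8000.0  # soma counts are typically 4000-15000
    bleach_tau: float = 2000.0  # s; sessions are spaced to keep in-trial bleaching mild
    transient_rate: float = 1.0  # spontaneous events / min
    transient_rise_s: float = 0.2
    transient_decay_s: float = 1.5
    transient_amp: float = 300.0  # fluorescence units at kernel peak
    response_gain: float = 3.0  # Z-units (x signal_scale)
    signal_scale: float = 100.0  # fluorescence units per Z-unit
    noise_sd: float = 50.0  # fluorescence units
    shared_factor_weight: float = 0.2  # Z-units of per-trial common drive
    vip_factor_weight: float = 0.0  # extra latent shared by VIP+ only
    cluster_mix: tuple[float, ...] = _DEFAULT_MIX
    light_intensity_uw_mm2: float = 1.76  # stimulus metadata only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_s <= 0 or self.light_s <= 0:
            raise ValueError("durations must be positive")
        if abs(sum(self.group_fractions) - 1.0) > 1e-6:
            raise ValueError("group_fractions must sum to 1")
        mix = np.asarray(self.cluster_mix, dtype=float)
        if mix.size != 7 or abs(mix.sum() - 1.0) > 1e-6 or (mix < 0).any():
            raise ValueError("cluster_mix must be 7 nonnegative values summing to 1")
        n_frames = self.frame_rate * (self.baseline_s + self.light_s)
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("trial duration x frame rate must be an integer frame count")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * (self.baseline_s + self.light_s)))

    @property
    def trials_per_neuron(self) -> int:
        return len(self.zts) * self.days_per_zt * self.trials_per_day


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth.

    ``truth_trial_clusters`` holds the planted archetype id (1..7) per
    trace, aligned with ``traces``; ``truth_groups`` holds the planted
    group (1..3) per neuron id.
    """

    config: CohortConfig
    traces: list[TraceRecording]
    truth_groups: np.ndarray
    truth_trial_clusters: np.ndarray
    coordinates: np.ndarray  # (n_neurons, 2) in µm
    z_planes: np.ndarray  # 'ventral' / 'dorsal' per neuron
    vip_labels: np.ndarray  # bool per neuron

    _values: np.ndarray | None = field(default=None, repr=False)

    @property
    def values(self) -> np.ndarray:
        """All raw traces stacked, shape (n_traces, n_frames)."""
        if self._values is None:
            self._values = np.stack([tr.values for tr in self.traces])
        return self._values

    def meta(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "neuron_id": [tr.neuron_id for tr in self.traces],
                "zt": [tr.zt for tr in self.traces],
                "day": [tr.day for tr in self.traces],
                "trial": [tr.trial for tr in self.traces],
                "z_plane": [tr.z_plane for tr in self.traces],
                "vip": [tr.vip for tr in self.traces],
            }
        )


def _transient_kernel(cfg: CohortConfig) -> np.ndarray:
    """Difference-of-exponentials calcium transient, peak-normalized."""
    dt = 1.0 / cfg.frame_rate
    length = int(round((cfg.transient_rise_s + 8 * cfg.transient_decay_s) / dt))
    tk = np.arange(length) * dt
    k = np.exp(-tk / cfg.transient_decay_s) - np.exp(-tk / cfg.transient_rise_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def _spontaneous(rng: np.random.Generator, cfg: CohortConfig, kernel: np.ndarray) -> np.ndarray:
    """Poisson-timed transients convolved with the event kernel."""
    duration_min = (cfg.baseline_s + cfg.light_s) / 60.0
    out = np.zeros(cfg.n_frames)
    n_events = rng.poisson(cfg.transient_rate * duration_min)
    if n_events == 0:
        return out
    starts = rng.integers(0, cfg.n_frames, size=n_events)
    amps = cfg.transient_amp * rng.lognormal(mean=0.0, sigma=0.25, size=n_events)
    for s, a in zip(starts, amps):
        seg = kernel[: cfg.n_frames - s]
        out[s : s + seg.size] += a * seg
    return out


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic recording cohort with ground truth."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_neurons

    groups = rng.choice([1, 2, 3], size=n, p=np.asarray(cfg.group_fractions))
    n_vip = int(round(n * cfg.vip_fraction))
    vip = np.zeros(n, dtype=bool)
    vip[rng.choice(n, size=n_vip, replace=False)] = True
    coords = rng.uniform(0.0, 300.0, size=(n, 2))
    z_planes = np.where(rng.random(n) < 0.5, "ventral", "dorsal")

    t = np.arange(cfg.n_frames) / cfg.frame_rate  # 0 .. 120 s
    light_on = t >= cfg.baseline_s
    t_light = t[light_on] - cfg.baseline_s
    bleach = cfg.baseline_level * np.exp(-t / cfg.bleach_tau)
    kernel = _transient_kernel(cfg)
    waveforms = {
        a: archetype_waveform(a, t_light) for a in range(1, 8)
    }

    trial_keys = [
        (zt, day, trial)
        for zt in cfg.zts
        for day in range(1, cfg.days_per_zt + 1)
        for trial in range(1, cfg.trials_per_day + 1)
    ]
    # per-trial latent factor shared by every neuron in that trial
    shared: dict[tuple[int, int, int], np.ndarray] = {}
    vip_shared: dict[tuple[int, int, int], np.ndarray] = {}
    for key in trial_keys:
        raw = rng.standard_normal(cfg.n_frames)
        smooth = gaussian_filter1d(raw, sigma=2.0 * cfg.frame_rate)
        sd = smooth.std()
        smooth = smooth / sd if sd > 0 else smooth
        shared[key] = cfg.shared_factor_weight * cfg.signal_scale * smooth
        if cfg.vip_factor_weight:
            raw_v = rng.standard_normal(cfg.n_frames)
            smooth_v = gaussian_filter1d(raw_v, sigma=2.0 * cfg.frame_rate)
            sd_v = smooth_v.std()
            smooth_v = smooth_v / sd_v if sd_v > 0 else smooth_v
            vip_shared[key] = cfg.vip_factor_weight * cfg.signal_scale * smooth_v

    mix = np.asarray(cfg.cluster_mix, dtype=float)
    traces: list[TraceRecording] = []
    truth_clusters: list[int] = []
    for neuron in range(n):
        for zt, day, trial in trial_keys:
            if groups[neuron] == 1 and zt == 16:
                arch = GROUP1_ARCHETYPE
            elif groups[neuron] == 2 and zt == 22:
                arch = GROUP2_ARCHETYPE
            else:
                arch = int(rng.choice(7, p=mix)) + 1
            values = bleach + _spontaneous(rng, cfg, kernel)
            if cfg.response_gain:
                resp = np.zeros(cfg.n_frames)
                resp[light_on] = (
                    cfg.response_gain * cfg.signal_scale * waveforms[arch]
                )
                values = values + resp
            values = values + shared[(zt, day, trial)]
            if cfg.vip_factor_weight and vip[neuron]:
                values = values + vip_shared[(zt, day, trial)]
            if cfg.noise_sd:
                values = values + rng.normal(0.0, cfg.noise_sd, cfg.n_frames)
            traces.append(
                TraceRecording(
                    neuron_id=neuron,
                    zt=zt,
                    day=day,
                    trial=trial,
                    values=values,
                    frame_rate=cfg.frame_rate,
                    z_plane=str(z_planes[neuron]),
                    vip=bool(vip[neuron]),
                    centroid=(float(coords[neuron, 0]), float(coords[neuron, 1])),
                )
            )
            truth_clusters.append(arch)

    return SyntheticCohort(
        config=cfg,
        traces=traces,
        truth_groups=groups,
        truth_trial_clusters=np.asarray(truth_clusters),
        coordinates=coords,
        z_planes=z_planes,
        vip_labels=vip,
    )


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def generate_image_stack(
    n_frames: int,
    true_shifts: np.ndarray,
    cell_layout: Iterable[tuple[float, float, float]] | None = None,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build a translated-scene stack plus ROI masks and truth shifts.

    Frame ``k`` is a fixed random smooth scene (with bright disc "cells"
    from ``cell_layout``) translated by ``true_shifts[k] = (t_x, t_y)``
    pixels, plus optional white noise.  The translation is realized by
    cropping from an oversized scene, so it is exact with no wrap or
    interpolation.  Masks are labelled in reference-frame coordinates.
    """
    shifts = np.asarray(true_shifts, dtype=int)
    if shifts.shape != (n_frames, 2):
        raise ValueError("true_shifts must have shape (n_frames, 2)")
    h, w = shape
    bound = min(h, w) // 4
    if np.abs(shifts).max() >= bound:
        raise ValueError(f"shifts must be within ±{bound} px")

    rng = np.random.default_rng(seed)
    m = int(np.abs(shifts).max()) + 1
    big = gaussian_filter(rng.standard_normal((h + 2 * m, w + 2 * m)), sigma=3.0)
    big = 100.0 + 500.0 * (big - big.min()) / (np.ptp(big) or 1.0)

    if cell_layout is None:
        n_cells = 12
        cell_layout = [
            (rng.uniform(20, w - 20), rng.uniform(20, h - 20), rng.uniform(5, 10))
            for _ in range(n_cells)
        ]
    yy, xx = np.mgrid[0 : h + 2 * m, 0 : w + 2 * m]
    masks = np.zeros(shape, dtype=np.int32)
    ry, rx = np.mgrid[0:h, 0:w]
    for label, (cx, cy, r) in enumerate(cell_layout, start=1):
        disc = (xx - (cx + m)) ** 2 + (yy - (cy + m)) ** 2 <= r**2
        big[disc] += 800.0
        masks[(rx - cx) ** 2 + (ry - cy) ** 2 <= r**2] = label

    stack = np.empty((n_frames, h, w))
    for k, (tx, ty) in enumerate(shifts):
        # moving[r, c] = scene[r - ty, c - tx]
        stack[k] = big[m - ty : m - ty + h, m - tx : m - tx + w]
    if noise_sd:
        stack = stack + rng.normal(0.0, noise_sd, stack.shape)
    return stack, masks, shifts


# ---------------------------------------------------------------------------
# actograms
# ---------------------------------------------------------------------------

@dataclass
class ActogramRecord:
    """Minute-binned wheel-running counts across consecutive days."""

    counts: np.ndarray
    n_days: int
    free_running_period: float  # hours
    injection_day: int | None = None
    true_shift: float | None = None  # hours; delays negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.n_days * 1440:
            raise ValueError("counts length must be n_days x 1440")
        if not (20.0 < self.free_running_period < 28.0):
            raise ValueError("free-running period must lie in (20, 28) h")


def generate_actogram(
    period_h: float = 23.8,
    active_hours: float = 10.0,
    n_days: int = 14,
    injection_day: int | None = None,
    true_shift_h: float | None = None,
    onset0_h: float = 18.0,
    active_rate: float = 6.0,
    quiet_rate: float = 0.05,
    noise: bool = True,
    seed: int = 0,
) -> ActogramRecord:
    """Simulate a free-running wheel actogram with an optional injected
    phase shift.

    Activity bouts of ``active_hours`` begin at onsets drifting by
    ``period_h - 24`` h/day.  Onsets after the injection day are offset
    by ``-true_shift_h`` (delays are negative, shifting activity later).
    Counts per minute are Poisson around the bout profile when ``noise``
    is on, otherwise the rounded rate itself.
    """
    if not (20.0 < period_h < 28.0):
        raise ValueError("period must lie in (20, 28) h")
    if injection_day is not None and n_days < injection_day + 5:
        raise ValueError("need at least injection_day + 5 days")
    rng = np.random.default_rng(seed)
    minutes = np.arange(n_days * 1440)
    hours_abs = minutes / 60.0
    rate = np.full(minutes.size, quiet_rate)
    n_cycles = int(np.ceil(n_days * 24.0 / period_h)) + 2
    for k in range(n_cycles):
        onset_abs = onset0_h + k * period_h
        if (
            injection_day is not None
            and true_shift_h is not None
            and onset_abs > injection_day * 24.0 + onset0_h
        ):
            onset_abs -= true_shift_h  # a delay (negative shift) moves activity later
        sel = (hours_abs >= onset_abs) & (hours_abs < onset_abs + active_hours)
        rate[sel] = active_rate
    counts = rng.poisson(rate) if noise else np.rint(rate).astype(int)
    return ActogramRecord(
        counts=counts,
        n_days=n_days,
        free_running_period=period_h,
        injection_day=injection_day,
        true_shift=true_shift_h,
    )
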