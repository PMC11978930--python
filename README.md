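# scnlight

Single-cell analysis of light-evoked calcium responses in the
suprachiasmatic nucleus (SCN), the mammalian master circadian clock.

Light during the early subjective night delays the clock, light during
the late subjective night advances it, and light in the mid-day "dead
zone" barely shifts it. `scnlight` implements an end-to-end pipeline for
asking, at single-neuron resolution, which SCN neurons carry those
time-gated responses: from raw two-photon GRIN-endoscope calcium traces
(or synthetic stand-ins with known ground truth) through light-response
clustering, time-gated neuron-group classification, correlation-network
statistics, and wheel-running phase-shift estimation.

The pipeline is for chronobiologists and imaging analysts working with
trial-structured stimulus-response calcium recordings — each trial here
being a 30-s dark baseline followed by a 90-s light pulse at 23 Hz,
repeated 3 trials × 3 days at each of ZT 16, ZT 22 and ZT 8 (27 trials
per neuron).

## The method

**Preprocessing.** Frames are motion-corrected by integer translation
maximizing a mutual-information metric against the first frame; ROI
traces are per-frame means over mask voxels; an out-of-endoscope
background trace is subtracted; the photobleaching trend
`a·exp(-t/τ) + c` is fitted on the response-free dark baseline and the
decaying part removed; each trial is normalized as

```
z(t) = (F(t) − F_baseline) / F_std
```

where `F_baseline` is the *median* over the 30-s dark baseline (so zero
marks the pre-stimulus level) and `F_std` the standard deviation over
the whole 120-s trial.

**Response clustering.** Z-scores are averaged in 5-s bins (6 baseline
+ 18 light bins); PCA on the light bins followed by k-means (k = 7)
partitions single-trial responses into seven semantic clusters —
transient/sustained/delayed activation, marginal response, and the
mirrored inhibitions. Per-cluster significance per bin is a one-way
ANOVA across the 19 bins (baseline −5..0 s plus 18 light bins) with a
Tukey post hoc, and per-neuron response diversity counts distinct
cluster labels across the 27 trials.

**Group classification.** Per neuron and ZT, each light bin is coded
+1/0/−1 against baseline across the nine trials (ANOVA + Tukey),
giving a length-54 trinary pattern over (ZT 16, ZT 22, ZT 8) × 18 bins.
k-means (k = 3) on the patterns separates group 1 (consistently
activated at ZT 16 — the phase-delay window), group 2 (consistently
inhibited at ZT 22 — the phase-advance window) and the stochastic
group 3 majority. Haar-wavelet features of each ZT's trinary series
and the 50–75 s response AUC provide independent group contrasts.

**Network statistics.** Pearson correlations over the 90-s light window
give R-same (between neurons, same trial) versus R-cross (same neuron,
trials at different ZTs), VIP⁺/VIP⁻ in/out-group contrasts, r > 0.5
connectivity maps over the nine repeats of each ZT, and an OLS
regression of pairwise r on inter-neuronal distance.

**Phase shifts.** Wheel-running actograms are reduced to daily activity
onsets; a regression line over 3–5 pre-injection days is extrapolated
past the (excluded) injection day and the shift is the gap to the
observed post-injection onsets (delays negative). A per-day 24-h
cosinor acrophase provides an alternative estimator.

Because no raw recordings ship with the package, a first-class
synthetic generator (`scnlight.synthetic`) emulates the recording
paradigm — photobleaching, spontaneous GCaMP transients, seven planted
response archetypes, three planted neuron groups, a shared per-trial
latent factor, and free-running actograms with injected phase shifts —
so every stage is testable against known ground truth.

## Worked example

```python
import scnlight as sl

cohort = sl.generate_cohort(sl.CohortConfig(n_neurons=40, seed=0))
z = sl.normalize_cohort(cohort)

labels, model, binned = sl.label_cohort(cohort, z_matrix=z, seed=0)
for c, f in labels["label"].value_counts(normalize=True).sort_index().items():
    print(f"cluster {c} ({model.cluster_names[c]}): {100*f:.1f}%")

patterns = sl.pattern_matrix(cohort, binned)
groups, _ = sl.classify_groups(patterns, seed=0)

net = sl.r_same_vs_r_cross(z, cohort.meta())
rec = sl.generate_actogram(period_h=23.8, n_days=14, injection_day=8,
                           true_shift_h=-1.5, seed=0)
est = sl.estimate_phase_shift(rec, injection_day=8)
```

prints

```
cluster 1 (transient activation): 6.4%
cluster 2 (sustained activation): 10.2%
cluster 3 (delayed activation): 14.4%
cluster 4 (marginal response): 32.2%
cluster 5 (delayed inhibition): 15.5%
cluster 6 (sustained inhibition): 5.6%
cluster 7 (transient inhibition): 15.6%
```

and recovers the planted structure: `groups` matches the planted
5 / 2 / 33 group-1/2/3 neurons exactly, `net` gives median
R-same = 0.072 against median R-cross = 0.006 (within-trial synchrony
with no cross-time stability), and `est.shift` is −1.51 h for the
−1.5 h injected delay, with the 23.80-h free-running period recovered
from the pre-injection onsets.

A thin CLI wraps the same stages:

```bash
scnlight simulate-cohort --out cohort/ --n-neurons 40 --seed 0
scnlight cluster  --traces cohort/ --out labels.csv --seed 0
scnlight classify --traces cohort/ --out groups.csv --seed 0
scnlight network  --traces cohort/ --out network.json
scnlight simulate-actogram --out acto.csv --injection-day 8 --shift -1.5
scnlight phaseshift --actogram acto.csv --injection-day 8
```

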