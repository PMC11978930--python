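# Methods

This note records the models behind each pipeline stage, the defaults
that matter, the design choices that were genuinely open, and what the
synthetic data do and do not establish.

## Recording paradigm and the synthetic generator

Every trial is a 120-s fluorescence series at 23 Hz (2760 frames): a
30-s dark baseline followed by 90 s of blue light to the eyes. A
session holds three such trials; sessions repeat on three days at each
of ZT 16, ZT 22 and ZT 8, so a tracked neuron contributes 27 trials.
The default cohort has 113 neurons, 46 of them VIP-labelled (40.7%),
split 11.5% / 4.4% / 84.1% across the three planted groups.

A raw synthetic trace is additive:

```
F(t) = B·exp(−t/τ_b)                  photobleaching
     + Σ_k A_k·k(t − t_k)             spontaneous transients
     + g·s·archetype(t − 30 s)        light response (light window only)
     + w·s·f_trial(t)                 shared per-trial latent factor
     + ε(t)                           white noise
```

Defaults, with reasoning:

| parameter | default | why |
|---|---|---|
| baseline level `B` | 8000 counts | somata are typically 4000–15000 counts in this kind of recording |
| bleach `τ_b` | 2000 s | sessions are spaced ≥14 h apart precisely to keep in-trial bleaching mild (~6% over 120 s) |
| transient rate | 1 / min | spontaneous SCN calcium transients are sparse on the 2-min timescale |
| transient kernel | rise 0.2 s, decay 1.5 s, peak 300 counts, lognormal amplitude (σ=0.25) | generic fast-indicator (GCaMP7f-like) event shape |
| noise `ε` | SD 50 counts | the out-of-endoscope background varies by <50 counts |
| signal scale `s` | 100 counts per Z-unit | sets the conversion from nominal Z-units to counts |
| response gain `g` | 3 | plants nominal ±3 SD effects for the consistent groups |
| shared factor weight `w` | 0.2 | produces a clearly positive R-same without dominating single-trial shapes |

The seven archetypes are parameterized shapes over the light window:
transient = fast rise (τ 1 s) returning with τ 18 s; sustained =
saturating step (τ 6 s); delayed = sigmoid onset at 40 s (width 6 s);
marginal = zero; inhibitions mirrored. Group-1 neurons receive the
sustained activation archetype in every ZT-16 trial, group-2 the
sustained inhibition in every ZT-22 trial; all other trials draw an
archetype from the seven-cluster mixture
(7.5/5.0/14.7/35.5/16.1/4.4/16.8%, renormalized to sum to one).
Group membership is a multinomial draw; the VIP count is deterministic
(`round(n·vip_fraction)`) so the labelled fraction is exact.

What the generator does *not* emulate: slow calcium oscillations and
their circadian modulation, neuropil contamination, z-drift, nonrigid
motion, cell-to-cell variation in bleaching, and any real network
coupling beyond a single within-trial latent factor. Passing tests on
this generator therefore demonstrate that the pipeline recovers planted
structure under realistic noise — not that real SCN data contain such
structure.

Image-stack fixtures are translated crops from an oversized smooth
random scene with disc "cells", so the planted shift is exact with no
wrap-around; actograms are Poisson counts around a drifting square
activity bout (period 23.8 h, 10 active hours, 6 counts/min active vs
0.05 quiet), with post-injection onsets offset by the injected shift.

## Motion correction

Integer-translation registration maximizes the joint-histogram mutual
information (32 bins per marginal, each image binned over its own
range) over the overlap of the candidate shift. The default strategy
scans every shift within ±20 px exhaustively — exact by construction
and fast enough at 512×512 (bin indices are precomputed; each shift is
one `bincount`); a coarse-to-fine scan (stride 4, then local
refinement) is available. Degenerate (constant) images return a zero
shift with a warning, and a session is flagged "excessive motion" when
any frame's shift exceeds 10 px (configurable).

## Detrending: identifiability dictates the design

The trend model is the mono-exponential decay `a·exp(−t/τ) + c`,
fitted by trust-region least squares; only the decaying part is
subtracted (the constant is kept).

Where the trend is *estimated* matters more than how. A fit over the
whole trial is not identifiable in the presence of slow evoked
components: over the 90-s light window, a sustained late response and
a bleaching trend are interchangeable to the fitter — in experiments on
planted archetypes, whole-trace fits (plain, robust-loss, and
decay-budget-constrained variants) all absorbed 30–80% of delayed and
sustained response shapes. The baseline-anchored design removes the
ambiguity:

* the trend is fitted on the dark pre-stimulus baseline only — the one
  window guaranteed response-free — and extrapolated across the trial;
* the exponential is used when it at least halves the straight line's
  residual sum of squares on that window (resolvable curvature, e.g. a
  strong decay or noise-free data); otherwise the decay is in its
  quasi-linear regime, where `a` and `τ` are not separately identified
  but their product is, and the robust Theil–Sen baseline slope is
  subtracted instead (exactly idempotent);
* `a ≥ 0` throughout: photobleaching is a decay.

A single 30-s baseline estimates the slope with enough variance that
extrapolation adds visible trial-end noise, so the cohort pipeline
pools: the bleach is a property of the preparation, and the trend is
fitted per *neuron* on the mean of that neuron's 27 dark baselines,
which cancels trial-specific transients and the shared latent factor
before extrapolation. The per-trace `detrend()` remains available for
standalone use.

Known limitation: a real decay component faster than the baseline
window but active beyond it, or per-trial bleach variation, violates
the pooling assumption; and a slope estimated on any finite window has
a boundary-term bias for large slow oscillations.

## Normalization

`z(t) = (F(t) − F_baseline)/F_std` with `F_baseline` the baseline
*median* (robust to transients; pins the pre-stimulus level at zero)
and `F_std` the population-denominator SD over the full 120 s. Note
`F_std` includes the evoked response itself, so a planted gain-3
response realizes at ~2–2.4 z after normalization; this shrinkage is a
property of the normalization, not of the generator. Zero-variance
traces are an error (the Z-score is undefined).

## Response clustering

Z-scores are averaged in half-open 5-s bins (115 frames each; 6
baseline + 18 light bins). PCA keeps components explaining ≥90%
variance of the 18 light bins; k-means uses k-means++ with 25 restarts
at a fixed seed. Clusters are *named* from their back-projected
centroid waveforms:

* marginal = smallest-amplitude centroid;
* polarity = sign of the waveform at its absolute extremum (the
  overall mean would misread transient shapes, whose late window sits
  near zero);
* within a polarity, the delayed response reaches half its extremum
  last; at 5-s binning both transient and sustained cross it in the
  first bin, so that pair is split by persistence — the ratio of the
  late-window mean to the peak (a transient returns toward baseline,
  a sustained response does not).

This naming is invariant to k-means label permutation (verified by
seed scan) and stable across generator seeds. When the polarity split
is not 3/3 the overflow takes the remaining slots in timing order, so
the map is always a bijection, with a warning.

Per-cluster significance: for each cluster, a one-way ANOVA across the
19 bins (baseline −5..0 s + 18 light bins) over member trials, with
Tukey-Kramer comparisons of each light bin against the baseline bin.
The Tukey step runs only when the omnibus ANOVA rejects at α = 0.05;
with the gate, null simulations keep the family-wise star rate at the
nominal level. The Tukey criterion is implemented directly from the
studentized-range distribution and cross-checked against statsmodels'
`pairwise_tukeyhsd` in the test suite.

## Group classification

The per-neuron trinary pattern applies the same ANOVA + Tukey
machinery per ZT with the nine per-trial bin means as samples, coding
each light bin +1/0/−1 against baseline, concatenated over
(ZT 16, ZT 22, ZT 8). k-means (k = 3) runs on the raw 54-vectors (not
on Haar features — both paths exist, the raw path is the default);
centroids map to groups semantically: maximal summed ZT-16 block →
group 1, then minimal summed ZT-22 block → group 2, remainder →
group 3, so k-means label permutation never changes the groups.

Haar features zero-pad each 18-bin trinary series to 32 and apply the
orthonormal Haar wavelet to full depth (PyWavelets), keeping the first
8 coarse-to-fine coefficients by default; the full 32 reconstruct the
padded series exactly and satisfy Parseval. Padding is required by the
power-of-two transform; neither the padding length nor the retained
dimension is canonical, both are configurable. The response AUC is the
signed trapezoid of z over 50–75 s after light onset (the window where
responses have stabilized), in z·s.

Group composition counts activation-side trials (clusters 1–4) and
consistent-inhibition trials (clusters 5–6) per neuron and ZT —
cluster 7 (transient inhibition) is the complement — and compares
groups per ZT by ANOVA + Tukey on the per-neuron fractions.

## Network statistics

All correlations are Pearson r between normalized traces over the
2070 light-window frames. R-same pairs different neurons within one
trial; R-cross pairs the same neuron across trials at *different* ZTs.
The two-group comparison runs on Fisher-z transformed values (variance
stabilization; raw r is reported). Connectivity graphs draw an edge
when the mean r over the nine repeats of a ZT exceeds 0.5; the
distance regression is OLS of per-pair mean r on Euclidean centroid
distance (µm per pixel configurable, default 1), reported per ZT plus
the across-ZT mean. Pairs with a zero-variance trace are omitted with
a warning, as are pairs with missing repeats (mean over available).

## Phase-shift estimation

Onsets: counts are smoothed with a 15-min moving average; the
threshold is half the 0.75-quantile of the nonzero raw counts (i.e.
half the typical within-bout count, placing it between the quiescent
and active levels — a quantile taken literally sits inside the active
count distribution and misses sustained crossings). An onset requires
≥90% of the preceding 6 h below threshold and ≥80% of the following
30 min above it; one onset per day, days without one are skipped.
Onsets are unwrapped across midnight by minimizing day-to-day jumps
(valid because free-running drift is far below 12 h/day).

The pre-injection line is OLS on 3–5 unwrapped onsets before the
injection day; slope + 24 h is the free-running period, constrained to
(20, 28) h at the generator level. The shift is the mean of
(extrapolated − observed) onset over the first valid post-injection
day (window configurable), with the injection day excluded; delays are
negative, advances positive.

The acrophase alternative fits `counts ~ mesor + a·cos(ωt) + b·sin(ωt)`
per calendar day (ω = 2π/24 h) and uses `atan2(b, a)/ω` as the peak
time. Because activity bouts cross midnight, the calendar day right
after the injection still contains morning activity from the last
pre-injection cycle; its acrophase is diluted, so the acrophase
estimator reads the first fully post-injection day (injection + 2 by
default). On clean synthetic actograms both estimators agree within
0.3 h, and over 100 noisy seeds both recover −1.5 h and +1.0 h
injected shifts with mean error below 0.1 h.

## Numerical conventions and degenerate inputs

* Half-open bin windows `[start, end)`; light onset is t = 0; frame
  times are `k/23 − 30` s.
* Mutual information in nats; constant images → MI 0 with a warning.
* k-means with fewer distinct inputs than k degrades to the distinct
  count and is flagged; all-identical trinary patterns → everyone in
  group 3.
* Sub-seeds derived from the user seed stay below 2³¹.
* Problem sizes in tests and in the acceptance script follow the study
  conditions (113 neurons × 27 trials; 2875 trials for the mixture
  cohort; 100 registration fixtures; 100 actogram seeds).
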