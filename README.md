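# meanet — multi-well MEA network-activity analysis

`meanet` is a tested, reusable implementation of a microelectrode-array
(MEA) analysis pipeline for cultured neuronal networks, of the kind used to
compare human pluripotent stem cell (hPSC)-derived cortical networks with
embryonic rat cortical cultures on multi-well plates (16 or 64 electrodes
per well, 12.5 kHz sampling, 10-minute recordings). It is aimed at
electrophysiologists and analysis engineers who need the full chain from
raw voltage traces to population-level feature clustering, with every stage
verifiable against simulated ground truth.

## What it computes

1. **Consensus spike detection.** Traces are band-passed with a zero-phase
   elliptic filter (200–3000 Hz); an amplitude detector thresholds at
   4.5 × σ̂, where σ̂ = median(|x|)/0.6745 is the robust noise SD; the
   SWTTEO detector (Teager energy ψ[c](n) = c(n)² − c(n−1)c(n+1) applied to
   stationary-wavelet detail coefficients, smoothed and summed) confirms as
   many energy peaks as the threshold stage found; only events reported by
   both detectors within 1 ms are kept. Electrodes with > 10 spikes/min are
   "active" and enter the analysis.
2. **logISI burst detection.** A per-electrode ISI threshold is taken at
   the valley of the log-ISI histogram between the intra-burst peak
   (< 100 ms) and a slower peak, gated by the void parameter
   v = 1 − h_min/√(h_p1·h_p2) ≥ 0.7. Two modifications: a burst must have
   ≥ 5 spikes, and when ISITh < 100 ms, bursts separated by < 100 ms are
   merged. Features: bursts/min, burst duration, spikes per burst, spike
   frequency in bursts, % spikes in bursts (well value = median over
   bursting electrodes).
3. **Synchrony and connectivity.** Pairwise spike time tiling coefficient
   STTC = ½[(P_A−T_B)/(1−P_A·T_B) + (P_B−T_A)/(1−P_B·T_A)] with Δt = 50 ms,
   and CorSE functional connectivity — the magnitude of the Pearson
   correlation between two channels' spectral-entropy time series — with
   connectivity maps thresholded at CorSE > 0.7.
4. **7-feature PCA.** Per well and time point: mean firing rate, burst
   rate, burst duration, spike frequency in bursts, spikes in burst,
   % spikes in bursts, STTC. Standard-score normalization, projection onto
   the leading principal components, and a silhouette score for group
   segregation. A percent-change operation summarizes pharmacology runs
   against same-well baselines.
5. **Synthetic data.** A point-process generator (Poisson network-burst
   onsets, per-electrode participation and onset jitter, Poisson
   intra-burst and tonic spiking, 1 ms refractory) plus a raw-trace
   synthesizer (biphasic templates, lognormal amplitudes, Gaussian and
   mains noise) with presets for the two phenotypes at peak activity:
   `hPSC_peak` (11 bursts/min, 0.7 s, ≈34 spikes/burst) and `rat_peak`
   (15 bursts/min, 0.3 s, ≈100 Hz intra-burst rate). Every generated data
   set carries its ground truth, so detection and burst recovery are
   measurable.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
plates (12 wells × 3 measurement days per phenotype) and write their tables
under `results/`:

```sh
python analysis/01_simulate_plates.py
python analysis/02_detection_validation.py
python analysis/03_burst_features.py
python analysis/04_connectivity.py
python analysis/05_features_pca.py
python analysis/06_pharmacology.py
```

Output from a complete run:

```
hPSC-like well (16 electrodes, 60 s): sensitivity 0.974, precision 0.999
noise-only audit: 0.250 consensus spikes/min/electrode
hpsc: plate-median burst rate 8.85/min (preset 11.0), duration 0.678 s (preset 0.7) — errors -19.5% / -3.1%
rat: plate-median burst rate 12.95/min (preset 15.0), duration 0.285 s (preset 0.3) — errors -13.7% / -4.8%
median well STTC — hPSC-like 0.735, rat-like 0.848
CorSE on shared-envelope well: average 0.872, 6/6 pairs above 0.7
72 samples; PC1/PC2/PC3 explain 84.3/14.3/0.7% of variance
silhouette of true labels 0.728 vs permutation 95th pct 0.052
antagonist_gabaergic: median change +64.1%
antagonist_glutamatergic: median change -91.9%
ttx_like: median change -100.0%
```

Reading this: consensus detection recovers 97.4% of ground-truth spikes at
99.9% precision while admitting only 0.25 false positives/min/electrode on
pure noise; the burst detector recovers the generator's burst rate and
duration (rates read ~10–20% low because electrodes skip 10% of network
bursts and near-coincident bursts merge); rat-like wells are more
synchronous than hPSC-like wells (STTC 0.85 vs 0.74), matching their
smaller onset jitter; and the two phenotypes segregate cleanly in the first
three principal components (silhouette 0.73 against a permutation null of
~0.05).

A `meanet` CLI wraps the same stages for ad-hoc use
(`meanet simulate | detect | bursts | connect | features | pca | pharm | run`);
`meanet run` executes the full pipeline and writes a JSON manifest with
config snapshot and content hashes.

## Layout

```
src/meanet/       library: io, simulate, detection, bursts, connectivity,
                  features, pipeline, cli
analysis/         numbered study drivers (simulate → detect → bursts →
                  connectivity → PCA → pharmacology)
tests/            pytest suite incl. brute-force oracles and end-to-end checks
scripts/          acceptance.py
docs/methods.md   models, parameter choices, numerical details, limitations
```
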