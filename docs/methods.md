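# Methods

This note records the models implemented in `meanet`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical details that matter when
reproducing results.

## Data model

All times are 0-based seconds from recording start; intervals are half-open
`[t_start, t_end)`. Spike times are stored at 1 µs resolution (six
decimals), which is lossless for the 80 µs sample period of the 12.5 kHz
target hardware. Raw traces are float32 µV in HDF5
(`/wells/<id>/traces`, electrodes × samples, root attribute `fs_hz`);
spikes, bursts, connectivity and features are plain CSV with fixed headers.
Readers validate invariants (sorted per-electrode times, unique electrode
ids, 1–64 electrodes per well) and reject rather than repair.

## Consensus spike detection

* **Prefilter** — elliptic band-pass, 200–3000 Hz edges, order 4, 0.1 dB
  passband ripple, 40 dB stopband attenuation, applied forward–backward
  (zero phase). The band edges are the analysis standard for extracellular
  spikes; order/ripple are conventional for a compact elliptic design.
* **Noise estimate** — σ̂ = median(|x|)/0.6745 on the *filtered* trace
  (the threshold is applied there). The median-based estimator is nearly
  insensitive to spike contamination: at 1% contaminated samples it stays
  within a few percent of the true σ while the plain SD more than doubles.
* **Amplitude detector** — local extrema of −x exceeding 4.5 σ̂, with a
  1 ms dead time (the larger extremum wins). Default polarity is
  negative-only: near-electrode extracellular spikes are negative-dominant,
  and one-sided thresholding halves the noise-only false-positive rate at
  identical sensitivity; `polarity: both` is available in the config for
  preparations with inverted or biphasic-symmetric units.
* **SWTTEO confirmation** — stationary wavelet transform (sym2) to level
  3; Teager energy ψ[c](n) = c(n)² − c(n−1)c(n+1) on each detail band;
  rectification; smoothing with a symmetric 25-sample (2 ms) Hamming
  window; summation over bands. Level 3 matters at 12.5 kHz: a ~1.2 ms
  biphasic spike concentrates its energy near 0.8–1.5 kHz, which is detail
  band 3 (781–1562 Hz); stopping at level 2 leaves the dominant band in
  the approximation and costs ~7 percentage points of sensitivity on
  synthetic ground truth. As many energy peaks are selected (top-N with
  1 ms spacing) as the amplitude detector produced candidates; an energy
  peak has a constant ~2-sample group delay relative to the waveform
  trough, far below the matching tolerance, and is left uncompensated.
* **Consensus** — greedy one-to-one in-order matching of amplitude times
  against energy-peak times within ±1 ms; the amplitude detector's time is
  the canonical spike time. For sorted sequences this greedy sweep attains
  the maximum-cardinality matching (verified against an assignment-solver
  oracle in the tests).
* **Active electrodes** — strictly more than 10 spikes per minute; an
  electrode at exactly 10/min is inactive. Only active electrodes enter
  firing-rate, burst and synchrony analysis.

On simulated hPSC-like wells (40 µV mean amplitude, CV 0.2, 5 µV noise)
the chain reaches ≈97% sensitivity and ≈99.9% precision at ±1 ms; residual
misses are low-amplitude tail spikes and spikes within ~1–2 ms of a
neighbour, whose energy peaks fuse under the 2 ms smoothing.

## logISI burst detection

The histogram of log10(ISI) is built at 10 bins/decade, padded with one
zero guard bin per side (so a mode in the first or last occupied bin is
still a peak), and lowess-smoothed (fraction ≈ 4 bins, one pass, no
robustness iterations). Local maxima need a prominence of 5% of the
histogram peak — this suppresses single-bin noise wiggles that would
otherwise fabricate an intra-burst peak in tonic trains. If a peak exists
below 100 ms, every later peak is scored by the void parameter
v = 1 − h_min/√(h_p1·h_p2); among minima with v ≥ 0.7 the deepest (largest
v) sets the ISI threshold. No qualifying valley, or no intra-burst peak,
marks the electrode non-bursting (no max-ISI fallback is applied; the
electrode is simply excluded, which is the conservative reading when the
histogram gives no evidence of bursting).

Burst assembly: for ISITh ≤ 100 ms, maximal runs of ISIs ≤ ISITh; for
larger thresholds, cores are built at ISI ≤ 100 ms and extended outward
while flanking ISIs ≤ ISITh. Runs with < 5 spikes are discarded. When
ISITh < 100 ms, consecutive bursts with gaps < 100 ms are merged (100 ms
is then the minimum time between bursts); the merge is idempotent and
preserves the spikes-in-burst count.

Features per electrode: bursts/min; median burst duration; median spikes
per burst; median of (n−1)/duration per burst (the ISI-based rate is
unbiased for short bursts; n/duration is a config switch); and
100 × (spikes in bursts)/(all spikes). The well value is the median over
bursting electrodes (median-of-electrode-medians, not pooled over bursts).
A duration floor of one sample period guards the per-burst rate against
degenerate hand-built input; real trains carry a 1 ms refractory, so a
≥5-spike burst lasts ≥4 ms.

## Synchrony and connectivity

**STTC** uses Δt = 50 ms. Tiling fractions T_X are computed by an exact
merged-interval union clipped to the observation window (O(n log n));
coincidence proportions P_X by nearest-neighbour search. A term whose
denominator 1 − P·T vanishes is dropped and the remaining term(s)
averaged; empty trains make the coefficient undefined (reported absent,
never imputed). The well summary is the median over defined pairs (mean by
config). The implementation agrees with a brute-force per-pair oracle to
1e−12 and is symmetric, bounded in [−1, 1], and invariant to joint
translation.

**CorSE** reduces each channel to a spectral-entropy series: 1 s Hann
windows with 50% overlap; per window the periodogram restricted to the
analysis band (200–3000 Hz) is normalized to a probability distribution
and its Shannon entropy divided by log N_f, giving SE ∈ [0, 1] (0 = pure
tone, 1 = flat spectrum). A zero-power window takes SE = 1 (maximal
uncertainty) with a logged warning. Connectivity strength is |Pearson r|
between two channels' SE series, computed on band-passed traces by default
(the entropy then reflects in-band dynamics rather than out-of-band drift;
a config switch disables the prefilter). Constant SE series leave the pair
undefined. Synchronous bursting modulates both channels' spectral content
together, so coupled channels correlate while amplitude scaling cancels
exactly. Connectivity maps list pairs with CorSE > 0.7; the well summary
is the mean over all defined pairs.

## Features and PCA

Seven features per well × time point: MFR (mean over active electrodes of
count/duration), the five burst features, and the STTC summary. Samples
missing any feature (no active or no bursting electrodes) are dropped with
a logged reason. Columns are standard-score normalized with the population
SD (divide by n; sample SD by config) — a zero-variance feature is an
error naming the column. PCA is the eigendecomposition of the covariance
of the z-scored matrix (via SVD); all component variances are reported (so
explained percentages sum to 100) and each component's sign is fixed by
making its largest-magnitude loading positive, which makes scores
reproducible. All samples are pooled into a single decomposition. Group
segregation is the mean silhouette of the labelled groups in the first
three components, compared against a 100-permutation label null; samples
in singleton groups take silhouette 0. Pharmacology runs are summarized as
100 × (treatment − baseline)/baseline per well; a zero baseline leaves the
value undefined.

## Synthetic-data generator

The generator is the package's ground-truth instrument, not a biophysical
model. Network-burst onsets are homogeneous Poisson at the configured
rate; each electrode joins a burst with probability `participation` (0.9
by default — near-full recruitment, as in strongly synchronized mature
cultures), with onset offset Normal(0, jitter). Intra-burst spiking is
homogeneous Poisson over the burst window, so expected spikes/burst =
rate × duration is analytic; tonic background is an independent Poisson
per electrode; trains are thinned to a 1 ms refractory (keeping
≈ 1/(1 + r·τ) of spikes, a ~5% loss at ~50 Hz). Raw synthesis inserts a
biphasic template (narrow negative trough, broader positive rebound, unit
peak, ~1.2 ms) scaled by lognormal amplitudes (mean 40 µV, CV 0.2 —
low-amplitude regime typical of hPSC-derived units) into white Gaussian
noise (5 µV) with optional 50 Hz mains.

Presets encode the two phenotypes at peak activity: `hPSC_peak`
(11 bursts/min, 0.7 s bursts, intra-burst rate 34/0.7 ≈ 48.6 Hz so bursts
average ≈34 spikes, 20 ms jitter, 0.8 Hz tonic) and `rat_peak`
(15 bursts/min, 0.3 s, 100 Hz intra-burst, 10 ms jitter, 0.3 Hz tonic).
The hPSC values cannot satisfy "≈34 spikes per 0.7 s burst" and "spike
frequency in bursts < 40 Hz" simultaneously — those are medians of
different empirical distributions — and the generator fixes spikes/burst,
accepting an intra-burst rate slightly above 40 Hz.

What the generator does **not** emulate: inter-electrode propagation
delays (zero mean; jitter only), rate decay within bursts, electrode
drift, unit overlap/superposition, correlated noise, or astrocytic slow
signals. Consequences for interpretation: detection scores on synthetic
raw data bound performance under ideal template/noise assumptions, not
under real waveform diversity; and recovered burst rates read systematically
low by ~10–20% (electrodes skip (1 − participation) of network bursts, and
at 11/min some consecutive bursts fall closer than the ISI threshold and
merge), which is a property of the study conditions, not a detector fault.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` regenerate everything at run
time with fixed or CLI-provided seeds: detection validation uses one
16-electrode 60 s well plus an 8-electrode 120 s noise audit; CorSE nulls
use 50 replicates of 120 s channel pairs; the phenotype-separation
experiment uses 12 wells × 3 days per phenotype at 300 s; parameter
recovery runs at the full 600 s. A single seed fans out to per-well seeds
through `numpy.random.default_rng`; identical seeds reproduce outputs
byte-for-byte, and the pipeline manifest records config and SHA-256 hashes
of every written table.

## Known limitations

* The coupling between the amplitude detector and the SWTTEO stage is
  implemented as "top-N energy peaks with dead time", N being the
  amplitude detector's candidate count; an energy-threshold variant
  calibrated to N would behave differently in pure noise.
* logISI peak/valley decisions on sparse histograms (< ~50 ISIs) are
  noisy; such electrodes are usually classified non-bursting.
* STTC summaries on wells with < 2 active electrodes and CorSE on constant
  channels are reported absent rather than zero; downstream feature rows
  with absent entries drop out of the PCA.
* The raw-trace path at full 600 s × 64 electrodes is compute-heavy
  (~10⁸ samples/well); the spike-train path is the practical route for
  plate-scale studies.
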