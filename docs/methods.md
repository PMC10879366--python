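# Methods

## Causal preprocessing

The chain 250 Hz → (zero-stuff ×4) → 1000 Hz → order-1000 FIR low-pass →
(keep every 5th sample) → 200 Hz is implemented with
`scipy.signal.upfirdn` and truncated to its causal prefix, so output
sample *k* depends only on input at times ≤ *k*/200 s.  The FIR is a
Hamming-windowed sinc (`scipy.signal.firwin`) with cutoff 30 Hz at the
1000 Hz internal rate; only the order, the causality requirement and the
0–30 Hz target are fixed by the reference procedure, so the design method
is this package's choice, validated against an explicit contract:
passband within −1 dB up to 27 Hz, and ≥ 40 dB attenuation over
100–500 Hz (the band that would alias into the 200 Hz output).  A
symmetric (type-I) filter of order 1000 delays every frequency by exactly
500 samples at 1000 Hz = 500 ms; the acceptance script measures this
delay empirically from an impulse response.

Numerical choices worth noting:

* **Gain compensation.** Zero-stuffing by 4 scales the spectrum by 1/4;
  the filter coefficients are multiplied by 4 so that passband gain is
  unity (DC gain checked to 1e-6).
* **Decimation phase.** Internal indices ≡ 0 (mod 5) are kept.  The phase
  is not dictated by the procedure; this choice shifts output sample
  times by < 5 ms relative to other phases and is fixed for
  reproducibility.  Output length is ⌊4N/5⌋ for N input samples.
* **Startup.** The first 500 ms of output is filter settling.  The full
  output is returned, but preprocessed recordings carry a
  `settled_from_s` flag (start + 1 s) and the segmentation stage drops
  any analysis window that starts before it.
* **Timestamps.** Output sample *k* carries the time of the newest input
  sample it can depend on; its *content* represents the input 500 ms
  earlier.  This is the natural convention for an online monitor, where
  the delay is a property of the display, not of the clock.

## Ordinal encoding

A pattern is the permutation sorting (x_i, x_{i+τ}, …, x_{i+(m−1)τ})
ascending, coded as the 0-based lexicographic rank of that permutation
(Lehmer code of the stable argsort).  Any fixed bijection between
permutations and integers would do — only pattern *frequencies* enter the
entropies — but the convention is pinned down so that an independent
brute-force oracle (explicit enumeration of all 120 permutations) can be
tested against.  Ties are broken by temporal order (earlier sample ranks
lower, via stable sort); on real-valued EEG with measurement noise ties
are measure-zero, so the rule only matters for determinism on synthetic
or quantized input.

Windows are defined on EEG-sample time: a 30 s window at 200 Hz holds
6000 samples, and a pattern belongs to a window iff all of its m samples
lie inside, giving 6000 − (m−1)τ = 5996 patterns per channel per window.
The reference text prints 5960 patterns per window for the same
parameters, which is inconsistent with N − (m−1)τ; this package
implements the formula.  Each window is stamped at its rightmost
underlying EEG sample (end-of-sample convention: the first full window of
a recording starting at t = 0 is stamped 30 s), and consecutive windows
are shifted by 1 s, putting all score series on a 1 s grid.

## Entropy estimation

All entropies are plug-in (maximum-likelihood) estimates in bits.  The
transfer entropy of a source/target pair at delay δ is computed from the
single empirical distribution of triples (X_t, Y_t, Y_{t+δ}) over
t = 0…len−1−δ; the four entropy terms are its marginals.  Computing all
terms from one distribution (rather than counting each term over its own
maximal index range) guarantees TE ≥ 0, because the combination is then
the conditional mutual information I(Y_{t+δ}; X_t | Y_t) of a single
distribution.  Values within −1e-9 of zero are clamped to 0 (float
round-off only).

Per 30 s window: 4 fronto-parietal pairs × 6 delays × 2 directions = 48
TE estimates; TE uses only within-window tuples (windows are the unit of
computation, no spill across edges).  δ is applied on the 200 Hz pattern
grid, so δ = 7…12 is 35…60 ms.  PE is the mean pattern entropy of Fp1 and
Fp2.  Scores are unnormalized bits (log base 2); whether reference scores
were bits or nats is not stated anywhere and affects only a constant
factor, which cancels in threshold-based classification.  A
`normalize_pe` flag divides PE by log2(m!) for 0–1 display.

The plug-in estimator is biased low for entropies (≈ (K−1)/(2N ln 2) for
K symbols, N observations) and biased *up* for TE on independent data;
no bias correction or surrogate normalization is applied, matching the
plain counting recipe.  The bias is the same for both transfer directions
under the null, so directional *comparisons* are unaffected; the PE bias
for K = 120, N = 5996 (≈ 0.014 bits) is verified by Monte-Carlo in the
test suite.

## Synthetic cohort

The generator stands in for clinical induction/emergence EEG, which is
not publicly available.  Each channel is

y_c(t) = w(t)·a_c(t) + (1 − w(t))·s_c(t) + ε(t),

where a_c is a stationary AR(2) with spectral peak at 10 Hz (pole radius
0.95) and unit-SD innovations, s_c an AR(2) peaking at 1.5 Hz (pole
radius 0.98) with 3× innovation amplitude — the larger, far more regular
slow-wave signal — and ε white noise at 5% of the awake signal SD (which
makes ordinal ties measure-zero).  w(t) = 1 − σ((t−LoR)/s)·σ((RoR−t)/s)
is built from two logistic edges of scale s = 10 s, consistent with an
entropy decline over roughly a minute around LoR.  Parietal channels
additionally receive g(t)·[Fp1(t−L) + Fp2(t−L)]/2 with L = 10 samples
(40 ms at 250 Hz, inside the 35–60 ms transfer-delay band after
resampling) and g interpolating between 0.4 (awake) and 0.05
(anesthetized) via the same w(t).

Default cohort conditions: 20 patients, 300 s per recording, LoR drawn
uniformly in [60, 120] s and RoR in [duration−120, duration−60] s.  The
recording length is scaled to a desk-size experiment — long enough for
stable awake and anesthetized plateaus plus both transitions — rather
than to surgical durations.  Determinism: patient i of a cohort uses seed
`master_seed + i`, and identical (config, seed) reproduce recordings
bit-identically.

What the generator does **not** emulate: biophysically realistic EEG
(no neural mass dynamics), artifacts/EMG/eye blinks, substance-specific
emergence heterogeneity, inter-patient spectral variability, or
non-stationarity within a regime.  Passing tests on this cohort show the
pipeline recovers effects *designed into* the data (regime ordering of PE
and STE, coupling direction, near-perfect LoR separation); they say
nothing about effect sizes or accuracies on clinical EEG, where overlap
between states is far larger.  On this synthetic cohort both PE and STE
classify essentially perfectly, so the paired STE − PE accuracy
difference is ~0 with a CI covering zero.

## Statistical analysis

* **Time points.** T1 = LoR−15 s, T2 = LoR+30 s, T3 = RoR−15 s,
  T4 = RoR+30 s; with 30 s right-edge-stamped windows, T1's window is the
  last containing only awake EEG and T2's the first containing none.
  Target times are matched to the nearest 1 s grid point, required within
  0.5 s.
* **Threshold.** Candidates are midpoints between consecutive distinct
  pooled T1/T2 scores plus sentinels below the minimum and above the
  maximum; the smallest candidate maximizing LoR accuracy is selected
  (the candidate grid and tie rule are this package's choices; the
  reference procedure fixes only "maximize LoR accuracy").  Scores
  strictly above the threshold are "positive for wakefulness"; ties at
  the threshold are negative.  The one LoR-derived threshold is reused
  for the RoR and combined contrasts.
* **Bootstrap.** Percentile bootstrap, default B = 10,000 at 95%; the
  resampling unit is the patient with all four time points, the only
  exchangeable unit in this design.  The threshold is *not* re-selected
  inside replicates — it is fixed once, as in the reference analysis —
  which makes the interval slightly optimistic about the threshold's
  out-of-sample validity (a documented caveat, not a bug).  Differences
  between two scores' accuracies use paired resamples: one patient draw
  per replicate, both accuracies recomputed on it.

## Degenerate inputs and edge rules

Empty windows, all-zero count vectors, δ ≥ sequence length, misaligned
pattern sequences, non-finite samples (reported with the offending
index), wrong sampling rates (no silent inference) and missing channels
(reported by name) all raise typed errors.  EDF writing requires an
integer sampling rate and truncates to whole 1 s records; samples are
quantized to 16 bits over a symmetric physical range padded by 1%.

## Problem sizes

The test suite runs the full chain on the default 20-patient cohort once
(shared fixture, ~1.5 min) and uses shorter recordings (40–150 s)
elsewhere; the oracle and analytic checks use sequences of 50–100,000
symbols.  These sizes were chosen so every statistical check has adequate
power while the whole suite stays interactive.
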