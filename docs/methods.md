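# Methods and design notes

This note documents the model choices, parameter conventions and numerical
decisions behind `cwdetect`, and what the synthetic-data results do and do
not establish about real recordings.

## The detection scheme

Myocardial ischemia expresses on the ECG as a level shift of the ST segment
relative to the PR segment, which acts as the voltage reference. Rather than
locating fiducial points beat by beat, the scheme treats each 1-minute,
single-lead interval as one analysis unit: the interval's energy is spread
over the time-frequency plane with the Choi-Williams distribution (CWD),
the negative part is truncated, and the ST-related (11–14 Hz) and PR-related
(5–8.5 Hz) band shares become a two-dimensional feature classified by a
multi-class SVM per lead, with majority fusion across leads. Working on
minutes rather than beats removes the need for QRS/ST delineation entirely
and averages away transient noise.

## Discrete Choi-Williams distribution

The discrete CWD used throughout is

    CWD(n, ω) = 2 Σ_k e^{-2iωk} Σ_m √(σ/4πk²) e^{-σ(m−n)²/4k²} x(m+k) x*(m−k)

with the following conventions, shared exactly by the fast path
(per-lag convolution + FFT) and the brute-force oracle (`cwd_reference`,
literal nested sums + explicit DFT matrix), which agree to ~1e-15 relative:

* **Analytic signal first.** Real input is converted via the Hilbert
  transform; otherwise negative-frequency interference destroys tone
  localization. Complex input is taken as already analytic.
* **k = 0 smoothing window is a Kronecker delta** — the k → 0 limit of the
  Gaussian. This makes the discrete time marginal *exactly* the
  instantaneous power |s(n)|² at every analyzed instant.
* **Lag window**: finite odd length (default 127 samples) under a Hamming
  taper. The taper slightly smooths the frequency marginal (it leaves the
  time marginal untouched because its k = 0 value is 1).
* **μ-window truncation**: the Gaussian at lag k is cut where it falls below
  1e-4 of its peak, i.e. at |m−n| > 2|k|√(ln 10⁴/σ) ≈ 6.07|k|/√σ, and is
  *not* renormalized (the literal kernel weights are used; their discrete
  sum is within a few percent of unity for σ ≤ 1).
* **Normalization**: values are scaled by 1/fs so Riemann sums reproduce the
  marginals: Σ_j CWD·Δf = |s(n)|², Σ_n Σ_j CWD·Δf·Δt = signal energy. Both
  hold only for the *untruncated* matrix; the marginal operations refuse a
  truncated input by contract.
* **Frequency axis**: n_freq + 1 bins spanning [0, fs/2] inclusive
  (Δf = fs/2n_freq). The discrete distribution is fs/2-periodic in
  frequency, so the endpoint bin duplicates bin 0; for band-pass-filtered
  ECG content (≤ 35 Hz at fs = 250) this bin carries essentially no energy.
  Riemann sums over frequency use the first n_freq bins.
* **Edges**: samples outside the record are zero (windows shrink); slices
  within one lag window of either end are flagged via `edge_mask`, and the
  marginal tests evaluate only the central half.
* **Defaults**: σ = 1 (no value is canonical for ECG; σ controls the
  cross-term/resolution trade-off and the feature bands are broad),
  n_freq = 256 (0.49 Hz bins comfortably resolve the 5–8.5 and 11–14 Hz
  bands), time_decimation = 4 in the pipeline configuration (one slice per
  16 ms; band means over a minute are insensitive to this for
  quasi-stationary content, and it keeps a 15000-sample segment at ~3750
  slices). The raw `cwd()` function defaults to no decimation, since the
  exact marginal identities are stated on the full grid.

The oracle is deliberately a different algorithm, not a refactoring: direct
summation over (t, k, μ) with an explicit e^{-2iωk} matrix, guarded to
≤ 256 samples.

## Preprocessing

* Resampling to 250 Hz uses rational polyphase filtering (anti-aliased).
* Baseline removal: 0.5 Hz high-pass, windowed-sinc FIR, 2001 taps at
  250 Hz; the taps are mean-subtracted to place an exact null at DC.
* Muscle-noise/mains suppression: 2–35 Hz band-pass FIR, 501 taps. The upper
  edge keeps the feature bands (≤ 14 Hz) far inside the passband while
  removing 50/60 Hz mains and most EMG energy.
* Both filters are applied forward-backward (zero net group delay — segment
  timing is preserved; attenuations double relative to single-pass).
  Measured: ≥ 105 dB at 0.1 Hz for the high-pass, ≥ 145 dB at 50 Hz for the
  band-pass, ≤ 0.02 dB passband loss at 10 Hz for both.
* Scaling is a per-lead z-score over the *whole record*, not per segment:
  the intent is removal of acquisition gain differences between set-ups, and
  a record-level statistic cannot leak class information between a record's
  segments. Filtering precedes scaling so the scale is set by the retained
  band.
* Segmentation takes consecutive non-overlapping 60 s windows; a trailing
  remainder is dropped (band means are length-sensitive, so padding would
  bias them).

## Features

`p_st` and `p_pr` are the mean positive-part CWD density over the 11–14 Hz
and 5–8.5 Hz bands (bin-center membership, closed intervals), divided by the
0–35 Hz full-band mean and multiplied by 100. The full post-filter band is
the only defensible normalization support after a 2–35 Hz band-pass.
Normalization is per segment, making every minute self-contained.

Note that this mean-ratio definition is a *relative density* percentage, not
a fraction of total power: a band whose mean density exceeds the full-band
mean yields a value above 100 (typical conditioned ECG gives p_st ≈ 160–190,
p_pr ≈ 230–260, because most full-band bins above 14 Hz are nearly empty).
Only non-negativity is an invariant. Combined with the z-scoring, the
features are invariant to any positive gain on the raw record (verified to
1e-6).

## Classifier

Each lead carries K(K−1)/2 binary soft-margin SVMs (one per class pair).
The binary dual problems are solved by scikit-learn's `SVC` (libsvm); the
one-vs-one assembly, decision-value evaluation from the stored support
vectors, lead fusion, metrics, and cross-validation are implemented here.
Trained machines are checked against the dual feasibility conditions
0 ≤ αᵢ ≤ γ and Σαᵢyᵢ = 0 (tolerance 1e-6).

* **Kernel**: Gaussian RBF, exp(−‖x−xᵢ‖²/2σ²) with σ = 0.1. Features are
  min-max scaled to [0, 1] using training-set statistics stored in the
  model, so σ = 0.1 is a meaningful relative length scale.
* **Cost**: γ = 10 by default (configurable). The synthetic classes are
  near-separable, so results are insensitive to γ over orders of magnitude.
* **Fusion**: pairwise majority per lead, then majority across leads, ties
  broken toward the label with the larger summed |R| margin. With two
  classes the machine reduces exactly to one binary SVM (verified against a
  direct `SVC` fit).
* **Metrics**: sensitivity/specificity pool the non-normal classes as
  "positive". Cross-validation is stratified by record label and split by
  record id, so the minutes of one record never appear on both sides.

## Synthetic data: what it emulates and what it does not

The generator produces beats as five Gaussian bumps (P, Q, R, S, T) with
explicit piecewise-constant level plateaus on the ST window
([S center + 40 ms, T center − 50 ms]) and PR window
([P center + 30 ms, Q center − 20 ms]) — chosen over a dynamical ODE model
because it gives direct, auditable control of exactly the quantities the
features measure. Condition presets: ST +0.15 mV (elevation ischemia),
−0.15 mV (depression ischemia), +0.30 mV with inverted T (infarction-like);
these magnitudes are generator conventions in the clinically typical range
(0.1–0.3 mV), not values taken from any particular patient population.
RR intervals jitter by a truncated Gaussian (sd 3% of the mean, clipped to
±10%) so minute-level beat counts stay stable; leads differ by seeded gains
in [0.7, 1.3]; noise adds a 0.25 Hz baseline sinusoid (0.10 mV), 50 Hz mains
(0.02 mV), and 20–100 Hz band-limited Gaussian muscle noise (0.03 mV input
sd) — the default amplitudes are moderate, realistic levels for resting
multi-lead acquisition.

Consequences for interpretation: the synthetic classes are *much* cleaner
than clinical data — no electrode motion artifacts, no within-record
morphology drift, no arrhythmia, no lead-specific waveform shapes, and the
ST shift is constant over a record. Passing tests therefore establish the
*correctness of the machinery* (transform, features, classifier, plumbing)
and the *direction and detectability* of the ST spectral signature, not
clinical performance. Held-out accuracy near 100% on this corpus is the
expected behavior of a correct implementation under near-separable classes,
and the permutation control confirms it is earned from the labels: because
within-class feature variance is tiny, a permuted-label model produces
cluster-coherent (all-or-nothing) predictions, so chance is assessed as the
mean over a 12-permutation ensemble (≈ 1/3) with its empirical standard
error rather than a per-minute binomial interval.

## Degenerate inputs and tie-breaks

All-zero segments yield (0, 0) features with a warning; constant leads
z-score to zeros with a warning; empty frequency bands and non-positive
kernel/cost parameters are rejected up front; per-segment extraction
failures in batch mode are logged and skipped rather than aborting. Vote
ties at either fusion level resolve by the larger accumulated |R| margin;
a remaining exact tie resolves lexicographically via the vote dictionary
ordering (deterministic).

## Problem sizes

The test suite and the acceptance script run on deliberately desk-scale
problems — oracle comparisons at ≤ 128 samples, marginal checks on 2 s
tones, and a corpus of 60 synthetic minutes per class (two leads) — chosen
so the full chain, including the quadratic-cost oracle, re-runs in about a
minute on one CPU. The implementation itself handles the native scales
(e.g. 120-minute records at 250 Hz) through the same code paths.

## Known limitations

* WFDB support covers the single-segment format-16 subset (gain/baseline
  applied on read) — enough for Physionet-style interoperability, not the
  full header grammar; no annotation files.
* No arrhythmia handling: the scheme classifies ST/PR spectral shares and
  is blind to rhythm disorders by design.
* The CWD σ, lag window and frequency-bin count have no single canonical
  values for ECG; defaults are documented above and configurable, and the
  cross-term suppression test pins down the qualitative behavior of σ.
* Amplitude units are assumed to be mV throughout.
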