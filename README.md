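# cwdetect

Automated screening for **myocardial ischemia** from multi-lead, long-interval
ECG. Ischemia shifts the ST segment of the ECG relative to the PR reference
level; instead of measuring that shift beat by beat in the time domain,
`cwdetect` analyses whole **1-minute intervals** in the time-frequency plane
and classifies each minute — a morphology-detection-free approach that needs
no QRS detector and is robust to the noise sources that plague beat-level
methods.

The package is aimed at biomedical-signal-processing researchers and
engineers who want a tested, fully reproducible implementation of the scheme:
every stage is an importable function, a seeded synthetic ECG generator
stands in for clinical recordings, and a thin CLI covers batch use.

## Method

For each lead of a conditioned record (resampled to 250 Hz, 0.5 Hz FIR
high-pass, 2–35 Hz FIR band-pass, per-lead z-scoring), each 1-minute segment
x(n) is mapped through:

1. **Discrete Choi-Williams distribution (CWD)** — the Cohen's-class
   bilinear distribution with exponential kernel,

   ```
   CWD(n, ω) = 2 Σ_k e^{-2iωk} Σ_m √(σ/4πk²) · e^{-σ(m-n)²/4k²} · x(m+k) x*(m-k)
   ```

   computed on the analytic signal. The kernel parameter σ trades
   time-frequency resolution against suppression of the oscillatory
   cross-terms that arise between genuine components. The implementation
   satisfies the marginal identities (frequency integral = instantaneous
   power, time integral = energy spectrum, double integral = signal energy)
   and is verified against a literal brute-force evaluation of the double
   sum.

2. **Positive-part truncation** — negative elements of the CWD matrix (the
   cross-term residue) are zeroed; the component information lives in the
   positive part.

3. **ST/PR band-power features** — the mean truncated-CWD density over the
   **11–14 Hz (ST)** and **5–8.5 Hz (PR)** bands, normalized by the
   full-band (0–35 Hz) mean and expressed as percentages `(p_st, p_pr)`.

4. **One-vs-one multi-class RBF-SVM** — per lead, K(K−1)/2 pairwise binary
   SVMs over the scaled feature pair with Gaussian kernel
   `K(x, xᵢ) = exp(−‖x−xᵢ‖²/2σ²)` (σ = 0.1 on min-max–scaled features).
   A test minute's decision value per pair is `R = Σ_{i∈SVs} Wᵢ K(x, xᵢ) + b`;
   sign(R) votes, a pairwise majority labels the lead, and a majority across
   leads ("cross-matching") gives the fused label
   {normal, ischemia, infarction}.

Evaluation reports accuracy plus pooled sensitivity/specificity (positive =
ischemia or infarction) and supports record-stratified k-fold
cross-validation (the minutes of one record never straddle folds).

## Worked example

`examples/` holds one short script per capability. End to end
(`python examples/04_train_and_detect.py`): train on a seeded synthetic
corpus of 5 records per class (2 minutes, 2 leads each), then screen two
unseen records:

```
training confusion matrix (rows = truth, columns = prediction):
            infarction  ischemia  normal
infarction          10         0       0
ischemia             0        10       0
normal               0         0      10
training accuracy: 1.000

unseen-normal: per-minute fused labels ['normal', 'normal', 'normal', 'normal'] -> 0% of minutes flagged
unseen-ischemia_st_elev: per-minute fused labels ['ischemia', 'ischemia', 'ischemia', 'ischemia'] -> 100% of minutes flagged
```

Every row of the confusion matrix is one class's minutes; the per-minute
fused labels show the detector's screening output — the fraction of flagged
minutes is what a reviewer would act on. `examples/02_time_frequency_analysis.py`
prints the cross-term level shrinking monotonically as σ decreases
(0.257 → 0.024 over σ = 10 → 0.01) and the marginal identities holding to
machine precision; `examples/03_extract_features.py` shows the ischemic
record's p_st sitting ~26 percentage points above normal with within-class
spreads under 1 point.

The same stages are scriptable:

```bash
cwdetect synth --condition ischemia_st_elev --minutes 2 --leads 2 --seed 5 --out rec.csv
cwdetect preprocess --in rec.csv --out pre.csv
cwdetect features --in pre.csv --preprocessed --out features.csv
cwdetect train --features features.csv --model model.json
cwdetect classify --model model.json --record rec.csv
cwdetect crossval --features features.csv --k 10
```

## Layout

```
src/cwdetect/
  records.py     ECG record + feature-table model, CSV/WFDB I/O
  synth.py       seeded synthetic ECG generator (morphology + noise)
  preprocess.py  resampling, FIR filters, scaling, 1-min segmentation
  tfd.py         discrete Choi-Williams distribution + brute-force oracle
  features.py    ST/PR band-power feature extraction
  svm.py         one-vs-one RBF-SVM, lead fusion, metrics, CV
  pipeline.py    end-to-end training / detection orchestration
  cli.py         command-line verbs
examples/        one narrative script per capability
tests/           pytest suite (unit, property, acceptance)
docs/methods.md  modelling and design notes
```
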