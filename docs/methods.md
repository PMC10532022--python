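# Methods

`pwvnet` classifies short single-lead ECG segments into four rhythm classes
— normal sinus rhythm (Normal), ventricular tachycardia (VT), ventricular
fibrillation (VF) and a rest class (Other) — and collapses the result into
the binary decision that matters for defibrillation: shockable (VT/VF)
versus non-shockable. The discriminative representation is a quadratic
time–frequency image of each analysis window, classified by a small CNN.
This note records the model, the defaults, the numerical choices, and the
places where the design was genuinely open.

## Preprocessing

Records are resampled to a fixed working rate of 125 Hz by polyphase
band-limited interpolation (`scipy.signal.resample_poly` at the exact
rational ratio); per-sample labels travel by nearest neighbour. The output
length is `round(n · fs_target / fs)`; the polyphase result (which is
`ceil`) is trimmed or edge-padded by at most one sample to meet that
contract.

Denoising is a single 8-pole Butterworth band-pass, 1–45 Hz, realized as
cascaded second-order sections and applied **causally** (single pass).
The band removes baseline wander (< 1 Hz), both 50 and 60 Hz power-line
interference, and resting EMG energy above 45 Hz. Two decisions here were
open:

* "8th order" is read as eight poles total for the band-pass, i.e. a
  4th-order low-pass prototype — the usual reading of "8th-order IIR
  band-pass".
* Causal rather than zero-phase filtering: the intended deployment is
  real-time rhythm analysis in an AED-like loop, where forward–backward
  filtering is unavailable (and would double the effective order). The
  constant group delay this introduces in the passband (≈ 1–2 samples at
  QRS frequencies) is irrelevant to windows cut relative to detected marks.

The filter's steady-state gain is checked in the tests against the exact
closed form of a bilinear-transform Butterworth band-pass: with
`W = tan(π f / fs)` and prewarped edges `W₁, W₂`,
`|H|² = 1 / (1 + u⁸)` where `u = (W² − W₁W₂) / ((W₂ − W₁) W)`. The naive
analog-prototype formula evaluated at the physical frequency is *not* the
response of any digital 8-pole design near Nyquist (it errs by four orders
of magnitude at 60 Hz) and is not used.

## Segmentation: Window Reference Marks

Analysis windows are 1.2 s long — exactly 150 samples at 125 Hz — and open
at Window Reference Marks (WRMs). Consecutive marks are constrained to
0.5–1.2 s apart, the RR-interval range of a 50–120 bpm heart rate.

The mark detector is an energy-peak detector:

1. detection function `d = MA₁₂₀ₘₛ(|x|)` (rectified filtered signal,
   centred 120 ms moving average);
2. candidate marks are local maxima of `d` above `0.3 ×` a centred rolling
   2 s maximum of `d`;
3. a 0.5 s refractory (⌈0.5 × 125⌉ = 63 samples) resolves conflicts in
   favour of the larger candidate;
4. any surviving gap longer than 1.2 s is filled with the largest interior
   local maximum that respects the refractory on both sides, repeated to
   a fixed point.

Windows are labeled with the class active at their mark sample (the mark
denotes window onset), and marks closer than 1.2 s to the record end are
dropped (counted, not erred).

Known limitation, by construction: at heart rates above ≈ 115 bpm the RR
interval (≤ 0.52 s) collides with the 0.5 s minimum mark distance, so not
every beat can legally receive a mark; beat coverage measured on synthetic
normal rhythm drawn uniformly from 50–120 bpm is ≈ 99% within ±3 samples,
dropping only in that top band. This is a property of the mark-spacing
contract, not of the detector.

## Time–frequency representation

Each window `w` is transformed to a Pseudo Wigner–Ville (PWV) distribution.
With `s` either the analytic signal `w + jH[w]` (Hilbert variant) or `w`
itself embedded as complex (ablation variant):

```
PWV[n, k] = 2 · Re Σₘ h[m] · s[n+m] · s*[n−m] · e^(−j2πkm/N)
```

lags `m ∈ [−(L−1)/2, (L−1)/2]`, `N = 150`, samples outside the window
taken as zero. Row `k` maps to frequency `k · fs / (2N)` — the lag pairing
`(n+m, n−m)` advances phase at twice the signal frequency, doubling the
density of the frequency grid. The implementation performs one FFT per
time instant over the kernel-weighted instantaneous autocorrelation, with
negative lags wrapped into the upper FFT bins; it is exactly the direct
lag sum (tested to 1e−9 against a triple-loop evaluation) at O(N² log N)
instead of O(N³).

Numerical/model choices:

* **Second factor conjugated at `−τ/2`.** The product is
  `S(t+τ/2) S*(t−τ/2)`, the standard Wigner–Ville bilinear form; the
  degenerate alternative `S(t+τ/2) S*(t+τ/2)` has no frequency resolution
  at all.
* **Analytic signal.** Computed as `x + j·Im(hilbert(x))` so the real part
  is bit-exact; the FFT Hilbert transformer leaves < 1e−10 of the energy
  on negative-frequency bins. Without it, a real window's negative
  frequencies mirror into the distribution and beat against the positive
  ones — the ablation variant exists to demonstrate exactly that.
* **Smoothing kernel.** Lag window `h`: symmetric, odd length, peak 1.
  Default Hamming of length 37 (≈ N/4), the conventional pseudo-WV
  trade-off between cross-term suppression and frequency resolution at
  this window length. `h ≡ 1` over all representable lags gives the
  unsmoothed WV (used by the marginal-property test
  `Σₖ WV[n,k] = 2N |s[n]|²`).
* **Image mapping.** The 1–45 Hz band of the 150-row matrix is linearly
  interpolated onto a 1 Hz row grid (45 rows, row 0 ↦ 1 Hz), negative WV
  values are clipped to 0, and each image is min–max normalized to [0, 1]
  (constant → all zeros). How the reference pipeline reduced 150 bins to
  45 rows is not specified anywhere; interpolation is the choice that is
  monotone, shape-preserving and axis-exact.
* **Classifier input.** The 45×150 image is bilinearly resized (separable,
  endpoint-aligned grids) to 180×180. That size is not arbitrary: it is
  the only input side consistent with the published dense-layer parameter
  counts of both classifier heads (180² · 512 + 512 = 16,589,312 and
  11·11·64 after two 4× poolings of 180).

## Classifiers

Two fixed architectures over the 180×180×1 input, four-way softmax output,
class order `[Normal, Other, VT, VF]` everywhere:

* **CNN1** — Flatten → FC 512 → FC 256 → softmax 4 (a dense head only).
* **CNN2** — Conv 3×3×32 (same, stride 1) → MaxPool 4×4/4 →
  Conv 3×3×64 → MaxPool 4×4/4 → Flatten (11·11·64 = 7744) → FC 128 →
  FC 256 → softmax 4.

ReLU follows every convolution and hidden dense layer; no dropout or batch
normalization. Per-layer trainable-parameter counts are exposed
(`layer_param_count`) and pinned in tests: CNN2
{320, 0, 18 496, 0, 991 360, 33 024, 1 028}, CNN1 {16 589 312; 131 328;
1 028}. A 4-class softmax head on 256 features has 1 028 parameters;
a printed count of 1 285 would imply a 5-unit head and is not reproducible
for this task.

The training engine is a small numpy framework written for this package:
im2col + GEMM convolutions with buffers reused across steps (the cost on
one CPU is memory traffic over the first convolution's 180×180×32
activation, not arithmetic), max-pooling by strided slices, softmax
cross-entropy, and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with bias
correction. Backpropagation is validated against finite differences of an
independent float64 re-implementation of the forward pass. On backward,
a tie inside a pooling window duplicates the gradient to every maximum;
ties at exactly 0 (the common ReLU case) are then zeroed by the ReLU mask,
so the only approximation concerns exactly-equal positive float32
activations, which have measure ≈ 0. All initialization (Glorot uniform)
and shuffling is driven by explicit seeded generators; identical seeds give
bitwise-identical runs on one machine/BLAS.

Training defaults: Adam learning rate 1e−3, batch 32 — unstated in the
reference protocol, chosen as the Adam conventions and configurable —
and categorical cross-entropy, 100 epochs by default (50 and 100 are the
protocol's settings; the desk-scale experiment below uses 30).

## Evaluation protocol and metrics

Stratified repeated holdout: per class, `round(0.67 · n_c)` items train and
the rest test, repeated 5 times with fresh seeded selections, metrics
averaged arithmetically over repeats. Metrics are one-vs-rest per class,
in percent: accuracy (TP+TN)/(all), sensitivity TP/(TP+FN), specificity
TN/(TN+FP), F-score 2TP/(2TP+FP+FN). "Global" specificity pools all
non-target classes; per-class specificity against class c′ is the fraction
of c′ items not predicted as the target. Shockable metrics collapse
{VT, VF} → positive and {Normal, Other} → negative *before* counting, so a
VT window called VF is not an error. Any metric with an empty denominator
is reported as missing (`None`), never coerced to 0 or 100.

## Synthetic data

The generator produces parametric template waveforms — not a
differential-equation heart model — so every stage and the end-to-end
classifier can be exercised without clinical data:

* **Normal**: P–QRS–T template train at 50–120 bpm, ±5% RR jitter. The QRS
  is a Gaussian derivative (σ = 18 ms, ≈ 1 mV peak): time-localized and
  broadband, which is what makes its time–frequency signature a vertical
  stripe. P (0.15 mV, −160 ms) and T (0.30 mV, +250 ms) are Gaussian bumps.
* **VT**: wide-complex quasi-sinusoid at 150–250 bpm (2.5–4.2 Hz) with 2%
  slow frequency jitter, a second harmonic, and slow amplitude modulation.
* **VF**: oscillation whose frequency performs a per-cycle random walk
  (reflected at the 4–7 Hz band edges, steps ~N(0, 0.5 Hz)) with per-cycle
  amplitude modulation (0.5–1.2×, smoothed).
* **Other**: either an atrial-arrhythmia-like irregular narrow-complex
  train (RR uniform 0.35–0.75 s, σ_QRS = 12 ms, no P/T, 5–8 Hz
  fibrillatory ripple at 0.12 mV) or structured motion-artifact noise
  (low-pass-filtered telegraph swings plus noise bursts).

Every record adds baseline wander (0.12 mV, 0.15–0.45 Hz), 50 Hz power-line
interference (0.05 mV) and white EMG-like noise (0.02 mV RMS). Defaults:
fs = 250 Hz (so the resampler is always exercised) and duration 2.0 s — an
AED-style short analysis snippet that reliably yields at least one full
1.2 s window per record (≈ 1.3 on average).

What passing tests on this data do **not** show: real ECG exhibits
morphology variability across patients and electrodes, rhythm transitions
inside a window, polymorphic VT, coarse-vs-fine VF, and recording
artifacts correlated with the rhythm — none of which the templates
emulate. Results on the synthetic classes demonstrate that the pipeline's
stages compose correctly and that the representation separates the four
template families; they say nothing quantitative about clinical
performance. Real WFDB records can be substituted anywhere an `EcgRecord`
is accepted (`pwvnet.io.read_wfdb` + `labels_from_annotations` with a
user-supplied rhythm-string map).

## Desk-scale experiment sizes

The end-to-end check (also recomputed by `scripts/acceptance.py`) uses 300
records per class (≈ 1 500 windows), the Hilbert + PWV + CNN2 variant, a
single stratified 67/33 holdout and 30 epochs — sizes chosen so the whole
experiment is a single-CPU desk-scale run while keeping per-class test
counts in the hundreds. Expected behaviour on the synthetic classes is
≥ 90% four-class holdout accuracy and ≥ 95% shockable sensitivity; typical
runs land well above both bounds.

## Known limitations

* The WRM detector is a documented stand-in for an unnamed "pre-existing"
  QRS detector; it satisfies the stated spacing contract but is not a
  validated clinical QRS delineator.
* Clinical-scale replication of published performance tables requires the
  MIT-BIH malignant-ventricular-arrhythmia and (licensed) AHA databases
  and is out of scope here.
* The WFDB reader covers single-file records in formats 16 and 212 and
  MIT-format annotations; multi-segment and multi-file records are not
  supported.
* The CNN engine targets exactly these two small architectures; it is not
  a general deep-learning library (no dilation, striding ≠ 1 convolutions,
  or GPU path).
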