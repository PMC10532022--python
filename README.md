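# pwvnet

Detection and discrimination of ventricular arrhythmias — ventricular
fibrillation (VF) and ventricular tachycardia (VT) — from short single-lead
ECG segments, using Pseudo Wigner–Ville time–frequency images classified by
small convolutional networks. The shockable/non-shockable decision this
supports is the one an automated external defibrillator (AED) or ICD has to
make: VT and VF are shockable; normal sinus rhythm and other rhythms are
not.

The package is aimed at biomedical-signal researchers who want a complete,
testable implementation of this pipeline that runs on synthetic data out of
the box and accepts PhysioNet WFDB records for real experiments.

## Method

1. **Preprocess** — resample to 125 Hz; causal 8-pole Butterworth band-pass
   1–45 Hz (removes baseline wander, 50/60 Hz interference, EMG noise).
2. **Segment** — detect Window Reference Marks (energy peaks, 0.5–1.2 s
   apart) and cut a 1.2 s / 150-sample window at each mark.
3. **Transform** — per window `w`, form the analytic signal
   `S = w + jH[w]` (Hilbert transform `H` suppresses negative-frequency
   mirror terms) and compute the Pseudo Wigner–Ville distribution

   ```
   PWV[n, k] = 2 Re Σₘ h[m] S[n+m] S*[n−m] e^(−j2πkm/N),   N = 150,
   ```

   with a Hamming lag window `h` (length 37) suppressing cross-terms; map
   the 1–45 Hz band to a 45×150 image, clip negatives, min–max normalize,
   and resize bilinearly to the 180×180 classifier input.
4. **Classify** — CNN1 (dense head: FC 512 → FC 256 → softmax 4) or CNN2
   (Conv 3×3×32 → pool 4×4 → Conv 3×3×64 → pool 4×4 → FC 128 → FC 256 →
   softmax 4), trained with Adam and categorical cross-entropy.
5. **Evaluate** — stratified 67/33 holdout repeated 5 times; per-class
   one-vs-rest sensitivity/specificity/accuracy/F-score and shockable
   (VT+VF vs rest) metrics, averaged over repeats.

Three pipeline variants are exposed: `TFR_CNN1` (no Hilbert, dense head),
`Ht_TFR_CNN1`, and `Ht_TFR_CNN2` (the reference configuration). See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
import pwvnet as pw

records, _ = pw.generate_dataset(n_per_class=60, seed=42)   # 240 labeled records
result = pw.run_experiment(records, variant="Ht_TFR_CNN2",
                           epochs=12, repeats=1, seed=5)
cm = result.report.confusions[0]
print(cm.counts)
print("4-class accuracy: %.1f%%" % (100 * np.trace(cm.counts) / cm.total))
print(pw.shockable_metrics(cm))
```

prints (class order Normal, Other, VT, VF; rows = truth):

```
[[21  1  0  0]
 [ 0 23  0  0]
 [ 0  0 23  1]
 [ 0  0  1 24]]
4-class accuracy: 96.8%
{'sensitivity': 100.0, 'specificity': 100.0, 'accuracy': 100.0}
```

The confusion matrix counts test windows: no Normal/Other window lands in
the shockable class and no VT/VF window escapes it (shockable sensitivity
and specificity both 100%), while the three 4-class errors are one
Normal→Other confusion and a VT↔VF swap — neither of which changes the
shock decision.

A command-line interface mirrors the stages:

```sh
pwvnet generate --n-per-class 10 --seed 1 --out data/
pwvnet segment --in data/vf-0003.csv --out windows.h5
pwvnet tfr --in windows.h5 --out images.h5 --png-dir tfri/
pwvnet evaluate --records data/ --variant Ht_TFR_CNN2 --epochs 30 --out report/
```

Real data: `pwvnet.io.read_wfdb` reads single-lead WFDB records (formats 16
and 212) and `labels_from_annotations` maps MIT-format rhythm annotations
(e.g. `"(N"`, `"(VT"`, `"(VF"`) to the four classes via a user-supplied
dictionary.

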