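# kcdetect

Automatic detection of **K-complexes** in single-channel sleep EEG, built on
recursive, reassigned Cohen-class time–frequency analysis and a small
from-scratch multilayer perceptron.

## Who this is for

K-complexes — biphasic stage-2 sleep transients with a sharp negative peak
exceeding 100 µV, a positive lobe peaking 350–550 ms after onset and a total
span near 900 ms — are markers of sleep quality and candidate biomarkers for
neurodegenerative disease, but they hide among delta waves of very similar
morphology. `kcdetect` is for researchers who want a transparent, fully
testable detection chain: every stage, from the raw microvolts to the event
list, is a documented function with an independent oracle, and a synthetic
stage-2 sleep generator supplies annotated recordings so nothing requires
clinical data.

## The method

For an analytic signal x[n], the package works with the discrete
smoothed pseudo-Wigner–Ville distribution

```
W[n, k] = Σ_l g[l] Σ_m h[m] · x[n+m+l] x*[n+m−l] · e^{−j2πkl/Nf},
```

with lag window `g`, time window `h` and frequency bins `v_k = k/(2·Nf)` on
[0, 0.5). Two things make it practical:

* **Reassignment.** Each cell's value is moved to a locally estimated center
  of gravity computed from two modified-kernel distributions — the
  time-weighted kernel `m·g[l]h[m]` and the lag-derivative kernel
  `g′[l]h[m]`:

  ```
  n̂ = n + Re{ W[·; TΦ] / W[·; Φ] },     v̂ = v − (1/4π)·Im{ W[·; DΦ] / W[·; Φ] }.
  ```

  This sharpens the "knife blade" ridge of a transient dramatically (a
  512-sample linear chirp's ridge localizes to within one frequency bin).

* **Recursion.** When `h` decomposes into exponential components
  `h[m] = Σ c_k ρ_k^m` (rectangular, exponential/forgetting-factor,
  half-sine, Hamming, Hanning windows all do), all three distributions obey
  a first-order streaming update touching only the two boundary
  autocorrelation lags — per-step cost independent of the time-window
  half-length M, and evaluating the reassignment operators over N frequency
  bins costs at most **3N additions and 2N multiplications** (instrumented,
  not estimated).

Distributions feed a fixed-length feature vector (a 16×16 resampled
magnitude patch plus delta/theta/sigma band-energy fractions), classified by
a hand-written MLP with **arctan** activations (derivative `1/(1+x²)`), a
2-unit softmax head, binary cross-entropy, and batch-1 stochastic gradient
descent. The classifier and featurizer follow the scikit-learn estimator
protocol, so they compose with `sklearn` pipelines and model selection.

The other Cohen-class members (Born–Jordan, Choi–Williams, Zhao–Atlas–Marks,
spectrogram) are implemented for comparative analysis on the same grid.

## Worked example

```python
import numpy as np
from kcdetect import (SynthConfig, make_dataset, TFRFeatureExtractor,
                      MLPNetClassifier, synth_record, run_detection,
                      score_events, DetectionConfig)

# annotated synthetic stage-2 sleep EEG: 100 training + 20 test segments
cfg = SynthConfig(duration_s=6000.0, seed=21)
ds = make_dataset(cfg, 120, 0.5, seed=5)
feat = TFRFeatureExtractor(fs=200.0).fit(ds.X)
F = feat.transform(ds.X)           # reassigned SPWVD -> 259 features/segment

clf = MLPNetClassifier(learning_rate=1e-3, random_state=0)   # 6x8 arctan MLP
clf.fit(F[:100], ds.y[:100], eval_set=(F[100:], ds.y[100:]))
report = clf.evaluate(F[100:], ds.y[100:])
print(f"segment-level test accuracy: {report.accuracy:.3f}")

# detect events in a fresh, unseen recording
record, truth = synth_record(SynthConfig(duration_s=600.0, seed=33))
result = run_detection(record, clf, feat, DetectionConfig(threshold=0.9))
score = score_events(result.events, truth.of_label("kcomplex"), tol_s=0.75)
print(f"events: {len(truth.of_label('kcomplex'))} true, "
      f"{len(result.events)} detected")
print(f"event-level precision {score.precision:.2f}  "
      f"recall {score.recall:.2f}")
```

prints

```
segment-level test accuracy: 1.000
events: 7 true, 11 detected
event-level precision 0.64  recall 1.00
```

All 7 planted K-complexes are recovered. The false alarms are delta-band
background bursts — the known confounder for this waveform; at the default
threshold 0.5 recall stays 1.00 but spurious detections roughly double,
because the per-segment z-scoring in the feature patch discards absolute
amplitude and a delta burst then resembles a K-complex in shape.

There is also a command-line interface:

```bash
kcdetect synth --duration 1620 --seed 1 --out rec.edf --events truth.csv
kcdetect tfr --record rec.edf --start 60 --duration 2 --out tfr.csv
kcdetect train --dataset segments.csv --layers 6x8 --activation arctan \
               --epochs 100 --lr 1e-5 --batch 1 --seed 0 --model m.json
kcdetect detect --record rec.edf --model m.json --out detected.csv
kcdetect eval --pred detected.csv --truth truth.csv
```

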