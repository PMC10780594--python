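# gaitenc

Feature-encoding pipelines for **multimodal wearable-sensor time
series** — gait and activity recordings from body-worn IMUs
(accelerometer / gyroscope / magnetometer, 3 axes each) — for
researchers and engineers who need to turn raw labeled sensor sequences
into classifiable representations and compare encoders under an honest,
leakage-free protocol.

Three encoder families are implemented behind one evaluation harness:

1. **Handcrafted features** — 18 statistics per channel per 128-sample
   window (max, min, μ, σ with the n−1 denominator, zero crossings,
   percentiles 20/50/80, IQR, kurtosis Σ(mᵢ−μ)⁴/(nσ⁴), skewness, lag-1
   autocorrelation R₁, sorted-gap statistics, spectral entropy
   −ΣF̂ log F̂ and spectral energy ΣF²), fused by concatenation into a
   3 × 3 × 18 = 162-vector.
2. **Codebook + LLC** — per sensor, k-means (k = 32, best of 10
   restarts, minimizing J = Σₘ Σₖ r_{mk}‖xₘ − cₖ‖²) over 3w = 192-dim
   sub-sequences (w = 64, stride l = 8, axes concatenated x|y|z), then
   locality-constrained linear coding: min_v ‖x − Cv‖² + λ‖d ⊙ v‖²
   s.t. Σv = 1, with λ = 0.01, the 5 nearest codewords and locality
   adaptor dᵢ = exp(dist(x, cᵢ)/σ), pooled into per-window descriptors.
3. **Deep models** — a fixed CNN (conv 32×(3,2) → pool(2,1) →
   conv 64×(2,1) → pool(2,1) → conv 128×(2,1) → flatten → softmax) and a
   2-layer, 50-unit LSTM with the standard gate equations and forget
   bias 1.0, trained with Adam and best-epoch restore, implemented in
   NumPy with manual backpropagation and verified against
   finite-difference and straight-line oracles.

Classification is linear one-vs-rest SVM (C by stratified 10-fold CV)
or a 100-tree random forest; evaluation is a stratified recording-level
80/20 holdout or leave-one-subject-out, with hard errors on any
train/test leakage. A seedable synthetic generator emulates multi-class
walking-style recordings (per-class stride frequency and harmonic
profile, per-subject variation, sensor noise, missing samples) so the
whole stack is testable without downloading anything.

## Worked example

```python
from gaitenc import (GeneratorConfig, clean_recording, extract_features,
                     generate_dataset, segment_windows)

recs, manifest = generate_dataset(GeneratorConfig(
    n_subjects=1, recordings_per_subject_per_class=1, n_samples=640,
    nan_rate=0.0, seed=2))
rec = clean_recording(recs[0])
windows = segment_windows(rec, w=128, overlap=0.5)
fv = extract_features(windows[0], rec.channel_names)
print(len(windows), fv.values.size)
```

Running `python examples/02_handcrafted_features.py` (which does the
above and prints the first channel's feature block) gives:

```
recording of 640 samples -> 9 windows (128 samples, 50% overlap)
fused feature vector: 162 values = 9 channels x 18 features

acc_x block of the first window:
                 max:  1.7517
                 min: -1.5478
                mean:  0.0068
                 std:  0.8331
      zero_crossings:  6.0000
                 ...
    spectral_entropy:  3.5571
     spectral_energy:  5642.7529
```

Nine windows because floor((640 − 128)/64) + 1 = 9; the window's six
zero crossings and high lag-1 autocorrelation (0.84) reflect a slow,
smooth periodic signal, and its spectral entropy (3.56 nats, against
log 65 ≈ 4.17 for white noise over the 65 one-sided DFT bins) shows the
energy is concentrated in a few stride-harmonic bins.

The other scripts in `examples/` walk through dataset simulation,
codebook learning + LLC encoding, the two evaluation protocols, the
deep models and an encoder comparison table. A thin CLI mirrors the
library (`gaitenc simulate | clean | features | codebook | encode |
train | train-deep | evaluate | compare`).

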