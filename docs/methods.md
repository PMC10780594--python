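# Methods

`gaitenc` implements three families of sequence representations for
multichannel wearable-sensor time series — handcrafted statistical/
spectral features, codebook encoding with locality-constrained linear
coding (LLC), and compact CNN/LSTM classifiers — together with the data
handling, synthetic benchmark and evaluation protocol needed to compare
them end to end. This note records the models, the defaults and why,
the numerical choices, and what the synthetic benchmark does and does
not demonstrate.

## Data model and cleaning

A recording is an (n_samples × n_channels) matrix at a fixed sample rate
(50 Hz by default), channels ordered sensor by sensor with axes x, y, z
within each sensor; the default schema is 3-axis accelerometer,
gyroscope and magnetometer (9 channels). Missing samples (sensor
dropout) are repaired by linear interpolation in sample index, with
boundary gaps extended from the nearest valid value. A recording in
which **any single channel** exceeds 30% missing data is rejected with a
reason, never silently dropped; the per-channel reading of the threshold
is the stricter of the two possible interpretations and is the one we
adopt (a recording whose gyroscope is one-third absent is not repairable
even if its other channels are clean). Cleaning is idempotent and never
alters observed samples.

## Segmentation

Two segmentations coexist:

* **Classification windows** — length w = 128 with 50% overlap
  (step 64), all channels. Window counts follow
  `floor((n − w)/step) + 1`; trailing partial windows are dropped rather
  than padded, since padding would distort the spectral features.
  Overlap converts to a step by rounding, which is exact at the default.
* **Codebook sub-sequences** — per sensor, length w = 64 advanced every
  l = 8 samples, the three axis windows concatenated as [x | y | z] into
  a 192-dimensional vector, so one vector captures the cross-axis
  correlation of one sensor. Sub-sequences keep raw units; a z-score
  switch exists but is off by default.

## Handcrafted features

Eighteen features per channel, fused by concatenation (9 channels × 18 =
162 per window): max, min, mean, standard deviation (n−1 denominator),
zero crossings, percentiles 20/50/80, interquartile range, kurtosis,
skewness, lag-1 autocorrelation, four sorted-gap ("order mean")
statistics, spectral entropy and spectral energy.

Numerical conventions worth calling out:

* **Moment features** compose the n−1 standard deviation into their
  denominators — kurtosis = Σ(mᵢ−μ)⁴/(nσ⁴) with σ the *sample* standard
  deviation — so a large normal sample has kurtosis slightly below 3.
  The test oracle uses the same convention.
* **Zero crossings**: an exact zero adopts the sign of the previous
  nonzero sample, preventing double counts across plateaus; leading
  zeros carry no sign.
* **Order-mean features**: sort the window ascending; FOM and its norm
  are the mean and L1 norm of consecutive gaps (the L1 norm telescopes
  to max − min), SOM and its norm are the mean and L2 norm of the
  second-order gaps. Other pairings of {L1, L2} × {first, second order}
  are selectable; this default uses both the sorting and both norms
  while staying nondegenerate.
* **Spectral features** use the one-sided DFT magnitude spectrum with no
  taper and DC included; spectral energy is ΣF², spectral entropy is the
  Shannon entropy (natural log) of the magnitudes normalized to unit
  sum, with zero bins contributing nothing. At 50 Hz and w = 128 the bin
  width is ≈ 0.39 Hz, which bounds how finely the features can resolve
  stride frequency — a limit that matters below.
* **Degenerate windows** (constant, or all-zero spectrum) map to 0 with
  a warning rather than NaN, keeping classifiers well-posed; the
  autocorrelation lag is configurable (default 1).

## Codebook + LLC

Per sensor, k = 32 codewords are learned by Lloyd's k-means over the
training split's sub-sequences, minimizing the within-cluster sum of
squared Euclidean distances. Initialization samples k distinct training
vectors uniformly; an emptied cluster is re-seeded to the point farthest
from its center; the objective after each assignment step is recorded
and is non-increasing by construction (asserted in tests). Ten restarts
from independent substreams are run and the lowest-objective run kept.

Encoding solves, on the support of the knn = 5 nearest codewords,

    min_v ‖x − Cv‖² + λ‖d ⊙ v‖²   s.t.  Σv = 1,     λ = 0.01,
    dᵢ = exp(dist(x, cᵢ)/σ),

via the exact KKT linear system of size knn+1. σ defaults to the mean
distance from x to its selected codewords (self-scaling; overridable);
the exponent is capped at 350 so the squared adaptor stays finite as
σ → 0, where weight provably concentrates on the single nearest
codeword. Distance ties at the knn boundary break by ascending codeword
index; a singular system (duplicate codewords) receives a logged
diagonal jitter of λ·trace/knn. Off-support coefficients are exactly
zero and every code sums to one to 1e−8.

Codes are pooled element-wise into descriptors (average by default; sum
and max selectable) and per-sensor blocks concatenated (3 × 32 = 96).
The default descriptor granularity is the **classification window** —
the nine sub-sequences inside each 128-sample window are pooled into one
descriptor — so the codebook pipeline classifies the same units under
the same windowing as the handcrafted one; whole-recording descriptors
are available via `codebook_unit="recording"`.

## Classifiers and evaluation protocol

The linear one-vs-rest SVM (hinge loss, liblinear) selects its penalty C
from {0.01, 0.1, 1, 10, 100} by stratified 10-fold cross-validated
accuracy computed **inside the training side only**; the fold count
drops to the rarest class size when necessary. Features are
standardized with training-side statistics before the SVM (not before
the forest; both switchable). The random forest uses 100 trees with
√d candidate features per split and majority voting, deterministic given
its seed.

Two protocols: a stratified 80/20 holdout and leave-one-subject-out
(LOSO). The split unit is the **recording**: all windows or descriptors
of one recording travel together, because 50%-overlapped windows are
near-duplicates and splitting them across sides would leak; a
window-level split exists (`unit="window"`) for comparison with
protocols that ignore this. Any subject (LOSO) or recording (holdout)
appearing on both sides is a hard error. Codebooks, scalers and the
SVM's internal CV see only the training side; tests assert that
corrupting test-side data changes no training artifact.

## Deep models

No deep-learning framework is part of the dependency set; the CNN and
LSTM are compact NumPy implementations with manual backpropagation
(im2col convolutions; full backpropagation through time), sized for the
data volumes this package targets.

* **CNN** (fixed stack, valid padding, ReLU): conv 32 × (3,2) → maxpool
  (2,1) → conv 64 × (2,1) → maxpool (2,1) → conv 128 × (2,1) → flatten →
  dense softmax. Input layout is (time, channels, 1) with the kernel's
  first axis on time. For a (128, 9, 1) window the stack yields
  205,222 parameters; the built model emits a per-layer shape and
  parameter report checked against closed-form arithmetic in tests.
* **LSTM**: each 3-feature input step is projected through a ReLU layer
  onto the hidden width, then two stacked recurrent cells of 50 units
  implement the standard gate equations (forget/input/output sigmoid,
  candidate tanh, forget-gate bias offset 1.0); the last step's hidden
  state feeds a linear softmax layer. Segments default to 200 samples
  of one sensor's three axes. The cell is verified against a
  straight-line scalar re-evaluation of the gate equations and against
  finite-difference gradients.

Training: Adam (lr 1e−3), cross-entropy, up to 27 epochs, CNN batch 5 /
LSTM batch 32; the LSTM clips the global gradient norm at 1.0
(recurrent nets are prone to exploding gradients; lr probes at 3e−3 and
5e−3 performed no better than the default). Early stopping monitors the
loss on a held-out 20% validation split drawn at the **recording**
level — a window-level validation split would contain near-duplicates of
training windows and report optimistically — with patience 8 and
restoration of the best-epoch weights. The monitored metric defaults
to validation *accuracy* rather than loss: with a small recording-level
validation set, cross-entropy is dominated by a handful of confidently
wrong windows and systematically selects under-trained epochs; a
validation-loss mode remains available. Inputs are standardized per
channel with training-side statistics. Deep pipelines use the same
50%-overlap windowing as the classical ones (LSTM segments advance by
half their length). A NaN loss aborts with diagnostics.

## Synthetic benchmark

The generator emulates the *statistical* structure of wearable gait
data, not its biomechanics: each class is a stride base frequency plus
harmonics, with per-subject multiplicative frequency/amplitude
perturbation, per-sensor Gaussian noise, a gravity offset on one
accelerometer axis, a heading offset plus slow drift on the
magnetometer, and uniform random missing samples. Gyroscope channels
are phase-shifted derivatives of the accelerometer harmonics (90°
lead, amplitude proportional to the absolute harmonic frequency);
faster gaits therefore swing harder, as real gyroscope data do. One
master seed derives one substream per (subject, class, repetition), so
growing the grid never perturbs existing recordings.

Reference benchmark defaults: 6 classes × 7 subjects × 2 recordings of
1280 samples at 50 Hz; class base frequencies evenly spaced over
0.8–2.0 Hz; harmonic amplitude profile (1.0, 0.1+0.12·i, 0.03+0.07·i)
for class index i, so pace also sharpens the waveform (quicker gaits
carry relatively more high-harmonic content, as impact dynamics do);
noise σ 0.3 (0.45 for the two "distracted" classes), phase jitter 0.3
rad, subject effect σ 3%, 1% missing samples.

What passing on this benchmark shows — and does not: the generator's
classes are fine gradations of a *single* periodic signal, which is a
deliberately hard discrimination regime. Supervised spectral/amplitude
features separate them essentially perfectly (handcrafted + RF reaches
100% held-out accuracy at the defaults, as `scripts/acceptance.py`
recomputes). Unsupervised 32-codeword quantization of raw
192-dimensional sub-sequences resolves them only partially
(codebook-LLC with SVM or RF lands in the 70s–80s), and the raw-window
deep models trail further still at this data volume (67 training
recordings). Real activity datasets differ: their classes (walking vs.
jogging vs. sitting) are grossly distinct signals, so published
codebook and deep results on such data land far higher, while *this*
benchmark compresses the encoder ranking into a harder, narrower
problem. The benchmark therefore demonstrates correct plumbing, honest
protocol and the expected *ordering* (supervised features ≥ codebook ≥
raw-window nets on narrowly periodic data); it is not evidence about
absolute accuracies on real recordings.

Problem sizes used by the test suite and the reproduction script are
the benchmark defaults above; unit tests use smaller grids (2–4
subjects, 256–640 samples) chosen to exercise every code path quickly.

## Known limitations

* The generator has no gait-cycle asymmetry, no double-support timing,
  no sensor drift or axis misalignment; conclusions about real IMU data
  require real recordings (external datasets are supported as CSV +
  manifest inputs but never required or downloaded).
* The LLC locality bandwidth σ is self-scaling by default; published
  LLC variants fix σ globally or approximate d away entirely, and the
  choice matters most at small k.
* LinearSVC's one-vs-rest hinge objective is deterministic but its
  coordinate-descent path can vary across library versions at loose
  tolerances; tests pin behavior only through predictions.
* The deep models are CPU-bound NumPy; they are faithful and tested,
  but not fast — minutes, not seconds, at the benchmark scale.
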