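"""Learn a k-means codebook over gait sub-sequences and LLC-encode them.

Sub-sequences are 64-sample windows of one sensor's three axes flattened
to a 192-vector (x | y | z), cut every 8 samples.  k-means (best of 10
restarts) learns 32 codewords; locality-constrained linear coding then
reconstructs each sub-sequence from its 5 nearest codewords under a
sum-to-one constraint, and averaging the sparse codes yields a compact
per-sequence descriptor.
"""

import numpy as np

from gaitenc import (
    GeneratorConfig, build_codebook, clean_recording, encode_sequence,
    generate_dataset, llc_encode, segment_subsequences, subsequence_matrix,
)

recs, _ = generate_dataset(GeneratorConfig(
    n_subjects=2, recordings_per_subject_per_class=1, n_samples=640,
    nan_rate=0.0, seed=3,
))
recs = [clean_recording(r) for r in recs]

subseqs = [s for r in recs for s in segment_subsequences(r, "acc", w=64, l=8)]
print(f"{len(subseqs)} accelerometer sub-sequences of length "
      f"{subseqs[0].vector.size} (= 3 x 64)")

cb = build_codebook(subseqs, k=32, n_restarts=10, seed=0, w=64, l=8)
print(f"codebook: {cb.k} codewords, clustering objective "
      f"{cb.training_objective:.1f} (best of {cb.n_restarts} restarts; "
      f"worst restart {max(cb.restart_objectives):.1f})")

code = llc_encode(subseqs[0].vector, cb, knn=5, lam=0.01)
nz = code.support
print(f"\nLLC code of one sub-sequence: {len(nz)} active codewords "
      f"{nz.tolist()}, coefficients sum to {code.coefficients.sum():.9f}")

desc = encode_sequence(recs[0], [cb], pooling="average")
top = np.argsort(desc.values)[-3:][::-1]
print(f"sequence descriptor: length {desc.values.size}; most-used "
      f"codewords {top.tolist()} — the recording's dominant local shapes")
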