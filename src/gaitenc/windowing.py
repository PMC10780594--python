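"""Fixed-size sliding-window segmentation.

Two segmentations feed the two classical encoders:

* classification windows — length ``w`` (default 128) with fractional
  overlap (default 50%), spanning all channels;
* codebook sub-sequences — per-sensor windows of length ``w`` (default 64)
  advanced every ``l`` samples (default 8), flattened to a 3w vector by
  concatenating the x, y and z axis windows in that order, so one vector
  captures the cross-axis correlation of one sensor.

Both drop trailing partial windows; both emit exact slices of the source
series.  Window count is ``floor((n - w) / step) + 1`` for ``n >= w``,
else zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .recordings import Recording, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class Window:
    """One classification window: (w x n_channels) slice of a recording."""

    samples: np.ndarray
    label: str
    subject_id: str
    source_index: tuple[str, int]   # (recording id, start sample)


@dataclass
class SubSequence:
    """One codebook sub-sequence: [x-window | y-window | z-window], length 3w."""

    vector: np.ndarray
    sensor_name: str
    source_index: tuple[str, int]


def n_windows(n_samples: int, w: int, step: int) -> int:
    return 0 if n_samples < w else (n_samples - w) // step + 1


def segment_windows(
    rec: Recording, w: int = 128, overlap: float = 0.5
) -> list[Window]:
    """Segment a recording into fixed windows with fractional overlap.

    ``step = round(w * (1 - overlap))``; at the default w=128, 50% overlap
    this is exactly 64.  A recording shorter than ``w`` yields zero windows
    and a logged warning rather than an error, so batch jobs survive short
    recordings.
    """
    if w < 2:
        raise ValueError("w must be >= 2")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = int(round(w * (1.0 - overlap)))
    if step < 1:
        raise ValueError(f"overlap {overlap} gives step < 1 at w={w}")
    if rec.n_samples < w:
        logger.warning(
            "recording %s has %d samples < window %d; no windows emitted",
            rec.recording_id, rec.n_samples, w,
        )
        return []
    return [
        Window(
            samples=rec.data[start : start + w],
            label=rec.label,
            subject_id=rec.subject_id,
            source_index=(rec.recording_id, start),
        )
        for start in range(0, rec.n_samples - w + 1, step)
    ]


def segment_subsequences(
    rec: Recording, sensor: str, w: int = 64, l: int = 8
) -> list[SubSequence]:
    """Segment one sensor's 3-axis data into 3w-dimensional sub-sequences.

    Windows start every ``l`` samples (heavy overlap by design, so enough
    sub-sequences exist to capture temporal correlation).  Each vector is
    the sensor's x, y and z windows concatenated in that order.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    axes = rec.sensor(sensor)                     # raises SchemaError if absent
    if axes.shape[1] != 3:
        raise SchemaError(
            f"sensor {sensor!r} has {axes.shape[1]} axes, expected 3"
        )
    n = rec.n_samples
    if n < w:
        logger.warning(
            "recording %s too short (%d < %d) for sub-sequences",
            rec.recording_id, n, w,
        )
        return []
    out = []
    for start in range(0, n - w + 1, l):
        block = axes[start : start + w]
        out.append(
            SubSequence(
                vector=np.concatenate([block[:, 0], block[:, 1], block[:, 2]]),
                sensor_name=sensor,
                source_index=(rec.recording_id, start),
            )
        )
    return out


def subsequence_matrix(subseqs: list[SubSequence]) -> np.ndarray:
    """Stack sub-sequence vectors into an (m, 3w) matrix."""
    return np.stack([s.vector for s in subseqs])
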