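"""Reading, writing and cleaning multichannel wearable-sensor recordings.

A :class:`Recording` holds one labeled multichannel time series: a matrix of
samples (rows) by sensor-axis channels (columns), plus subject id, class
label and sample rate.  Files are plain CSV with a ``timestamp`` column and
one ``<sensor>_<axis>`` column per channel; a dataset is described by a
YAML/JSON manifest listing the recording files with their subjects and
labels.

Missing samples (empty cells or literal ``NaN``) are repaired by linear
interpolation in sample index, with boundary gaps filled by nearest-value
extension.  A recording in which any channel exceeds a missing-data
threshold (30% by default) is rejected rather than repaired, mirroring
standard practice for sensor-malfunction dropout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Default axis names of a 3-axis sensor, in fixed order.
AXES = ("x", "y", "z")

#: Default channel schema: 3 sensors x 3 axes.
DEFAULT_SCHEMA: dict[str, tuple[str, ...]] = {
    "acc": AXES,
    "gyro": AXES,
    "mag": AXES,
}


class SchemaError(ValueError):
    """A file's columns do not match the expected channel schema."""


class RecordingRejected(ValueError):
    """A recording failed the missing-data quality gate."""

    def __init__(self, reason: str, channel: str | None = None):
        self.reason = reason
        self.channel = channel
        msg = reason if channel is None else f"{reason} (channel {channel!r})"
        super().__init__(msg)


def channel_names(schema: Mapping[str, Sequence[str]]) -> list[str]:
    """Flat ``<sensor>_<axis>`` column names in schema order."""
    return [f"{s}_{a}" for s, axes in schema.items() for a in axes]


@dataclass
class Recording:
    """One labeled multichannel time series.

    ``data`` is an (n_samples, n_channels) float array whose columns follow
    ``schema`` order (sensor by sensor, axes x, y, z within each sensor).
    """

    subject_id: str
    label: str
    sample_rate_hz: float
    schema: Mapping[str, tuple[str, ...]]
    data: np.ndarray
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        n_expected = sum(len(a) for a in self.schema.values())
        if self.data.shape[1] != n_expected:
            raise SchemaError(
                f"data has {self.data.shape[1]} channels, schema expects {n_expected}"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return channel_names(self.schema)

    def sensor(self, name: str) -> np.ndarray:
        """(n_samples, n_axes) view of one sensor's axes in x, y, z order."""
        names = self.channel_names
        cols = [i for i, c in enumerate(names) if c.startswith(name + "_")]
        if not cols:
            raise SchemaError(f"sensor {name!r} not in schema {list(self.schema)}")
        return self.data[:, cols]

    def equals(self, other: "Recording") -> bool:
        return (
            self.subject_id == other.subject_id
            and self.label == other.label
            and self.sample_rate_hz == other.sample_rate_hz
            and list(channel_names(self.schema)) == list(channel_names(other.schema))
            and self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data, equal_nan=True)
        )


@dataclass
class ManifestEntry:
    path: str
    subject: str
    label: str


@dataclass
class DatasetManifest:
    """Index of a dataset: sample rate, channel schema and recording entries."""

    sample_rate_hz: float
    channels: Mapping[str, tuple[str, ...]]
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        paths = [e.path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths must be unique")

    @property
    def classes(self) -> list[str]:
        return sorted({e.label for e in self.entries})

    def to_dict(self) -> dict:
        return {
            "sample_rate_hz": self.sample_rate_hz,
            "channels": {s: list(a) for s, a in self.channels.items()},
            "entries": [
                {"path": e.path, "subject": e.subject, "label": e.label}
                for e in self.entries
            ],
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls(
            sample_rate_hz=float(raw["sample_rate_hz"]),
            channels={s: tuple(a) for s, a in raw["channels"].items()},
            entries=[ManifestEntry(**e) for e in raw["entries"]],
        )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV: ``timestamp`` plus one column per channel.

    Timestamps are sample index / sample rate.  NaN cells are written as
    empty fields, read back as missing.
    """
    t = np.arange(rec.n_samples) / rec.sample_rate_hz
    df = pd.DataFrame(rec.data, columns=rec.channel_names)
    df.insert(0, "timestamp", t)
    df.to_csv(path, index=False, float_format="%.10g")


def read_recording(
    path: str | Path,
    schema: Mapping[str, Sequence[str]],
    *,
    subject_id: str = "",
    label: str = "",
    sample_rate_hz: float = 50.0,
) -> Recording:
    """Read a CSV recording, validating its columns against ``schema``.

    Columns are reordered to schema order; extra columns are ignored.
    Missing cells and literal ``NaN`` both parse as missing samples.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged/unparseable rows in {path}: {exc}") from exc
    expected = channel_names(schema)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    data = df[expected].to_numpy(dtype=float)
    return Recording(
        subject_id=subject_id,
        label=label,
        sample_rate_hz=sample_rate_hz,
        schema={s: tuple(a) for s, a in schema.items()},
        data=data,
        recording_id=path.stem,
    )


def _interpolate_channel(col: np.ndarray) -> np.ndarray:
    """Fill NaNs: linear interpolation in sample index, nearest at boundaries."""
    mask = np.isnan(col)
    if not mask.any():
        return col
    idx = np.arange(col.size)
    # np.interp extends flat beyond the first/last valid point, which is
    # exactly the nearest-value boundary rule.
    return np.interp(idx, idx[~mask], col[~mask])


def clean_recording(rec: Recording, max_nan_frac: float = 0.3) -> Recording:
    """Repair missing samples or reject the recording.

    Raises :class:`RecordingRejected` if any channel's NaN fraction exceeds
    ``max_nan_frac`` (strictly), or if a channel is entirely NaN.  Otherwise
    returns a new Recording with every NaN filled by linear interpolation
    (boundaries by nearest valid value); non-missing samples are untouched.
    """
    data = rec.data
    nan_frac = np.isnan(data).mean(axis=0)
    names = rec.channel_names
    for j, frac in enumerate(nan_frac):
        if frac >= 1.0:
            raise RecordingRejected("empty channel", names[j])
        if frac > max_nan_frac:
            raise RecordingRejected(
                f"NaN fraction {frac:.1%} exceeds {max_nan_frac:.0%}", names[j]
            )
    if not np.isnan(data).any():
        return rec
    filled = np.column_stack([_interpolate_channel(data[:, j]) for j in range(data.shape[1])])
    return replace(rec, data=filled)


@dataclass
class LoadLog:
    """Outcome of loading a manifest: rejections and class counts."""

    rejections: list[tuple[str, str]] = field(default_factory=list)
    class_counts: dict[str, int] = field(default_factory=dict)


def load_dataset(
    manifest: DatasetManifest,
    *,
    root: str | Path | None = None,
    max_nan_frac: float = 0.3,
) -> tuple[list[Recording], LoadLog]:
    """Load and clean every manifest entry, in manifest order.

    Rejected recordings are reported in the returned :class:`LoadLog`
    (never silently dropped).  Unreadable paths raise ``FileNotFoundError``
    naming the path.
    """
    log = LoadLog()
    recs: list[Recording] = []
    if not manifest.entries:
        logger.warning("manifest has no entries")
        return recs, log
    for entry in manifest.entries:
        path = Path(root) / entry.path if root is not None else Path(entry.path)
        if not path.exists():
            raise FileNotFoundError(f"manifest entry not readable: {path}")
        rec = read_recording(
            path,
            manifest.channels,
            subject_id=entry.subject,
            label=entry.label,
            sample_rate_hz=manifest.sample_rate_hz,
        )
        try:
            recs.append(clean_recording(rec, max_nan_frac=max_nan_frac))
        except RecordingRejected as rej:
            log.rejections.append((entry.path, str(rej)))
            logger.info("rejected %s: %s", entry.path, rej)
            continue
        log.class_counts[entry.label] = log.class_counts.get(entry.label, 0) + 1
    logger.info("loaded %d recordings, %d rejected; classes: %s",
                len(recs), len(log.rejections), log.class_counts)
    return recs, log
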