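"""Seedable synthetic multimodal gait recordings.

The generator emulates the statistical structure of wearable IMU walking
data — not its biomechanics.  Each class is a periodic signature: a stride
base frequency plus a few harmonics, with per-subject frequency/amplitude
perturbation, per-sensor Gaussian noise, a gravity-like baseline offset on
one accelerometer axis, and optional uniformly random missing samples.

Accelerometer axes carry the harmonic stack directly; gyroscope axes are
built from the same harmonics phase-shifted by 90 degrees with amplitude
proportional to frequency (a derivative-like relationship); magnetometer
axes are a slow low-frequency drift around a constant heading offset.

Determinism: one master seed spawns one independent child stream per
(subject, class, repetition) via ``numpy.random.SeedSequence``, so adding
recordings never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recordings import AXES, DEFAULT_SCHEMA, DatasetManifest, ManifestEntry, Recording


@dataclass
class ClassSpec:
    """Signal signature of one walking-style class."""

    name: str
    base_freq_hz: float
    #: amplitude of harmonic h (h = 1, 2, ...) applied to every axis
    harmonic_amps: tuple[float, ...] = (1.0, 0.4, 0.15)
    phase_jitter_sd: float = 0.3          # rad, per-recording phase wobble
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"acc": 0.3, "gyro": 0.3, "mag": 0.1}
    )
    #: per-channel additive constant, keyed "<sensor>_<axis>"
    baseline_offset: dict[str, float] = field(
        default_factory=lambda: {"acc_z": 9.81, "mag_x": 40.0}
    )

    def validate(self, sample_rate_hz: float) -> None:
        n_h = len(self.harmonic_amps)
        if self.base_freq_hz * n_h >= sample_rate_hz / 2:
            raise ValueError(
                f"class {self.name!r}: harmonic {n_h} at "
                f"{self.base_freq_hz * n_h:g} Hz reaches Nyquist "
                f"({sample_rate_hz / 2:g} Hz)"
            )
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be non-negative")


def default_class_specs(
    freq_lo: float = 0.8, freq_hi: float = 2.0, n_classes: int = 6
) -> list[ClassSpec]:
    """Six walking-style classes spanning slow to fast stride frequencies.

    Frequencies are evenly spaced in [freq_lo, freq_hi] Hz (slow < normal
    < fast); the last two classes get extra noise, mimicking less steady
    walking (blindfolded / dual-task conditions).
    """
    names = ["slow", "normal", "fast", "very_fast", "blindfolded", "dual_task"]
    freqs = np.linspace(freq_lo, freq_hi, n_classes)
    specs = []
    for i in range(n_classes):
        noisy = i >= n_classes - 2
        specs.append(
            ClassSpec(
                name=names[i] if i < len(names) else f"class{i}",
                base_freq_hz=float(freqs[i]),
                # waveform morphology varies with pace: quicker gaits carry
                # sharper impacts, i.e. relatively more harmonic content
                harmonic_amps=(1.0, 0.1 + 0.12 * i, 0.03 + 0.07 * i),
                noise_sd={"acc": 0.45 if noisy else 0.3,
                          "gyro": 0.45 if noisy else 0.3,
                          "mag": 0.15 if noisy else 0.1},
            )
        )
    return specs


@dataclass
class GeneratorConfig:
    class_specs: list[ClassSpec] = field(default_factory=default_class_specs)
    n_subjects: int = 7
    recordings_per_subject_per_class: int = 2
    n_samples: int = 1280
    sample_rate_hz: float = 50.0
    subject_effect_sd: float = 0.03       # relative freq/amp perturbation
    nan_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if len(self.class_specs) < 2:
            raise ValueError("need at least 2 classes")
        if not 0 <= self.nan_rate < 1:
            raise ValueError("nan_rate must be in [0, 1)")
        for spec in self.class_specs:
            spec.validate(self.sample_rate_hz)


def generate_recording(
    spec: ClassSpec,
    subject_effect: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    *,
    subject_id: str = "s0",
    recording_id: str = "",
) -> Recording:
    """Synthesize one recording for one (class, subject) pair.

    ``subject_effect`` perturbs the class base frequency and amplitudes
    multiplicatively: the subject's stride frequency is
    ``base_freq_hz * (1 + subject_effect)``.
    """
    spec.validate(config.sample_rate_hz)
    n = config.n_samples
    t = np.arange(n) / config.sample_rate_hz
    f_subj = spec.base_freq_hz * (1.0 + subject_effect)
    amp_scale = 1.0 + subject_effect

    cols = []
    for sensor, axes in DEFAULT_SCHEMA.items():
        for axis in axes:
            key = f"{sensor}_{axis}"
            offset = spec.baseline_offset.get(key, 0.0)
            phase0 = rng.uniform(0, 2 * np.pi)
            sig = np.full(n, offset, dtype=float)
            if sensor == "mag":
                # slow drift around the heading offset
                drift_f = 0.05 * (1 + 0.5 * rng.standard_normal())
                sig += 0.5 * np.sin(2 * np.pi * drift_f * t + phase0)
            else:
                for h, amp in enumerate(spec.harmonic_amps, start=1):
                    jitter = rng.normal(0.0, spec.phase_jitter_sd)
                    phase = phase0 * h + jitter
                    a = amp * amp_scale
                    if sensor == "gyro":
                        # derivative relationship: 90 deg phase lead and
                        # amplitude proportional to the absolute harmonic
                        # frequency (faster strides swing harder), in
                        # rad/s per unit accelerometer amplitude per Hz
                        a *= h * f_subj
                        phase += np.pi / 2
                    sig += a * np.sin(2 * np.pi * h * f_subj * t + phase)
            sd = spec.noise_sd.get(sensor, 0.0)
            if sd > 0:
                sig = sig + rng.normal(0.0, sd, size=n)
            cols.append(sig)

    data = np.column_stack(cols)
    if config.nan_rate > 0:
        mask = rng.random(data.shape) < config.nan_rate
        data[mask] = np.nan
    return Recording(
        subject_id=subject_id,
        label=spec.name,
        sample_rate_hz=config.sample_rate_hz,
        schema=DEFAULT_SCHEMA,
        data=data,
        recording_id=recording_id,
    )


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[Recording], DatasetManifest]:
    """Generate the full grid of subjects x classes x repetitions.

    Fully reproducible from ``config.seed``: each (subject, class,
    repetition) cell draws from its own spawned child stream, and each
    subject's effect from a dedicated subject stream.
    """
    config.validate()

    def stream(*key: int) -> np.random.Generator:
        # key-derived substreams: each (subject, class, repetition) cell is
        # seeded by its own coordinates, so growing the grid never
        # perturbs previously generated cells
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((config.seed, *key)))
        )

    effects = [
        float(stream(1, s).normal(0.0, config.subject_effect_sd))
        for s in range(config.n_subjects)
    ]

    recs: list[Recording] = []
    entries: list[ManifestEntry] = []
    for s in range(config.n_subjects):
        for ci, spec in enumerate(config.class_specs):
            for r in range(config.recordings_per_subject_per_class):
                rng = stream(2, s, ci, r)
                rid = f"sub{s:02d}_{spec.name}_r{r}"
                rec = generate_recording(
                    spec, effects[s], config, rng,
                    subject_id=f"sub{s:02d}", recording_id=rid,
                )
                recs.append(rec)
                entries.append(
                    ManifestEntry(path=rid + ".csv", subject=rec.subject_id,
                                  label=rec.label)
                )
    manifest = DatasetManifest(
        sample_rate_hz=config.sample_rate_hz,
        channels=DEFAULT_SCHEMA,
        entries=entries,
    )
    return recs, manifest
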