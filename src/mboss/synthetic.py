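"""Seeded generator of activity-like tri-axial signals.

Emulates the structure of smartphone accelerometer benchmarks at desk scale:
dynamic classes (walking-, jogging-, stairs-like) are quasi-periodic — per
axis an offset plus a harmonic stack at a class-specific fundamental plus
Gaussian noise — while "static" classes (sitting-, standing-like) combine a
gravity-projection offset with a low-amplitude postural sway at a distinct
frequency.  Subject heterogeneity enters as deterministic multiplicative
amplitude/frequency jitter per subject.  A single integer seed drives one
root SeedSequence; subject/class/instance streams are derived by stable
spawn keys, so adding subjects never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LabeledDataset
from .segmentation import Instance, RawRecording


@dataclass(frozen=True)
class ClassSpec:
    """One activity class: a harmonic stack on each axis plus noise.

    ``harmonics`` are the amplitudes of sin components at k * fundamental_hz,
    k = 1, 2, ...; ``axis_gains`` scales the stack per axis (so axes carry
    different amounts of the movement); ``axis_offsets`` is the per-axis
    baseline (gravity projection), in g.
    """

    name: str
    fundamental_hz: float
    harmonics: tuple[float, ...]
    axis_offsets: tuple[float, float, float] = (0.0, 0.0, 1.0)
    axis_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_std: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.fundamental_hz <= 0:
            raise ValueError("fundamental_hz must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    classes: tuple[ClassSpec, ...]
    subjects: int = 10
    subject_jitter: float = 0.05
    sampling_rate: float = 50.0
    seg_len: int = 128
    instances_per_class_per_subject: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one class spec required")
        nyquist = self.sampling_rate / 2.0
        for spec in self.classes:
            top = spec.fundamental_hz * len(spec.harmonics)
            # jitter can push frequencies up slightly; keep a 20% guard band
            if top * 1.2 >= nyquist:
                raise ValueError(
                    f"class {spec.name}: harmonic at {top} Hz violates Nyquist"
                )


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The frozen default benchmark: 6 classes (4 dynamic, 2 static postural),
    10 subjects, 50 Hz, 128-sample segments."""
    classes = (
        ClassSpec(
            "walking",
            fundamental_hz=1.2,
            harmonics=(1.0, 0.45, 0.2),
            axis_offsets=(0.1, -0.2, 0.95),
            axis_gains=(1.0, 0.6, 0.8),
            noise_std=0.2,
        ),
        ClassSpec(
            "jogging",
            fundamental_hz=3.2,
            harmonics=(1.4, 0.5),
            axis_offsets=(0.15, -0.1, 0.9),
            axis_gains=(1.0, 0.9, 1.1),
            noise_std=0.2,
        ),
        ClassSpec(
            "stairs_up",
            fundamental_hz=1.6,
            harmonics=(0.9, 0.5),
            axis_offsets=(0.3, -0.15, 0.9),
            axis_gains=(0.7, 1.0, 0.9),
            noise_std=0.2,
        ),
        ClassSpec(
            "stairs_down",
            fundamental_hz=2.3,
            harmonics=(1.0, 0.2, 0.45),
            axis_offsets=(0.25, -0.2, 0.92),
            axis_gains=(0.9, 0.7, 1.0),
            noise_std=0.2,
        ),
        ClassSpec(
            "sitting",
            fundamental_hz=0.7,
            harmonics=(0.3,),
            axis_offsets=(0.0, 0.7, 0.7),
            axis_gains=(1.0, 0.6, 0.6),
            noise_std=0.2,
        ),
        ClassSpec(
            "standing",
            fundamental_hz=4.2,
            harmonics=(0.35,),
            axis_offsets=(0.05, 0.0, 1.0),
            axis_gains=(1.0, 0.8, 0.8),
            noise_std=0.2,
        ),
    )
    kwargs = dict(
        classes=classes,
        subjects=10,
        subject_jitter=0.05,
        sampling_rate=50.0,
        seg_len=128,
        instances_per_class_per_subject=4,
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def config_from_dict(obj: dict, seed: int | None = None) -> GeneratorConfig:
    """Build a GeneratorConfig from a YAML/JSON mapping; unspecified fields
    fall back to the frozen defaults."""
    obj = dict(obj or {})
    if seed is not None:
        obj["seed"] = seed
    classes = obj.pop("classes", None)
    if classes is not None:
        obj["classes"] = tuple(
            ClassSpec(
                name=c["name"],
                fundamental_hz=float(c["fundamental_hz"]),
                harmonics=tuple(float(a) for a in c["harmonics"]),
                axis_offsets=tuple(float(a) for a in c.get("axis_offsets", (0, 0, 1))),
                axis_gains=tuple(float(a) for a in c.get("axis_gains", (1, 1, 1))),
                noise_std=float(c.get("noise_std", 0.05)),
            )
            for c in classes
        )
        return GeneratorConfig(**obj)
    return default_config(**obj)


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Deterministic synthetic benchmark dataset.

    Per (subject, class, axis), the phase and the subject's jitter factors are
    drawn once from a subject/class-keyed stream, so with zero noise every
    instance of a class for a given subject is identical; instance-level
    variation comes from the per-instance noise stream.
    """
    t = np.arange(config.seg_len) / config.sampling_rate
    instances: list[Instance] = []
    for s_idx in range(config.subjects):
        subject = f"S{s_idx:02d}"
        for c_idx, spec in enumerate(config.classes):
            sc_rng = _rng(config.seed, s_idx, c_idx)
            amp_jit = max(0.2, 1.0 + config.subject_jitter * sc_rng.standard_normal())
            freq_jit = max(0.2, 1.0 + config.subject_jitter * sc_rng.standard_normal())
            phases = sc_rng.uniform(0, 2 * np.pi, size=(3, len(spec.harmonics)))
            f0 = spec.fundamental_hz * freq_jit
            clean = np.empty((config.seg_len, 3))
            for axis in range(3):
                sig = np.full(config.seg_len, spec.axis_offsets[axis], dtype=float)
                gain = spec.axis_gains[axis] * amp_jit
                for k, amp in enumerate(spec.harmonics, start=1):
                    sig += gain * amp * np.sin(
                        2 * np.pi * k * f0 * t + phases[axis, k - 1]
                    )
                clean[:, axis] = sig
            for i_idx in range(config.instances_per_class_per_subject):
                noise_rng = _rng(config.seed, s_idx, c_idx, i_idx)
                noise = noise_rng.normal(0.0, spec.noise_std, size=(config.seg_len, 3))
                instances.append(
                    Instance(segment=clean + noise, label=spec.name, subject=subject)
                )
    return LabeledDataset.from_instances(
        instances, provenance={"generator": "synthetic", "seed": config.seed}
    )


@dataclass(frozen=True)
class FallConfig:
    """Quiescent ~1 g recording with injected transient spikes above 1.5 g."""

    duration_s: float = 30.0
    sampling_rate: float = 50.0
    n_spikes: int = 3
    spike_amplitude: float = 2.0
    spike_width_s: float = 0.12
    noise_std: float = 0.02
    spike_times_s: tuple[float, ...] | None = None
    seed: int = 0


def fall_like_recording(config: FallConfig) -> RawRecording:
    """Recording whose magnitude rests near 1 g and crosses 1.5 g exactly once
    per injected spike, for exercising peak segmentation.

    Spikes are Gaussian bumps added to the vertical axis; when their centers
    are separated by more than one window, peak segmentation recovers exactly
    one instance per in-bounds spike.
    """
    rng = _rng(config.seed, 97)
    n = round(config.duration_s * config.sampling_rate)
    t = np.arange(n) / config.sampling_rate
    samples = rng.normal(0.0, config.noise_std, size=(n, 3))
    samples[:, 2] += 1.0
    if config.spike_times_s is not None:
        centers = np.asarray(config.spike_times_s, dtype=float)
    else:
        centers = np.linspace(
            0.15 * config.duration_s, 0.85 * config.duration_s, config.n_spikes
        )
    for center in centers:
        bump = config.spike_amplitude * np.exp(
            -0.5 * ((t - center) / config.spike_width_s) ** 2
        )
        samples[:, 2] += bump
    return RawRecording(
        samples=samples,
        sampling_rate=config.sampling_rate,
        label="fall",
        subject="S00",
    )
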