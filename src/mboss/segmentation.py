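"""Segmentation of raw multivariate sensor streams into fixed-length instances.

Raw recordings (one matrix per user/activity, rows = time steps, columns =
sensor axes) are cut into labeled instances either by a fixed-size sliding
window with optional overlap, or — for impact-like events such as falls — by
centering a window on each upward crossing of a magnitude threshold.
Windows fed to the symbolic transform are z-normalized (mean 0, population
standard deviation 1) for amplitude/offset invariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Windows whose population std is below this are treated as flat and map to
#: the all-zero normalized window.
FLAT_STD_EPS = 1e-8


@dataclass(frozen=True)
class RawRecording:
    """A continuous multivariate stream for one subject performing one activity.

    ``samples`` has one row per time step and one column per sensor axis
    (v axes; tri-axial accelerometers give v = 3).
    """

    samples: np.ndarray
    sampling_rate: float
    label: str
    subject: str

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D (time x axes) array")
        if samples.shape[1] < 1:
            raise ValueError("recording needs at least one axis")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_axes(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class Instance:
    """A fixed-length labeled segment: an n x v matrix with class and subject."""

    segment: np.ndarray
    label: str
    subject: str

    def __post_init__(self) -> None:
        segment = np.asarray(self.segment, dtype=float)
        if segment.ndim != 2:
            raise ValueError("segment must be a 2-D (time x axes) array")
        if segment.shape[0] < 2:
            raise ValueError("segment needs at least 2 samples")
        if not np.all(np.isfinite(segment)):
            raise ValueError("segment contains missing or non-finite values")
        object.__setattr__(self, "segment", segment)

    @property
    def n_samples(self) -> int:
        return self.segment.shape[0]

    @property
    def n_axes(self) -> int:
        return self.segment.shape[1]


def sliding_segments(
    recording: RawRecording, seg_len: int, overlap_frac: float = 0.0
) -> list[Instance]:
    """Cut a recording into fixed-size windows with fractional overlap.

    Segment starts advance by ``round(seg_len * (1 - overlap_frac))`` samples;
    a trailing partial segment is discarded.  Each instance inherits the
    recording's label and subject.
    """
    if seg_len < 2:
        raise ValueError("seg_len must be at least 2")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    step = max(1, round(seg_len * (1.0 - overlap_frac)))
    n = recording.n_samples
    out: list[Instance] = []
    for start in range(0, n - seg_len + 1, step):
        out.append(
            Instance(
                segment=recording.samples[start : start + seg_len],
                label=recording.label,
                subject=recording.subject,
            )
        )
    return out


def magnitude(instance: Instance) -> np.ndarray:
    """Per-sample Euclidean norm of a tri-axial instance.

    ``mag(t) = sqrt(ax(t)^2 + ay(t)^2 + az(t)^2)``.
    """
    if instance.n_axes != 3:
        raise ValueError("magnitude requires exactly 3 axes")
    return np.linalg.norm(instance.segment, axis=1)


def _magnitude_of(samples: np.ndarray) -> np.ndarray:
    return np.linalg.norm(samples, axis=1)


def peak_segments(
    recording: RawRecording, threshold: float = 1.5, seg_seconds: float = 3.0
) -> list[Instance]:
    """Extract windows centered on upward magnitude-threshold crossings.

    A peak at index t is valid iff ``mag(t) > threshold`` and
    ``mag(t-1) < threshold`` (an upward crossing).  Each valid peak yields one
    instance of ``round(seg_seconds * sampling_rate)`` samples centered on it,
    with floor((len-1)/2) samples before the peak.  Peaks whose window would
    exceed the recording bounds are skipped.  Data are assumed expressed in g
    units, so the default 1.5 threshold is the 1.5 g rule used for fall-like
    events.
    """
    if recording.n_axes != 3:
        raise ValueError("peak segmentation requires a 3-axis recording")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    mag = _magnitude_of(recording.samples)
    seg_len = round(seg_seconds * recording.sampling_rate)
    before = (seg_len - 1) // 2
    n = recording.n_samples
    out: list[Instance] = []
    for t in range(1, n):
        if mag[t] > threshold and mag[t - 1] < threshold:
            start = t - before
            end = start + seg_len
            if start < 0 or end > n:
                continue
            out.append(
                Instance(
                    segment=recording.samples[start:end],
                    label=recording.label,
                    subject=recording.subject,
                )
            )
    return out


def znormalize_window(window: np.ndarray) -> np.ndarray:
    """z-normalize a window to mean 0 and population std 1.

    Flat windows (std below :data:`FLAT_STD_EPS`) map to all zeros, which
    keeps downstream Fourier coefficients finite and well defined.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    mu = x.mean()
    sd = x.std()  # population (1/n) normalization
    if sd < FLAT_STD_EPS:
        return np.zeros_like(x)
    return (x - mu) / sd
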