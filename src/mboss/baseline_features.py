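"""Hand-crafted time/frequency features for baseline comparisons.

Per axis of a tri-axial instance: eight time-domain statistics (mean, median,
min, max, population variance, population std, zero crossing rate, RMS) and
four frequency-domain statistics (DC magnitude, sum of the magnitudes of the
first five non-DC Fourier coefficients, spectral energy, spectral entropy in
nats).  36 features total, axis-major order, with stable names — ready for
any external classifier via CSV export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import Instance

TIME_FEATURE_NAMES = (
    "mean",
    "median",
    "min",
    "max",
    "variance",
    "std",
    "zero_crossing_rate",
    "rms",
)
FREQ_FEATURE_NAMES = (
    "dc",
    "fourier_sum5",
    "spectral_energy",
    "spectral_entropy",
)
AXIS_NAMES = ("x", "y", "z")

#: Frozen axis-major feature-name list (x features, then y, then z).
FEATURE_NAMES = tuple(
    f"{axis}_{name}"
    for axis in AXIS_NAMES
    for name in TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES
)


def time_features(axis_window: np.ndarray) -> np.ndarray:
    """Eight time-domain statistics of one axis window.

    Zero crossing rate counts strict sign flips between consecutive samples,
    divided by n - 1; variance and std are population-normalized (1/n).
    """
    x = np.asarray(axis_window, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    signs = np.sign(x)
    zcr = float(np.count_nonzero(signs[:-1] * signs[1:] < 0)) / (x.size - 1)
    return np.array(
        [
            x.mean(),
            np.median(x),
            x.min(),
            x.max(),
            x.var(),
            x.std(),
            zcr,
            np.sqrt(np.mean(x**2)),
        ]
    )


def frequency_features(axis_window: np.ndarray) -> np.ndarray:
    """Four frequency-domain statistics of one axis window (raw, not
    z-normalized, so the DC component carries the gravity offset).

    Uses the 1/n-normalized DFT.  Spectral energy is the mean squared
    magnitude over the non-DC half-spectrum; spectral entropy is the Shannon
    entropy (nats) of the normalized non-DC power spectrum, 0 for a flat-zero
    spectrum (0 * log 0 = 0).
    """
    x = np.asarray(axis_window, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("window must be 1-D with at least 8 samples")
    n = x.size
    full = np.fft.fft(x) / n
    dc = float(np.abs(full[0]))
    sum5 = float(np.abs(full[1:6]).sum())
    half = np.fft.rfft(x) / n
    power = np.abs(half[1:]) ** 2
    energy = float(power.mean())
    total = power.sum()
    if total <= 0.0:
        entropy = 0.0
    else:
        p = power / total
        p = p[p > 0]
        entropy = float(-(p * np.log(p)).sum())
    return np.array([dc, sum5, energy, entropy])


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")


def feature_vector(instance: Instance) -> FeatureVector:
    """36-dimensional axis-major feature vector of a tri-axial instance."""
    if instance.n_axes != 3:
        raise ValueError("feature_vector requires exactly 3 axes")
    parts = []
    for i in range(3):
        axis = instance.segment[:, i]
        parts.append(time_features(axis))
        parts.append(frequency_features(axis))
    return FeatureVector(values=np.concatenate(parts), names=FEATURE_NAMES)


def feature_matrix(instances) -> tuple[np.ndarray, tuple[str, ...]]:
    """Feature matrix (one row per instance) plus the frozen name tuple."""
    rows = [feature_vector(inst).values for inst in instances]
    return np.vstack(rows), FEATURE_NAMES
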