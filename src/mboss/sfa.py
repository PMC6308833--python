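"""Symbolic Fourier Approximation: DFT truncation plus MCB quantization.

A real-valued window is approximated by its first l/2 Fourier coefficients
(real and imaginary parts interleaved into l reals; the DC coefficient may be
dropped for offset invariance) and each of the l values is quantized against
a per-coefficient breakpoint table (Multiple Coefficient Binning, MCB) fitted
by equi-depth binning of the training coefficients.  The result is a short
word over a small alphabet — the SFA word.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .segmentation import FLAT_STD_EPS

#: Alphabet symbols, in quantization-interval order.
ALPHABET = "abcdefghijklmnopqrstuvwxyz"

#: The recursive sliding DFT is re-seeded with a direct computation every this
#: many windows to bound floating-point drift.
MFT_RESEED_EVERY = 256


def count_possible_words(l: int, c: int) -> int:
    """Number of distinct SFA words of length ``l`` over ``c`` symbols: c**l.

    Raises OverflowError when the count is not representable as a 64-bit
    count, the practical limit for word-indexed histograms.
    """
    if l < 1 or c < 1:
        raise ValueError("word length and alphabet size must be >= 1")
    total = c**l
    if total >= 2**63:
        raise OverflowError("c**l exceeds a 64-bit count")
    return total


@dataclass(frozen=True)
class SFAParams:
    """Tunable triple (window size w, word length l, alphabet size c).

    ``drop_first_coeff`` discards the DC coefficient X0 (the window mean) for
    offset invariance; the l real values then come from X1..X_{l/2}.
    ``normalize_windows`` z-normalizes every sliding window before the DFT;
    ``normalize_series`` instead (or additionally) z-normalizes the whole
    series once before windowing.
    """

    window_size: int
    word_length: int = 16
    alphabet_size: int = 4
    drop_first_coeff: bool = True
    normalize_windows: bool = True
    normalize_series: bool = False

    def __post_init__(self) -> None:
        l, c, w = self.word_length, self.alphabet_size, self.window_size
        if not (4 <= l <= 16) or l % 2 != 0:
            raise ValueError("word_length must be even and in [4, 16]")
        if not (2 <= c <= 26):
            raise ValueError("alphabet_size must lie in [2, 26]")
        count_possible_words(l, c)  # 64-bit representability
        if w < self.min_window:
            raise ValueError(
                f"window_size {w} too small for word_length {l} "
                f"(needs >= {self.min_window})"
            )

    @property
    def n_coeffs(self) -> int:
        return self.word_length // 2

    @property
    def min_window(self) -> int:
        # 2 samples per kept complex coefficient, plus 2 when X0 is dropped.
        return 2 * (self.n_coeffs + int(self.drop_first_coeff))

    def with_word_length(self, l: int) -> "SFAParams":
        return SFAParams(
            window_size=self.window_size,
            word_length=l,
            alphabet_size=self.alphabet_size,
            drop_first_coeff=self.drop_first_coeff,
            normalize_windows=self.normalize_windows,
            normalize_series=self.normalize_series,
        )


def _select_coeffs(spectrum: np.ndarray, params: SFAParams) -> np.ndarray:
    """Interleave real/imag parts of the kept coefficients along the last axis.

    ``spectrum`` is an rfft result already scaled by 1/n.
    """
    start = 1 if params.drop_first_coeff else 0
    sel = spectrum[..., start : start + params.n_coeffs]
    out = np.empty(sel.shape[:-1] + (params.word_length,), dtype=float)
    out[..., 0::2] = sel.real
    out[..., 1::2] = sel.imag
    return out


def dft_coefficients(window: Sequence[float], params: SFAParams) -> np.ndarray:
    """First l/2 Fourier coefficients of a window, 1/n-normalized, interleaved.

    The DFT convention is ``X_u = (1/n) * sum_x T(x) exp(-j 2 pi u x / n)``,
    so the real part of X0 equals the arithmetic mean of the window.  With
    ``drop_first_coeff`` set, X1..X_{l/2} are returned instead of
    X0..X_{l/2 - 1}.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValueError("window must be 1-D")
    needed = 2 * (params.n_coeffs + int(params.drop_first_coeff))
    if x.size < needed:
        raise ValueError(f"window of {x.size} samples is shorter than {needed}")
    if params.drop_first_coeff:
        # mathematically a no-op for the kept bins; numerically it removes
        # the offset exactly rather than up to FFT cancellation error
        x = x - x.mean()
    spectrum = np.fft.rfft(x) / x.size
    return _select_coeffs(spectrum, params)


def mft_sliding_coefficients(
    series: Sequence[float], params: SFAParams
) -> np.ndarray:
    """Coefficient vectors of every sliding window via the Momentary Fourier
    Transform.

    Returns an (n - w + 1, l) array; row i equals
    :func:`dft_coefficients` of the raw window starting at i.  The recursive
    update ``X_u <- exp(j 2 pi u / w) * (X_u + (x[i+w] - x[i]) / w)`` advances
    all kept bins in O(l) per window and is re-seeded with a direct DFT every
    :data:`MFT_RESEED_EVERY` windows.
    """
    x = np.asarray(series, dtype=float)
    w = params.window_size
    if x.ndim != 1 or x.size < w:
        raise ValueError("series must be 1-D with length >= window_size")
    start = 1 if params.drop_first_coeff else 0
    bins = np.arange(start, start + params.n_coeffs)
    factors = np.exp(2j * np.pi * bins / w)
    n_win = x.size - w + 1
    out = np.empty((n_win, params.word_length), dtype=float)

    def direct(i: int) -> np.ndarray:
        spec = np.fft.rfft(x[i : i + w]) / w
        return spec[bins].astype(complex)

    current = direct(0)
    out[0, 0::2] = current.real
    out[0, 1::2] = current.imag
    for i in range(1, n_win):
        if i % MFT_RESEED_EVERY == 0:
            current = direct(i)
        else:
            current = factors * (current + (x[i + w - 1] - x[i - 1]) / w)
        out[i, 0::2] = current.real
        out[i, 1::2] = current.imag
    return out


@dataclass(frozen=True)
class MCBTable:
    """Per-coefficient quantization breakpoints.

    ``breakpoints`` is a (c + 1) x l matrix; column j holds
    -inf = beta_j(0) <= beta_j(1) <= ... <= beta_j(c) = +inf, and coefficient
    value t falls in interval a (symbol ``alphabet[a]``) iff
    beta_j(a) <= t < beta_j(a + 1) (half-open; boundary values join the upper
    interval).
    """

    breakpoints: np.ndarray
    alphabet: str

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        c = len(self.alphabet)
        if bp.ndim != 2 or bp.shape[0] != c + 1:
            raise ValueError("breakpoints must be (c + 1) x l")
        if not np.all(np.isneginf(bp[0])) or not np.all(np.isposinf(bp[-1])):
            raise ValueError("breakpoint columns must start at -inf, end at +inf")
        if np.any(np.diff(bp[1:-1], axis=0) < 0):
            raise ValueError("interior breakpoints must be non-decreasing")
        object.__setattr__(self, "breakpoints", bp)

    @property
    def word_length(self) -> int:
        return self.breakpoints.shape[1]

    @property
    def alphabet_size(self) -> int:
        return len(self.alphabet)

    def truncated(self, l_new: int) -> "MCBTable":
        """Table restricted to the first ``l_new`` coefficient columns."""
        if l_new > self.word_length:
            raise ValueError("cannot truncate to a longer word")
        return MCBTable(self.breakpoints[:, :l_new].copy(), self.alphabet)

    def to_json(self) -> str:
        cols = []
        for j in range(self.word_length):
            col = []
            for v in self.breakpoints[:, j]:
                if np.isneginf(v):
                    col.append("-inf")
                elif np.isposinf(v):
                    col.append("inf")
                else:
                    col.append(v)
            cols.append(col)
        return json.dumps(
            {
                "alphabet_size": self.alphabet_size,
                "word_length": self.word_length,
                "breakpoints": cols,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MCBTable":
        obj = json.loads(text)
        c, l = obj["alphabet_size"], obj["word_length"]
        bp = np.empty((c + 1, l), dtype=float)
        for j, col in enumerate(obj["breakpoints"]):
            bp[:, j] = [float(v) for v in col]
        return cls(bp, ALPHABET[:c])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "MCBTable":
        return cls.from_json(Path(path).read_text())


def fit_mcb(coeff_matrix: np.ndarray, c: int) -> MCBTable:
    """Fit equi-depth breakpoints per coefficient column.

    Each of the l columns of the N x l training matrix is sorted and split
    into c equi-depth bins: interior breakpoint a (1 <= a <= c - 1) is the
    sorted value at 0-based rank ceil(a * N / c), i.e. the first element of
    the next bin.  Ties may collapse duplicate breakpoints (emptying a bin);
    the half-open interval rule stays well defined.
    """
    A = np.asarray(coeff_matrix, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("coefficient matrix must be 2-D and non-empty")
    N, l = A.shape
    if N < c:
        raise ValueError(f"need at least c={c} training rows, got {N}")
    if not (2 <= c <= 26):
        raise ValueError("alphabet size must lie in [2, 26]")
    srt = np.sort(A, axis=0)
    ranks = [math.ceil(a * N / c) for a in range(1, c)]
    bp = np.empty((c + 1, l), dtype=float)
    bp[0] = -np.inf
    bp[-1] = np.inf
    bp[1:-1] = srt[ranks, :]
    return MCBTable(bp, ALPHABET[:c])


def symbol_indices(coeff_matrix: np.ndarray, mcb: MCBTable) -> np.ndarray:
    """Vectorized quantization: map an (..., l) coefficient array to symbol
    indices in [0, c) per column, boundary values joining the upper interval."""
    A = np.asarray(coeff_matrix, dtype=float)
    if A.shape[-1] != mcb.word_length:
        raise ValueError("coefficient length does not match MCB columns")
    out = np.empty(A.shape, dtype=np.uint8)
    interior = mcb.breakpoints[1:-1]  # (c - 1, l)
    for j in range(mcb.word_length):
        out[..., j] = np.searchsorted(interior[:, j], A[..., j], side="right")
    return out


def discretize(coeffs: np.ndarray, mcb: MCBTable) -> str:
    """Quantize one coefficient vector into an SFA word."""
    v = np.asarray(coeffs, dtype=float)
    if v.ndim != 1 or v.size != mcb.word_length:
        raise ValueError("coefficient vector length does not match MCB columns")
    idx = symbol_indices(v[None, :], mcb)[0]
    return "".join(mcb.alphabet[i] for i in idx)


def sliding_coefficients(series: np.ndarray, params: SFAParams) -> np.ndarray:
    """Coefficient vectors of every (optionally z-normalized) sliding window.

    This is the transform actually used by the bag-of-words pipeline: windows
    are extracted with a strided view, z-normalized per ``params``, and
    transformed with a batched rfft (numerically identical to the per-window
    DFT; see :func:`mft_sliding_coefficients` for the incremental variant).
    Flat windows map to all-zero coefficient vectors.
    """
    x = np.asarray(series, dtype=float)
    w = params.window_size
    if x.ndim != 1 or x.size < w:
        raise ValueError("series must be 1-D with length >= window_size")
    if params.normalize_series:
        mu, sd = x.mean(), x.std()
        x = np.zeros_like(x) if sd < FLAT_STD_EPS else (x - mu) / sd
    wins = np.lib.stride_tricks.sliding_window_view(x, w).astype(float)
    if params.normalize_windows:
        mu = wins.mean(axis=1, keepdims=True)
        sd = wins.std(axis=1, keepdims=True)
        wins = np.where(sd < FLAT_STD_EPS, 0.0, (wins - mu) / np.maximum(sd, FLAT_STD_EPS))
    elif params.drop_first_coeff:
        wins = wins - wins.mean(axis=1, keepdims=True)
    spectrum = np.fft.rfft(wins, axis=1) / w
    return _select_coeffs(spectrum, params)
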