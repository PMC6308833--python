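"""Bag-Of-SFA-Symbols histograms and their multivariate fusion (MBOSS).

Every sliding window of a series becomes an SFA word; numerosity reduction
counts a word only when it differs from the immediately preceding one,
suppressing runs from stable signal regions.  For multivariate instances the
per-axis histograms are fused by prefixing each word with its source-axis
identifier (axis 2, word "ab" -> "2ab") and taking the disjoint union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .segmentation import Instance
from .sfa import MCBTable, SFAParams, sliding_coefficients, symbol_indices


def axis_prefix(axis_id: int) -> str:
    """Axis identifier prepended to each word.

    Single-digit axes use the bare digit (the common tri-axial case); axes
    beyond 9 are delimited with '|' so prefixes stay unambiguous.
    """
    if axis_id < 1:
        raise ValueError("axis_id must be >= 1")
    return str(axis_id) if axis_id <= 9 else f"{axis_id}|"


def split_axis_prefix(word: str) -> tuple[str, str]:
    """Split a stored word into (prefix, symbols)."""
    if "|" in word:
        pre, _, sym = word.partition("|")
        return pre + "|", sym
    return word[:1], word[1:]


@dataclass(frozen=True)
class WordSequence:
    """Ordered SFA words, one per window position, for one axis of one series.

    The full sequence (not just its histogram) is retained so that smaller
    word lengths can be derived by truncation without recomputing the
    transform.
    """

    words: tuple[str, ...]
    axis_id: int

    def __len__(self) -> int:
        return len(self.words)


@dataclass
class WordHistogram:
    """Sparse word -> count map; the BOSS/MBOSS feature object."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


def boss_word_sequence(
    series: Sequence[float],
    params: SFAParams,
    mcb: MCBTable,
    axis_id: int,
) -> WordSequence:
    """SFA words of every sliding window of one axis, axis-prefixed.

    Window i (start offset i) is z-normalized per ``params``, transformed to
    its truncated Fourier coefficients and quantized against ``mcb``; there
    are exactly n - w + 1 words.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < params.window_size:
        raise ValueError("series must be 1-D with length >= window_size")
    if mcb.word_length != params.word_length:
        raise ValueError("MCB word length does not match params")
    coeffs = sliding_coefficients(x, params)
    idx = symbol_indices(coeffs, mcb)
    pre = axis_prefix(axis_id)
    alpha = mcb.alphabet
    words = tuple(pre + "".join(alpha[i] for i in row) for row in idx)
    return WordSequence(words=words, axis_id=axis_id)


def numerosity_reduce(seq: WordSequence) -> WordHistogram:
    """Histogram with numerosity reduction.

    A word is counted only when it differs from the immediately preceding word
    in the sequence; the first word is always counted.
    """
    counts: dict[str, int] = {}
    last: str | None = None
    for word in seq.words:
        if word != last:
            counts[word] = counts.get(word, 0) + 1
        last = word
    return WordHistogram(counts)


def truncate_words(seq: WordSequence, l_new: int) -> WordSequence:
    """Shorten every word to its first ``l_new`` symbols, keeping the prefix.

    Numerosity reduction is *not* applied here; it is reapplied downstream on
    the truncated sequence.
    """
    if l_new % 2 != 0:
        raise ValueError("l_new must be even")
    if seq.words:
        _, sym = split_axis_prefix(seq.words[0])
        if l_new > len(sym):
            raise ValueError("l_new exceeds the stored word length")
    new_words = []
    for word in seq.words:
        pre, sym = split_axis_prefix(word)
        new_words.append(pre + sym[:l_new])
    return WordSequence(words=tuple(new_words), axis_id=seq.axis_id)


def mboss_transform(
    instance: Instance,
    params: SFAParams,
    mcbs: Sequence[MCBTable],
) -> WordHistogram:
    """Fused multivariate histogram of one instance.

    Equals the disjoint (axis-prefixed) union of the numerosity-reduced
    per-axis histograms; the last-word comparison is reset at each axis
    boundary.
    """
    if len(mcbs) != instance.n_axes:
        raise ValueError(
            f"need one MCB per axis: {instance.n_axes} axes, {len(mcbs)} tables"
        )
    fused: dict[str, int] = {}
    for i in range(instance.n_axes):
        seq = boss_word_sequence(
            instance.segment[:, i], params, mcbs[i], axis_id=i + 1
        )
        for word, count in numerosity_reduce(seq).counts.items():
            fused[word] = fused.get(word, 0) + count
    return WordHistogram(fused)


def fit_axis_mcbs(
    instances: Sequence[Instance], params: SFAParams
) -> list[MCBTable]:
    """Fit one MCB per axis on the coefficient vectors of all sliding windows
    of all training instances."""
    from .sfa import fit_mcb  # local import keeps module load order simple

    if not instances:
        raise ValueError("no training instances")
    v = instances[0].n_axes
    mcbs = []
    for i in range(v):
        rows = [
            sliding_coefficients(inst.segment[:, i], params) for inst in instances
        ]
        mcbs.append(fit_mcb(np.concatenate(rows, axis=0), params.alphabet_size))
    return mcbs
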