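"""Dataset/model readers and writers and memory accounting.

Datasets travel as long-format CSV (header ``subject,label,t,<axis1>,...``;
the pre-segmented variant adds an ``instance`` column); models, histograms
and reports as JSON; configs as YAML.  The memory report compares the raw
footprint of a dataset (8 bytes per double sample) with the serialized size
of its word histograms (UTF-8 words plus a 4-byte count each).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .boss import WordHistogram, fit_axis_mcbs, mboss_transform
from .segmentation import Instance, RawRecording, peak_segments, sliding_segments
from .sfa import SFAParams


@dataclass
class LabeledDataset:
    """Collection of labeled, subject-tagged instances plus provenance."""

    instances: list[Instance]
    class_order: list[str]
    subjects: list[str]
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_instances(cls, instances: Sequence[Instance], provenance=None):
        instances = list(instances)
        return cls(
            instances=instances,
            class_order=sorted({i.label for i in instances}),
            subjects=sorted({i.subject for i in instances}),
            provenance=provenance or {},
        )

    def __post_init__(self) -> None:
        known = set(self.class_order)
        for inst in self.instances:
            if inst.label not in known:
                raise ValueError(f"instance label {inst.label!r} not in class_order")
        axes = {inst.n_axes for inst in self.instances}
        if len(axes) > 1:
            raise ValueError("instances have inconsistent axis counts")

    def __len__(self) -> int:
        return len(self.instances)


@dataclass(frozen=True)
class SegmentationConfig:
    """How to turn raw CSV streams into instances."""

    mode: str = "sliding"  # sliding | peak | presegmented
    seg_len: int = 128
    overlap_frac: float = 0.5
    threshold: float = 1.5
    seg_seconds: float = 3.0
    sampling_rate: float = 50.0

    def __post_init__(self) -> None:
        if self.mode not in ("sliding", "peak", "presegmented"):
            raise ValueError(f"unknown segmentation mode {self.mode!r}")


REQUIRED_COLUMNS = ("subject", "label", "t")


def read_dataset(
    path: str | Path, seg_config: SegmentationConfig | None = None
) -> LabeledDataset:
    """Read a long-format CSV and segment it into instances.

    Streams are grouped by (subject, label) — or (subject, label, instance)
    in presegmented mode — ordered by the ``t`` column.  Malformed rows are
    reported with their 1-based line numbers; nothing is silently coerced.
    """
    seg_config = seg_config or SegmentationConfig()
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if seg_config.mode == "presegmented" and "instance" not in df.columns:
        missing.append("instance")
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    meta = list(REQUIRED_COLUMNS) + (
        ["instance"] if seg_config.mode == "presegmented" else []
    )
    axis_cols = [c for c in df.columns if c not in meta and c != "instance"]
    if not axis_cols:
        raise ValueError(f"{path}: no axis columns found")

    numeric = df[["t"] + axis_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | df[["subject", "label"]].isna().any(axis=1)
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines[:20]}")
    df[["t"] + axis_cols] = numeric

    instances: list[Instance] = []
    if seg_config.mode == "presegmented":
        for (subject, label, _inst), grp in df.groupby(
            ["subject", "label", "instance"], sort=True
        ):
            grp = grp.sort_values("t")
            instances.append(
                Instance(
                    segment=grp[axis_cols].to_numpy(float),
                    label=label,
                    subject=subject,
                )
            )
    else:
        for (subject, label), grp in df.groupby(["subject", "label"], sort=True):
            grp = grp.sort_values("t")
            rec = RawRecording(
                samples=grp[axis_cols].to_numpy(float),
                sampling_rate=seg_config.sampling_rate,
                label=label,
                subject=subject,
            )
            if seg_config.mode == "sliding":
                instances.extend(
                    sliding_segments(rec, seg_config.seg_len, seg_config.overlap_frac)
                )
            else:
                instances.extend(
                    peak_segments(rec, seg_config.threshold, seg_config.seg_seconds)
                )
    if not instances:
        raise ValueError(f"{path}: no instances after segmentation")
    return LabeledDataset.from_instances(
        instances,
        provenance={"source": str(path), "segmentation": seg_config.mode},
    )


def write_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a dataset in the pre-segmented long CSV format (round-trippable
    with ``SegmentationConfig(mode="presegmented")``)."""
    path = Path(path)
    frames = []
    for k, inst in enumerate(dataset.instances):
        n, v = inst.segment.shape
        frame = {
            "subject": [inst.subject] * n,
            "label": [inst.label] * n,
            "instance": [k] * n,
            "t": list(range(n)),
        }
        for a in range(v):
            frame[f"a{a + 1}" if v != 3 else "xyz"[a]] = inst.segment[:, a]
        frames.append(pd.DataFrame(frame))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# memory accounting
# ---------------------------------------------------------------------------

#: Bytes per raw sample (double precision).
BYTES_PER_SAMPLE = 8
#: Bytes per stored word count.
BYTES_PER_COUNT = 4


@dataclass(frozen=True)
class MemoryReport:
    raw_bytes: int
    symbolic_bytes: int
    reduction_percent: float

    def to_jsonable(self) -> dict:
        return {
            "raw_bytes": self.raw_bytes,
            "symbolic_bytes": self.symbolic_bytes,
            "reduction_percent": self.reduction_percent,
        }


def histogram_bytes(hist: WordHistogram) -> int:
    """Serialized size of one histogram: UTF-8 word bytes + 4 bytes per count."""
    return sum(len(w.encode("utf-8")) + BYTES_PER_COUNT for w in hist.counts)


def memory_report(
    dataset: LabeledDataset,
    params: SFAParams,
    mcbs=None,
    histograms: Sequence[WordHistogram] | None = None,
) -> MemoryReport:
    """Raw vs symbolic footprint of a dataset under a fitted transform.

    raw_bytes = instances x n x v x 8; symbolic_bytes sums the serialized
    histogram sizes.  Histograms are computed with the given (or freshly
    fitted) MCB tables unless supplied.
    """
    if not dataset.instances:
        return MemoryReport(0, 0, 0.0)
    raw = sum(
        inst.n_samples * inst.n_axes * BYTES_PER_SAMPLE for inst in dataset.instances
    )
    if histograms is None:
        if mcbs is None:
            mcbs = fit_axis_mcbs(dataset.instances, params)
        histograms = [
            mboss_transform(inst, params, mcbs) for inst in dataset.instances
        ]
    symbolic = sum(histogram_bytes(h) for h in histograms)
    return MemoryReport(
        raw_bytes=raw,
        symbolic_bytes=symbolic,
        reduction_percent=100.0 * (1.0 - symbolic / raw),
    )


# ---------------------------------------------------------------------------
# JSON / YAML helpers
# ---------------------------------------------------------------------------


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, repr-round-trip floats)."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def histograms_to_json(hists: Sequence[WordHistogram]) -> list[dict]:
    return [dict(sorted(h.counts.items())) for h in hists]


def histograms_to_triplets(
    hists: Sequence[WordHistogram],
) -> tuple[list[str], list[tuple[int, int, int]]]:
    """Sparse (instance, word-index, count) triplets over the union vocabulary,
    for export to external classifiers."""
    vocab = sorted({w for h in hists for w in h.counts})
    index = {w: j for j, w in enumerate(vocab)}
    triplets = [
        (i, index[w], c)
        for i, h in enumerate(hists)
        for w, c in sorted(h.counts.items())
    ]
    return vocab, triplets
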