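"""Epoch extraction from PSG/hypnogram text exports.

Takes the two text files an EDF browser export produces (a time/value
trace and a stage annotation list), cuts the trace into 30 s scoring
epochs, applies the study's filtering rules and produces the per-recording
dataset file ``input{PP}{n}.csv`` consumed by training.

Filtering rules, applied in this order:

1. movement (``M``) and not-scored (``?``) epochs are skipped;
2. of the leading run of wake (``W``) epochs, only the last one - the one
   immediately before the first non-wake epoch - is kept.

Every surviving epoch is labelled ``REM`` (stage R) or ``NonREM``
(everything else).  Normalization statistics (mean and population SD) are
computed across the entire dataset of retained epochs.
"""

from __future__ import annotations

import logging
import sys
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RecordingId",
    "EpochRecord",
    "EpochDataset",
    "NormalizationParams",
    "ParseError",
    "parse_psg_text",
    "parse_hypnogram_text",
    "cut_epochs",
    "filter_and_trim",
    "binarize",
    "compute_normalization",
    "write_epoch_file",
    "read_epoch_file",
    "prepare_recording",
]

VALID_STAGES = ("W", "R", "1", "2", "3", "4", "M", "?")
SKIPPED_STAGES = ("M", "?")
REM_LABEL = "REM"
NONREM_LABEL = "NonREM"


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class RecordingId:
    """Two-digit patient code plus one-digit night code."""

    patient: int
    night: int

    def __post_init__(self):
        if not 0 <= self.patient <= 99:
            raise ValueError(f"patient code outside 0..99: {self.patient}")
        if not 0 <= self.night <= 9:
            raise ValueError(f"night code outside 0..9: {self.night}")

    @property
    def filename(self) -> str:
        """Dataset file name, ``input{PP}{n}.csv`` with zero-padded patient."""
        return f"input{self.patient:02d}{self.night:d}.csv"


@dataclass
class EpochRecord:
    """One scored 30 s epoch: samples, hypnogram stage, ordinal index."""

    samples: np.ndarray
    stage: str
    index: int

    @property
    def binary_label(self) -> str:
        return binarize(self.stage)


@dataclass
class NormalizationParams:
    """Z-score parameters (normMean / normSTD) over a whole dataset."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError(f"normalization sd must be positive, got {self.sd}")

    def apply(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


@dataclass
class EpochDataset:
    """Retained epochs across one or more recordings.

    ``annotation_counts`` keeps the pre-filter stage tallies (the counts
    printed to standard out during preparation).
    """

    records: list = field(default_factory=list)
    source_files: list = field(default_factory=list)
    annotation_counts: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.binary_label for r in self.records]

    def sample_matrix(self) -> np.ndarray:
        return np.stack([r.samples for r in self.records])


def _parse_row(line: str, lineno: int, path, n_fields: int) -> list[float]:
    for sep in ("\t", ",", None):
        parts = line.split(sep) if sep else line.split()
        if len(parts) >= n_fields:
            try:
                return [float(p) for p in parts[:n_fields]]
            except ValueError:
                continue
    raise ParseError(f"{path}:{lineno}: malformed row: {line!r}")


def parse_psg_text(path) -> np.ndarray:
    """Read a time/value PSG text export; returns samples ordered by time.

    Accepts tab-, comma- or whitespace-separated two-column rows; a
    non-numeric first line is treated as a header.  A malformed data row
    raises :class:`ParseError` naming the line.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if lineno == 1:
                try:
                    t, v = _parse_row(line, lineno, path, 2)
                except ParseError:
                    continue  # header line
                times.append(t)
                values.append(v)
                continue
            t, v = _parse_row(line, lineno, path, 2)
            times.append(t)
            values.append(v)
    if not values:
        return np.empty(0)
    order = np.argsort(np.asarray(times), kind="stable")
    return np.asarray(values, dtype=float)[order]


def parse_hypnogram_text(path) -> list[tuple[float, str]]:
    """Read ``onset_s<TAB>duration_s<TAB>stage`` annotation rows."""
    path = Path(path)
    annotations: list[tuple[float, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 3:
                if lineno == 1:
                    continue  # tolerate a header
                raise ParseError(f"{path}:{lineno}: malformed annotation: {line!r}")
            try:
                onset = float(parts[0])
            except ValueError as exc:
                if lineno == 1:
                    continue
                raise ParseError(f"{path}:{lineno}: bad onset {parts[0]!r}") from exc
            stage = parts[2].strip()
            if stage not in VALID_STAGES:
                raise ParseError(f"{path}:{lineno}: unknown stage {stage!r}")
            annotations.append((onset, stage))
    return annotations


def cut_epochs(
    samples,
    annotations,
    samples_per_epoch: int = 3000,
    sample_rate: float = 100.0,
) -> list[EpochRecord]:
    """Cut the trace into one epoch per annotation.

    Epoch windows are half-open ``[onset, onset + epoch)`` in 0-based
    samples; an annotation whose full window runs past the end of the
    signal is dropped with a warning.
    """
    x = np.asarray(samples, dtype=float)
    out: list[EpochRecord] = []
    for idx, (onset_s, stage) in enumerate(annotations):
        start = int(round(onset_s * sample_rate))
        stop = start + samples_per_epoch
        if start < 0 or stop > x.size:
            logger.warning(
                "annotation %d at t=%.1fs needs samples %d..%d but signal has %d; dropped",
                idx, onset_s, start, stop, x.size,
            )
            continue
        out.append(EpochRecord(samples=x[start:stop], stage=stage, index=idx))
    return out


def filter_and_trim(epochs: list[EpochRecord]) -> list[EpochRecord]:
    """Apply the stage-filtering rules, preserving order.

    Skips M/? epochs first, then trims the leading wake run down to its
    final epoch.  A recording that never leaves wake yields no epochs.
    Idempotent.
    """
    kept = [e for e in epochs if e.stage not in SKIPPED_STAGES]
    first_non_wake = next((i for i, e in enumerate(kept) if e.stage != "W"), None)
    if first_non_wake is None:
        return []
    start = max(0, first_non_wake - 1)
    return kept[start:]


def binarize(stage: str) -> str:
    """Map a hypnogram stage to the binary REM / NonREM label."""
    if stage in SKIPPED_STAGES:
        raise ValueError(
            f"stage {stage!r} must be filtered out before binarization"
        )
    if stage not in VALID_STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return REM_LABEL if stage == "R" else NONREM_LABEL


def compute_normalization(dataset: EpochDataset | list[EpochRecord]) -> NormalizationParams:
    """Mean and population SD over every sample of every retained epoch."""
    records = dataset.records if isinstance(dataset, EpochDataset) else dataset
    if not records:
        raise ValueError("cannot normalize an empty dataset")
    flat = np.concatenate([np.asarray(r.samples, dtype=float) for r in records])
    mean = float(flat.mean())
    sd = float(flat.std())  # population (divide-by-N)
    if sd == 0.0:
        raise ValueError("dataset has zero variance; normalization undefined")
    return NormalizationParams(mean=mean, sd=sd)


def write_epoch_file(dataset: EpochDataset | list[EpochRecord], rec_id: RecordingId, out_dir) -> Path:
    """Write ``input{PP}{n}.csv``: one line per epoch, label field first."""
    records = dataset.records if isinstance(dataset, EpochDataset) else dataset
    if not records:
        raise ValueError("refusing to write an empty epoch file")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / rec_id.filename
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            values = ",".join(f"{v:.8g}" for v in np.asarray(rec.samples, dtype=float))
            fh.write(f"{rec.binary_label},{values}\n")
    return path


def read_epoch_file(path) -> tuple[list[str], np.ndarray]:
    """Read an ``inputPPn.csv`` file back into labels and a sample matrix."""
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            label, _, rest = line.partition(",")
            if label not in (REM_LABEL, NONREM_LABEL):
                raise ParseError(f"{path}:{lineno}: unknown label {label!r}")
            labels.append(label)
            rows.append(np.array(rest.split(","), dtype=float))
    return labels, (np.stack(rows) if rows else np.empty((0, 0)))


def prepare_recording(
    psg_path,
    hyp_path,
    samples_per_epoch: int = 3000,
    sample_rate: float = 100.0,
    stream=None,
) -> tuple[list[EpochRecord], Counter]:
    """Parse, cut and filter one recording; print per-stage counts.

    Returns the retained epochs plus the pre-filter annotation tallies,
    which are also written to ``stream`` (default stdout) as
    ``stage<TAB>count`` lines.
    """
    samples = parse_psg_text(psg_path)
    annotations = parse_hypnogram_text(hyp_path)
    epochs = cut_epochs(samples, annotations, samples_per_epoch, sample_rate)
    counts = Counter(e.stage for e in epochs)
    stream = sys.stdout if stream is None else stream
    for stage in VALID_STAGES:
        if counts.get(stage):
            print(f"{stage}\t{counts[stage]}", file=stream)
    return filter_and_trim(epochs), counts
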