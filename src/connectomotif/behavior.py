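"""Behavioral performance on the center-embedded sentence task.

Each training day a subject hears 33 single- and 33 double-center-embedded
sentences, each followed by a content question about thematic-role
assignment.  Performance is the proportion of correct *first* answers:

    performance = n_correct / (n_correct + n_incorrect + n_missed)

Second questions after repeated sentences never enter the score.  The
training effect is the day-4 minus day-1 performance.  Double-embedding
performance is the default analysis variable (single embeddings sit near
ceiling); reading-span and digit-span working-memory scores ride along as
optional covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError, MissingDataError, UsageError

SENTENCE_TYPES = ("single", "double")
TRIALS_PER_TYPE_PER_DAY = 33


@dataclass(frozen=True)
class AnswerCounts:
    """First-answer outcome counts for one subject, day and sentence type."""

    subject: str
    day: int
    sentence_type: str
    n_correct: int
    n_incorrect: int
    n_missed: int

    def __post_init__(self) -> None:
        if self.sentence_type not in SENTENCE_TYPES:
            raise UsageError(f"unknown sentence type {self.sentence_type!r}")
        if min(self.n_correct, self.n_incorrect, self.n_missed) < 0:
            raise DomainError("answer counts must be nonnegative")
        if self.total == 0:
            raise DomainError("at least one answer outcome required")
        if self.total != TRIALS_PER_TYPE_PER_DAY:
            warnings.warn(
                f"{self.subject} day {self.day} {self.sentence_type}: "
                f"{self.total} trials (design has {TRIALS_PER_TYPE_PER_DAY})",
                stacklevel=2,
            )

    @property
    def total(self) -> int:
        return self.n_correct + self.n_incorrect + self.n_missed


def performance(counts: AnswerCounts) -> float:
    """Proportion of correct first answers."""
    return counts.n_correct / counts.total


@dataclass
class BehavioralTable:
    """All answer-count records plus optional per-subject span covariates.

    ``spans`` maps subject -> {"reading_span": x, "digit_span": y}; spans
    are stored as one real per type (forward and backward levels averaged
    upstream where applicable).
    """

    records: dict[tuple[str, int, str], AnswerCounts]
    spans: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: list[AnswerCounts],
                     spans: dict[str, dict[str, float]] | None = None
                     ) -> "BehavioralTable":
        table: dict[tuple[str, int, str], AnswerCounts] = {}
        for rec in records:
            key = (rec.subject, rec.day, rec.sentence_type)
            if key in table:
                raise UsageError(f"duplicate behavioral record for {key}")
            table[key] = rec
        return cls(records=table, spans=spans or {})

    def record(self, subject: str, day: int, sentence_type: str) -> AnswerCounts:
        try:
            return self.records[(subject, day, sentence_type)]
        except KeyError:
            raise MissingDataError(
                f"no behavioral record for subject {subject!r} day {day} "
                f"({sentence_type} embedding)"
            )

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _, _ in self.records})

    def span(self, subject: str, span_type: str) -> float | None:
        return self.spans.get(subject, {}).get(span_type)


def performance_change(
    table: BehavioralTable, subject: str, sentence_type: str = "double"
) -> float:
    """Training effect: day-4 minus day-1 performance."""
    p1 = performance(table.record(subject, 1, sentence_type))
    p4 = performance(table.record(subject, 4, sentence_type))
    return p4 - p1


def performance_vector(
    table: BehavioralTable,
    subjects: list[str],
    day: int,
    sentence_type: str = "double",
) -> np.ndarray:
    """Per-subject performance on one day, aligned to the given subject order."""
    return np.array(
        [performance(table.record(s, day, sentence_type)) for s in subjects]
    )


def performance_change_vector(
    table: BehavioralTable, subjects: list[str], sentence_type: str = "double"
) -> np.ndarray:
    """Per-subject day-4 minus day-1 performance, aligned to subject order."""
    return np.array([performance_change(table, s, sentence_type) for s in subjects])


def span_vector(
    table: BehavioralTable, subjects: list[str], span_type: str
) -> np.ndarray:
    """Per-subject span covariate; missing scores raise."""
    out = []
    for s in subjects:
        v = table.span(s, span_type)
        if v is None:
            raise MissingDataError(f"no {span_type} for subject {s!r}")
        out.append(v)
    return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["subject", "day", "sentence_type", "n_correct", "n_incorrect", "n_missed"]


def load_behavior(
    path: str | Path, spans_path: str | Path | None = None
) -> BehavioralTable:
    """Read the answer-count table (TSV/CSV) and optional spans table.

    The spans table has columns subject, reading_span, digit_span.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise UsageError(f"{path}: missing columns {missing}")
    records = [
        AnswerCounts(
            subject=str(row.subject),
            day=int(row.day),
            sentence_type=str(row.sentence_type),
            n_correct=int(row.n_correct),
            n_incorrect=int(row.n_incorrect),
            n_missed=int(row.n_missed),
        )
        for row in df.itertuples()
    ]
    spans: dict[str, dict[str, float]] = {}
    if spans_path is not None:
        spans_path = Path(spans_path)
        ssep = "\t" if spans_path.suffix in (".tsv", ".txt") else ","
        sdf = pd.read_csv(spans_path, sep=ssep)
        for row in sdf.itertuples():
            spans[str(row.subject)] = {
                k: float(getattr(row, k))
                for k in ("reading_span", "digit_span")
                if hasattr(row, k)
            }
    return BehavioralTable.from_records(records, spans)


def write_behavior(
    table: BehavioralTable, path: str | Path, spans_path: str | Path | None = None
) -> Path:
    """Write the answer-count table as TSV; optionally the spans table too."""
    path = Path(path)
    rows = [
        {
            "subject": r.subject,
            "day": r.day,
            "sentence_type": r.sentence_type,
            "n_correct": r.n_correct,
            "n_incorrect": r.n_incorrect,
            "n_missed": r.n_missed,
        }
        for r in sorted(
            table.records.values(), key=lambda r: (r.subject, r.day, r.sentence_type)
        )
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
    if spans_path is not None and table.spans:
        srows = [
            {"subject": s, **vals} for s, vals in sorted(table.spans.items())
        ]
        pd.DataFrame(srows).to_csv(spans_path, sep="\t", index=False)
    return path
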