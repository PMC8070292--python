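"""Entity-level scoring of predicted mentions against gold annotations.

Matching is mention-level and greedy left-to-right within each (document,
sentence): a prediction is a true positive when it can claim an unmatched
gold annotation — identical span and type under the EXACT policy, or
intersecting span and identical type under OVERLAP.  Counts are pooled
across documents (micro-averaging) before computing precision, recall and
the F1 harmonic mean, all expressed as percentages.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .annotate import EntityMention, EntityType

__all__ = [
    "GoldAnnotation",
    "ConfusionRow",
    "EvalResult",
    "score_entities",
    "f_score",
    "write_confusion_csv",
    "read_gold_tsv",
]

POLICIES = ("EXACT", "OVERLAP")


@dataclass(frozen=True)
class GoldAnnotation:
    """A manually annotated entity span (sentence-relative offsets)."""

    doc_id: str
    sentence_index: int
    start: int
    end: int
    entity_type: EntityType

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gold span must be non-empty")


@dataclass(frozen=True)
class ConfusionRow:
    """Per-document entity-detection counts."""

    doc_id: str
    total_gold: int
    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.total_gold, self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fn != self.total_gold:
            raise ValueError("tp + fn must equal total_gold")


@dataclass(frozen=True)
class EvalResult:
    """Per-document confusion rows plus micro-averaged percentage metrics."""

    rows: tuple[ConfusionRow, ...]
    precision: float
    recall: float
    f1: float

    @property
    def tp(self) -> int:
        return sum(r.tp for r in self.rows)

    @property
    def fp(self) -> int:
        return sum(r.fp for r in self.rows)

    @property
    def fn(self) -> int:
        return sum(r.fn for r in self.rows)


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percentage in, percentage out)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _matches(
    gold: GoldAnnotation, predicted: EntityMention, policy: str
) -> bool:
    if (
        gold.doc_id != predicted.doc_id
        or gold.sentence_index != predicted.sentence_index
        or gold.entity_type is not predicted.entity_type
    ):
        return False
    if policy == "EXACT":
        return gold.start == predicted.start and gold.end == predicted.end
    return predicted.start < gold.end and gold.start < predicted.end


def score_entities(
    gold: Sequence[GoldAnnotation],
    predicted: Sequence[EntityMention],
    policy: str = "EXACT",
) -> EvalResult:
    """Score predictions against gold, producing per-document rows and
    micro-averaged precision / recall / F1 percentages."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")

    doc_ids = sorted(
        {g.doc_id for g in gold} | {p.doc_id for p in predicted}
    )
    rows: list[ConfusionRow] = []
    for doc_id in doc_ids:
        doc_gold = sorted(
            (g for g in gold if g.doc_id == doc_id),
            key=lambda g: (g.sentence_index, g.start, g.end),
        )
        doc_pred = sorted(
            (p for p in predicted if p.doc_id == doc_id),
            key=lambda p: (p.sentence_index, p.start, p.end),
        )
        unmatched = list(doc_gold)
        tp = 0
        for pred in doc_pred:
            hit: Optional[GoldAnnotation] = None
            for g in unmatched:
                if _matches(g, pred, policy):
                    hit = g
                    break
            if hit is not None:
                unmatched.remove(hit)
                tp += 1
        fp = len(doc_pred) - tp
        fn = len(doc_gold) - tp
        rows.append(
            ConfusionRow(
                doc_id=doc_id, total_gold=len(doc_gold), tp=tp, fn=fn, fp=fp
            )
        )

    total_tp = sum(r.tp for r in rows)
    total_fp = sum(r.fp for r in rows)
    total_fn = sum(r.fn for r in rows)
    precision = (
        100.0 * total_tp / (total_tp + total_fp) if total_tp + total_fp else 0.0
    )
    recall = (
        100.0 * total_tp / (total_tp + total_fn) if total_tp + total_fn else 0.0
    )
    return EvalResult(
        rows=tuple(rows),
        precision=precision,
        recall=recall,
        f1=f_score(precision, recall),
    )


def write_confusion_csv(result: EvalResult, path: str | Path) -> None:
    """Per-document confusion matrix plus a final aggregate row."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["doc_id", "total_gold", "tp", "fn", "fp"])
        for row in result.rows:
            writer.writerow([row.doc_id, row.total_gold, row.tp, row.fn, row.fp])
        writer.writerow(
            [
                "TOTAL",
                sum(r.total_gold for r in result.rows),
                result.tp,
                result.fn,
                result.fp,
            ]
        )


def read_gold_tsv(path: str | Path) -> list[GoldAnnotation]:
    """Load gold TSV: doc_id, sentence_index, start, end, entity_type."""
    gold: list[GoldAnnotation] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        for row in reader:
            if not row:
                continue
            gold.append(
                GoldAnnotation(
                    doc_id=row[0],
                    sentence_index=int(row[1]),
                    start=int(row[2]),
                    end=int(row[3]),
                    entity_type=EntityType(row[4]),
                )
            )
    return gold
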