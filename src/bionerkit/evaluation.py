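"""Strict entity-level precision, recall and F1.

A predicted entity counts as a true positive only when its type, start and
end all match a gold entity exactly; a partially overlapping prediction is
both a false positive and a false negative.  Metrics use the zero-denominator
convention P = R = F1 = 0 (configurable to NaN), and the pooled ("micro")
metrics are computed from summed counts across entity types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

from .corpus import Corpus, EntitySpan

if TYPE_CHECKING:  # pragma: no cover
    from .model import TaggerModel

__all__ = ["EvalCounts", "MetricReport", "match_spans", "compute_metrics",
           "evaluate_corpus", "evaluate_predictions"]


@dataclass
class EvalCounts:
    """True/false positive and false negative tallies, per type and pooled."""

    per_type: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def add(self, entity_type: str, tp: int = 0, fp: int = 0, fn: int = 0) -> None:
        a, b, c = self.per_type.get(entity_type, (0, 0, 0))
        self.per_type[entity_type] = (a + tp, b + fp, c + fn)

    def merge(self, other: "EvalCounts") -> None:
        for etype, (tp, fp, fn) in other.per_type.items():
            self.add(etype, tp, fp, fn)

    @property
    def pooled(self) -> tuple[int, int, int]:
        tp = sum(v[0] for v in self.per_type.values())
        fp = sum(v[1] for v in self.per_type.values())
        fn = sum(v[2] for v in self.per_type.values())
        return tp, fp, fn

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvalCounts):
            return NotImplemented
        keys = set(self.per_type) | set(other.per_type)
        return all(
            self.per_type.get(k, (0, 0, 0)) == other.per_type.get(k, (0, 0, 0))
            for k in keys
        )


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


@dataclass
class MetricReport:
    """Precision/recall/F1 per entity type plus the micro-averaged totals."""

    counts: EvalCounts
    per_type: dict[str, tuple[float, float, float]]
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        tp, fp, fn = self.counts.pooled
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "counts": {"tp": tp, "fp": fp, "fn": fn},
            "per_type": {
                etype: {
                    "precision": p,
                    "recall": r,
                    "f1": f,
                    "counts": dict(
                        zip(("tp", "fp", "fn"), self.counts.per_type[etype])
                    ),
                }
                for etype, (p, r, f) in self.per_type.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_table(self) -> str:
        lines = [f"{'type':<16}{'P':>8}{'R':>8}{'F1':>8}{'support':>9}"]
        for etype, (p, r, f) in sorted(self.per_type.items()):
            tp, _, fn = self.counts.per_type[etype]
            lines.append(f"{etype:<16}{p:>8.4f}{r:>8.4f}{f:>8.4f}{tp + fn:>9}")
        tp, _, fn = self.counts.pooled
        lines.append(
            f"{'micro':<16}{self.precision:>8.4f}{self.recall:>8.4f}"
            f"{self.f1:>8.4f}{tp + fn:>9}"
        )
        return "\n".join(lines)


def _assert_no_overlap(spans: Sequence[EntitySpan], side: str) -> None:
    last_end = -1
    for span in sorted(spans):
        if span.start < last_end:
            raise ValueError(f"overlapping spans on the {side} side: {span}")
        last_end = span.end


def match_spans(
    gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]
) -> EvalCounts:
    """Exact (start, end, type) matching for one sentence's span sets."""
    _assert_no_overlap(gold, "gold")
    _assert_no_overlap(pred, "predicted")
    counts = EvalCounts()
    gold_set = {(s.start, s.end, s.entity_type) for s in gold}
    pred_set = {(s.start, s.end, s.entity_type) for s in pred}
    for s in gold:
        counts.add(s.entity_type)  # make sure every gold type is reported
    for start, end, etype in gold_set & pred_set:
        counts.add(etype, tp=1)
    for start, end, etype in pred_set - gold_set:
        counts.add(etype, fp=1)
    for start, end, etype in gold_set - pred_set:
        counts.add(etype, fn=1)
    return counts


def compute_metrics(counts: EvalCounts) -> MetricReport:
    """Apply the P/R/F1 formulas to pooled and per-type counts."""
    per_type = {etype: _prf(*c) for etype, c in counts.per_type.items()}
    precision, recall, f1 = _prf(*counts.pooled)
    return MetricReport(counts, per_type, precision, recall, f1)


def evaluate_predictions(
    gold_spans: Iterable[Sequence[EntitySpan]],
    pred_spans: Iterable[Sequence[EntitySpan]],
) -> MetricReport:
    """Pool per-sentence matches over aligned gold/predicted span lists."""
    counts = EvalCounts()
    for gold, pred in zip(gold_spans, pred_spans, strict=True):
        counts.merge(match_spans(gold, pred))
    return compute_metrics(counts)


def evaluate_corpus(model: "TaggerModel", corpus: Corpus) -> MetricReport:
    """Decode every sentence and score strictly against the gold annotation.

    Predicted tag sequences are converted to spans with the lenient policy
    (orphan inside-tags start a span), gold with the strict policy.
    """
    gold = [sent.spans(policy="strict") for sent in corpus]
    pred = [
        model.predict_spans(sent.words, pos_symbols=sent.pos_tags) for sent in corpus
    ]
    return evaluate_predictions(gold, pred)
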