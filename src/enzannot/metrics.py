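"""Evaluation metrics and benchmark construction.

The metric suite extends the usual confusion-matrix cells with two
"unclassified" cells: UP (gold-positive records the predictor abstained
on) and UN (gold-negative records it abstained on).  Abstentions count
against accuracy and recall but not precision, which matches how
annotation-transfer tools behave: a tool that refuses to call most
queries can still show high precision, so accuracy/recall with UP/UN in
the denominator are the honest summary.

Binary metrics:

    ACC       = (TP + TN) / (TP + FP + TN + FN + UP + UN)
    Precision = TP / (TP + FP)
    NPV       = TN / (TN + FN)
    Recall    = TP / (TP + FN + UP)
    F1        = 2 * Precision * Recall / (Precision + Recall)

Multiclass metrics are one-vs-all macro averages: mACC, mPR and mRecall
are unweighted means of the per-class ACC/Precision/Recall, and
mF1 = 2 * mPR * mRecall / (mPR + mRecall) — the harmonic mean of the two
macro means, NOT the mean of per-class F1 scores (the two disagree on
asymmetric inputs).

Any 0/0 ratio is defined as 0 and the class still counts toward the
macro mean; the report flags which values were degenerate.

Prediction representation used throughout: a mapping from record id to
either ``None`` (the predictor abstained / made no call), an empty list
(a definite non-enzyme call), or a list of :class:`ECNumber` assignments.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

from .ec import ECNumber
from .records import AnnotationTable

__all__ = [
    "ConfusionSummary",
    "MetricReport",
    "binary_metrics",
    "multiclass_metrics",
    "chronological_split",
    "filter_novel_labels",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts including unclassified-positive/-negative cells."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    UP: int = 0
    UN: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN", "UP", "UN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN + self.UP + self.UN


@dataclass
class MetricReport:
    """Metric values as fractions in [0, 1]; scale to percent at display."""

    values: dict[str, float]
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def _ratio(num: int, den: int, tag: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(tag)
        return 0.0
    return num / den


def binary_metrics(c: ConfusionSummary) -> MetricReport:
    """ACC, Precision, NPV, Recall and F1 from one confusion summary."""
    if c.total == 0:
        raise ValueError("empty confusion summary")
    flags: list[str] = []
    acc = (c.TP + c.TN) / c.total
    precision = _ratio(c.TP, c.TP + c.FP, "precision", flags)
    npv = _ratio(c.TN, c.TN + c.FN, "npv", flags)
    recall = _ratio(c.TP, c.TP + c.FN + c.UP, "recall", flags)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    if precision + recall == 0:
        flags.append("f1")
    return MetricReport(
        values={
            "acc": acc,
            "precision": precision,
            "npv": npv,
            "recall": recall,
            "f1": f1,
        },
        degenerate=flags,
    )


def multiclass_metrics(per_class: list[tuple[str, ConfusionSummary]]) -> MetricReport:
    """Macro-averaged metrics from one-vs-all confusion summaries.

    mACC/mPR/mRecall are unweighted means over the N classes; mF1 is the
    harmonic mean of mPR and mRecall.  Degenerate (0/0) per-class values
    contribute 0 and the class still counts in N.
    """
    if not per_class:
        raise ValueError("need at least one class")
    flags: list[str] = []
    breakdown: dict[str, dict[str, float]] = {}
    accs, prs, recs = [], [], []
    for name, c in per_class:
        rep = binary_metrics(c)
        breakdown[name] = dict(rep.values)
        flags.extend(f"{name}:{tag}" for tag in rep.degenerate)
        accs.append(rep["acc"])
        prs.append(rep["precision"])
        recs.append(rep["recall"])
    n = len(per_class)
    m_acc = sum(accs) / n
    m_pr = sum(prs) / n
    m_rec = sum(recs) / n
    m_f1 = 2 * m_pr * m_rec / (m_pr + m_rec) if (m_pr + m_rec) > 0 else 0.0
    return MetricReport(
        values={"macc": m_acc, "mpr": m_pr, "mrecall": m_rec, "mf1": m_f1},
        per_class=breakdown,
        degenerate=flags,
    )


def chronological_split(
    table: AnnotationTable,
    train_cutoff: _dt.date,
    test_windows: list[tuple[_dt.date, _dt.date]],
) -> tuple[AnnotationTable, list[AnnotationTable], dict]:
    """Date-ordered benchmark construction.

    Training set: records dated on or before ``train_cutoff`` (a record
    dated exactly at the cutoff lands on the train side).  Each test
    window ``(start, end)`` (inclusive) collects records in range whose
    exact sequence string does not occur in the training set — later
    re-depositions of a training sequence are filtered out so test
    records are genuinely unseen.

    Returns (train, [test tables...], filter_log); the log reports how
    many records each window dropped for sequence overlap.
    """
    undated = [r.id for r in table if r.date_added is None]
    if undated:
        raise ValueError(f"records without dates cannot be split: {undated}")
    train = AnnotationTable([r for r in table if r.date_added <= train_cutoff])
    train_seqs = {r.sequence for r in train}
    tests: list[AnnotationTable] = []
    log = {"train_size": len(train), "windows": []}
    for start, end in test_windows:
        in_range = [
            r
            for r in table
            if start <= r.date_added <= end and r.date_added > train_cutoff
        ]
        kept = [r for r in in_range if r.sequence not in train_seqs]
        log["windows"].append(
            {
                "start": start.isoformat(),
                "end": end.isoformat(),
                "candidates": len(in_range),
                "removed_overlap": len(in_range) - len(kept),
                "kept": len(kept),
            }
        )
        tests.append(AnnotationTable(kept))
    return train, tests, log


def filter_novel_labels(
    test: AnnotationTable, train_vocab
) -> tuple[AnnotationTable, AnnotationTable]:
    """Drop test records carrying EC numbers unseen in training.

    A label absent from the training vocabulary cannot be predicted by
    any method trained on it, so such records are excluded from
    evaluation.  A record with a mixture of known and novel ECs is wholly
    excluded (any-novel rule).  Returns (evaluable, excluded).
    """
    vocab = set(train_vocab)
    keep, drop = [], []
    for r in test:
        if any(ec not in vocab for ec in r.ec_numbers):
            drop.append(r)
        else:
            keep.append(r)
    return AnnotationTable(keep), AnnotationTable(drop)


def _truncate_set(ecs, level: int) -> set[ECNumber]:
    return {ec.truncate(level) for ec in ecs}


def evaluate_predictions(
    gold: AnnotationTable,
    predicted: dict,
    task: int,
    level: int = 4,
    k_max: int = 8,
) -> MetricReport:
    """Score predictions against gold labels for one of the three tasks.

    Parameters
    ----------
    gold : AnnotationTable
        Labeled records.
    predicted : dict
        id -> ``None`` (abstained) | ``[]`` (non-enzyme call) |
        list of :class:`ECNumber`.
    task : {1, 2, 3}
        1 = enzyme/non-enzyme (binary); 2 = number of functions
        (multiclass over counts 1..k_max, enzymes only); 3 = EC
        assignment (one-vs-all per EC class, enzymes and non-enzymes).
    level : 1..4
        For task 3 only: both gold and predicted ECs are truncated to
        this depth before comparison, so a depth-4 prediction that
        matches gold in its first three levels is correct at level 3
        even if its fourth level is wrong.

    Abstention semantics: ``None`` is always an abstention.  For tasks 2
    and 3 an empty assignment on a gold enzyme also counts as an
    abstention (the predictor produced no EC call for a record that
    needed one); for task 1 an empty list is a definite non-enzyme call.
    """
    if task not in (1, 2, 3):
        raise ValueError(f"task must be 1, 2 or 3, got {task}")
    if level != 4 and task != 3:
        raise ValueError("level truncation applies to task 3 only")
    missing = [r.id for r in gold if r.id not in predicted]
    if missing:
        raise ValueError(f"missing predictions for ids: {missing}")

    if task == 1:
        tp = fp = tn = fn = up = un = 0
        for r in gold:
            pos = bool(r.is_enzyme)
            pred = predicted[r.id]
            if pred is None:
                up, un = up + pos, un + (not pos)
            elif len(pred) > 0:
                tp, fp = tp + pos, fp + (not pos)
            else:
                fn, tn = fn + pos, tn + (not pos)
        return binary_metrics(ConfusionSummary(TP=tp, FP=fp, TN=tn, FN=fn, UP=up, UN=un))

    if task == 2:
        enzymes = [r for r in gold if r.is_enzyme]
        if not enzymes:
            raise ValueError("task 2 needs at least one gold enzyme")
        gold_counts = {r.id: min(len(r.ec_numbers), k_max) for r in enzymes}
        pred_counts = {}
        for r in enzymes:
            pred = predicted[r.id]
            pred_counts[r.id] = len(pred) if pred else None  # None/[] = no call
        classes = sorted(
            set(gold_counts.values())
            | {c for c in pred_counts.values() if c is not None}
        )
        per_class = []
        for cls in classes:
            tp = fp = tn = fn = up = un = 0
            for r in enzymes:
                pos = gold_counts[r.id] == cls
                pred = pred_counts[r.id]
                if pred is None:
                    up, un = up + pos, un + (not pos)
                elif pred == cls:
                    tp, fp = tp + pos, fp + (not pos)
                else:
                    fn, tn = fn + pos, tn + (not pos)
            per_class.append(
                (str(cls), ConfusionSummary(TP=tp, FP=fp, TN=tn, FN=fn, UP=up, UN=un))
            )
        return multiclass_metrics(per_class)

    # task 3: one-vs-all over EC classes at the requested level
    gold_sets = {r.id: _truncate_set(r.ec_numbers, level) for r in gold}
    pred_sets = {}
    for r in gold:
        pred = predicted[r.id]
        pred_sets[r.id] = None if not pred else _truncate_set(pred, level)
    classes = sorted(
        {ec for s in gold_sets.values() for ec in s}
        | {ec for s in pred_sets.values() if s for ec in s}
    )
    if not classes:
        raise ValueError("no EC classes present in gold or predictions")
    per_class = []
    for cls in classes:
        tp = fp = tn = fn = up = un = 0
        for r in gold:
            pos = cls in gold_sets[r.id]
            pred = pred_sets[r.id]
            if pred is None:
                # no call at all: unclassified, but a definite non-enzyme
                # call on a gold non-enzyme is a clean true negative
                if predicted[r.id] is not None and not r.is_enzyme:
                    tn += 1
                else:
                    up, un = up + pos, un + (not pos)
            elif cls in pred:
                tp, fp = tp + pos, fp + (not pos)
            else:
                fn, tn = fn + pos, tn + (not pos)
        per_class.append(
            (str(cls), ConfusionSummary(TP=tp, FP=fp, TN=tn, FN=fn, UP=up, UN=un))
        )
    return multiclass_metrics(per_class)
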