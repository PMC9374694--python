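"""Confusion-matrix metrics, tenfold cross-validation, holdout evaluation.

The classifier under evaluation is the peptide-mode epitope call (at
least one qualifying ungapped hit to the positive database).  Metrics:

    SE  = 100 * TP / (TP + FN)
    SP  = 100 * TN / (TN + FP)
    ACC = 100 * (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TP+FN)(TN+FP)(TP+FP))

Cross-validation follows the database-resampling design: each round the
search database is built from 90% of the positives and the held-out 10%
of positives plus 10% of negatives are classified against it.  Negatives
never enter the database.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import EpitopeSearchIndex, SearchParams
from .datasets import EpitopeDataset
from .predict import classify_peptide

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVResult",
    "metrics",
    "tenfold_cv",
    "holdout_eval",
    "report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts of a binary evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, accuracy (percent) and MCC."""

    se: float
    sp: float
    acc: float
    mcc: float


def metrics(c: ConfusionCounts) -> MetricSet:
    """Compute SE/SP/ACC/MCC from a confusion table.

    A zero denominator yields NaN for the affected metric, with a
    warning: MCC needs all four marginals positive, SE needs tested
    positives, SP tested negatives.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    if c.total == 0:
        raise ValueError("empty confusion table")

    if tp + fn > 0:
        se = 100.0 * tp / (tp + fn)
    else:
        warnings.warn("no positives tested; SE undefined", stacklevel=2)
        se = float("nan")
    if tn + fp > 0:
        sp = 100.0 * tn / (tn + fp)
    else:
        warnings.warn("no negatives tested; SP undefined", stacklevel=2)
        sp = float("nan")
    acc = 100.0 * (tp + tn) / c.total
    denom = (tn + fn) * (tp + fn) * (tn + fp) * (tp + fp)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        warnings.warn("zero marginal in confusion table; MCC undefined",
                      stacklevel=2)
        mcc = float("nan")
    return MetricSet(se=se, sp=sp, acc=acc, mcc=mcc)


@dataclass
class CVResult:
    """Per-fold and aggregate metrics of a k-fold cross-validation."""

    fold_metrics: list[MetricSet]
    fold_counts: list[ConfusionCounts]
    mean: MetricSet
    std: MetricSet  # population std over folds
    seed: int
    fold_of_positive: dict[str, int]
    fold_of_negative: dict[str, int]
    audit: pd.DataFrame  # per-item verdicts

    @property
    def k(self) -> int:
        return len(self.fold_metrics)


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded uniform shuffle then round-robin slicing into k folds."""
    folds = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for rank, idx in enumerate(perm):
        folds[idx] = rank % k
    return folds


def _aggregate(fold_metrics: list[MetricSet]) -> tuple[MetricSet, MetricSet]:
    arr = np.array([[m.se, m.sp, m.acc, m.mcc] for m in fold_metrics])
    mean = arr.mean(axis=0)
    std = arr.std(axis=0)
    return (
        MetricSet(*(float(x) for x in mean)),
        MetricSet(*(float(x) for x in std)),
    )


def _classify_set(
    ds: EpitopeDataset, index: EpitopeSearchIndex, label: int, fold: int | None
) -> list[dict]:
    rows = []
    for rec in ds:
        pred = classify_peptide(rec.sequence, index, query_id=rec.id)
        best = pred.hits[0] if pred.hits else None
        if pred.hits:
            best = max(pred.hits, key=lambda h: (h.raw_score, h.length))
        rows.append(
            {
                "id": rec.id,
                "label": label,
                "fold": fold,
                "verdict": 1 if pred.verdict == "epitope" else 0,
                "best_hit_subject": best.subject_id if best else "",
                "best_identity": best.identity_pct if best else float("nan"),
                "best_length": best.length if best else 0,
            }
        )
    return rows


def tenfold_cv(
    positives: EpitopeDataset,
    negatives: EpitopeDataset,
    params: SearchParams = SearchParams(),
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """k-fold cross-validation of the hit-based epitope classifier.

    Positives and negatives are independently partitioned (seeded) into k
    near-equal folds.  Round r builds the search database from the
    positives outside fold r and classifies positive fold r (label 1) and
    negative fold r (label 0) against it.  Reported metrics are per-fold
    plus mean and population std across folds.  The positive fold
    assignment depends only on ``seed`` and the positives, so SE is
    unchanged when the negative set is swapped.
    """
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("positives and negatives must be non-empty")
    if k < 2:
        raise ValueError("k must be >= 2")

    folds_pos = _fold_assignment(
        len(positives), k, np.random.default_rng([seed, 0])
    )
    folds_neg = _fold_assignment(
        len(negatives), k, np.random.default_rng([seed, 1])
    )
    for r in range(k):
        if (folds_pos == r).sum() == 0 or (folds_neg == r).sum() == 0:
            raise ValueError(f"fold {r} has no positives or no negatives")

    fold_metrics: list[MetricSet] = []
    fold_counts: list[ConfusionCounts] = []
    audit_rows: list[dict] = []
    for r in range(k):
        train = positives.subset(np.nonzero(folds_pos != r)[0])
        test_pos = positives.subset(np.nonzero(folds_pos == r)[0])
        test_neg = negatives.subset(np.nonzero(folds_neg == r)[0])
        index = EpitopeSearchIndex(train, params)
        rows = _classify_set(test_pos, index, 1, r)
        rows += _classify_set(test_neg, index, 0, r)
        audit_rows.extend(rows)
        tp = sum(1 for x in rows if x["label"] == 1 and x["verdict"] == 1)
        fn = sum(1 for x in rows if x["label"] == 1 and x["verdict"] == 0)
        fp = sum(1 for x in rows if x["label"] == 0 and x["verdict"] == 1)
        tn = sum(1 for x in rows if x["label"] == 0 and x["verdict"] == 0)
        counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        fold_counts.append(counts)
        fold_metrics.append(metrics(counts))

    mean, std = _aggregate(fold_metrics)
    return CVResult(
        fold_metrics=fold_metrics,
        fold_counts=fold_counts,
        mean=mean,
        std=std,
        seed=seed,
        fold_of_positive={
            positives[i].id: int(folds_pos[i]) for i in range(len(positives))
        },
        fold_of_negative={
            negatives[i].id: int(folds_neg[i]) for i in range(len(negatives))
        },
        audit=pd.DataFrame(audit_rows),
    )


def holdout_eval(
    positives: EpitopeDataset,
    negatives: EpitopeDataset,
    db: EpitopeDataset,
    params: SearchParams = SearchParams(),
    return_details: bool = False,
):
    """Evaluate against a fixed database (independent-test design).

    Every positive and negative is classified against ``db``; returns a
    single :class:`MetricSet` (and, optionally, the confusion counts and
    per-item audit table).  Deterministic.
    """
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("positives and negatives must be non-empty")
    index = EpitopeSearchIndex(db, params)
    rows = _classify_set(positives, index, 1, None)
    rows += _classify_set(negatives, index, 0, None)
    tp = sum(1 for x in rows if x["label"] == 1 and x["verdict"] == 1)
    fn = sum(1 for x in rows if x["label"] == 1 and x["verdict"] == 0)
    fp = sum(1 for x in rows if x["label"] == 0 and x["verdict"] == 1)
    tn = sum(1 for x in rows if x["label"] == 0 and x["verdict"] == 0)
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    ms = metrics(counts)
    if return_details:
        return ms, counts, pd.DataFrame(rows)
    return ms


def report(results: "CVResult | MetricSet", format: str = "tsv") -> str:
    """Format CV or holdout metrics as a one-row TSV or markdown table."""
    if isinstance(results, CVResult):
        if not results.fold_metrics:
            raise ValueError("empty results")
        cells = [
            f"{m:.2f} ± {s:.2f}"
            for m, s in zip(
                (results.mean.se, results.mean.sp, results.mean.acc,
                 results.mean.mcc),
                (results.std.se, results.std.sp, results.std.acc,
                 results.std.mcc),
            )
        ]
    elif isinstance(results, MetricSet):
        cells = [
            f"{v:.2f}"
            for v in (results.se, results.sp, results.acc, results.mcc)
        ]
    else:
        raise ValueError("empty results")
    header = ["% SE", "% SP", "% ACC", "MCC"]
    if format == "markdown":
        return (
            "| " + " | ".join(header) + " |\n"
            + "|" + "---|" * len(header) + "\n"
            + "| " + " | ".join(cells) + " |"
        )
    return "\t".join(header) + "\n" + "\t".join(cells)
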