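"""Evaluation of inferred regulators against ground truth.

Predicted causal TFs are compared to a gold set of truly activated TFs
(e.g. candidates with two-fold or more differential expression) via
confusion counts and the Jaccard similarity score TP/(TP+FP+FN); recovery
across a collection of perturbation experiments is summarised as a
prediction rate (fraction of experiments whose perturbed TF was correctly
identified).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import UndefinedScoreError, ValidationError
from .regnet_io import ExpressionProfile


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and Jaccard score of one prediction-vs-gold contrast.

    TFs in ``unprofiled`` were predicted but never measured by the
    expression experiment; they are excluded from the counts entirely
    (neither true nor false positives) since the gold standard cannot speak
    to them.
    """

    tp: int
    fp: int
    fn: int
    jaccard: float
    unprofiled: frozenset[str] = frozenset()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tp": self.tp,
                    "fp": self.fp,
                    "fn": self.fn,
                    "jaccard": self.jaccard,
                    "unprofiled": ",".join(sorted(self.unprofiled)),
                }
            ]
        )


def jaccard_score(tp: int, fp: int, fn: int) -> float:
    """Jaccard similarity of the predicted and gold sets: TP/(TP+FP+FN)."""
    if min(tp, fp, fn) < 0:
        raise ValidationError("confusion counts must be non-negative")
    denom = tp + fp + fn
    if denom == 0:
        raise UndefinedScoreError("Jaccard score undefined for tp=fp=fn=0")
    return tp / denom


def confusion_vs_gold(
    predicted: Iterable[str],
    gold: Iterable[str],
    candidates: Iterable[str],
    unprofiled: Iterable[str] = (),
) -> EvaluationReport:
    """Confusion counts of a predicted TF set against a gold TF set.

    Both sets must lie within the candidate roster. Predicted TFs that were
    not profiled are removed before counting: tp = |predicted ∩ gold|,
    fp = |predicted \\ gold|, fn = |gold \\ predicted|.
    """
    predicted = frozenset(predicted)
    gold = frozenset(gold)
    candidates = frozenset(candidates)
    unprofiled = frozenset(unprofiled)
    for name, subset in (("predicted", predicted), ("gold", gold)):
        stray = sorted(subset - candidates)
        if stray:
            raise ValidationError(
                f"{name} TFs outside the candidate set, e.g. {stray[:5]}"
            )
    kept = predicted - unprofiled
    tp = len(kept & gold)
    fp = len(kept - gold)
    fn = len(gold - kept)
    return EvaluationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        jaccard=jaccard_score(tp, fp, fn),
        unprofiled=unprofiled & predicted,
    )


def gold_from_fold_change(
    profile: ExpressionProfile,
    candidates: Iterable[str],
    fold_threshold: float = 2.0,
    log_scale: bool = False,
) -> tuple[frozenset[str], frozenset[str]]:
    """Gold set of truly activated TFs from their own expression change.

    Candidates with |fold change| >= ``fold_threshold`` form the gold set.
    Fold changes are signed ratios by default (−3.3 means 3.3-fold down);
    pass ``log_scale=True`` for log2 ratios, in which case the threshold is
    applied as |log2 fc| >= log2(fold_threshold). Candidates absent from the
    profile are returned separately as unprofiled.

    Returns ``(gold, unprofiled)``.
    """
    candidates = frozenset(candidates)
    fc = profile.statistic("fold_change")
    profiled = candidates & frozenset(fc.dropna().index)
    unprofiled = candidates - profiled
    if log_scale:
        import math

        cut = math.log2(fold_threshold)
    else:
        cut = fold_threshold
    gold = frozenset(g for g in profiled if abs(fc[g]) >= cut)
    return gold, unprofiled


def prediction_rate(n_correct: int, n_experiments: int) -> float:
    """Fraction of perturbation experiments with a correctly identified TF."""
    if n_experiments <= 0:
        raise UndefinedScoreError("prediction rate undefined without experiments")
    if not 0 <= n_correct <= n_experiments:
        raise ValidationError("n_correct must lie in [0, n_experiments]")
    return n_correct / n_experiments


def percent(rate: float) -> int:
    """A rate as a whole percentage, rounded half-up (0.1439 -> 14)."""
    return int(
        decimal.Decimal(100 * rate).quantize(0, rounding=decimal.ROUND_HALF_UP)
    )


def write_report(report: EvaluationReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> EvaluationReport:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    row = frame.iloc[0]
    unprofiled = frozenset(x for x in str(row["unprofiled"]).split(",") if x)
    return EvaluationReport(
        tp=int(row["tp"]),
        fp=int(row["fp"]),
        fn=int(row["fn"]),
        jaccard=float(row["jaccard"]),
        unprofiled=unprofiled,
    )
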