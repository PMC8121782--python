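"""Classifier-style evaluation of the scoring models on labelled cohorts.

Severe is the positive class: sensitivity is P(predicted severe | truly
severe) and specificity pools mild+moderate as not-severe.  Accuracy is
three-class agreement.  Model 1 predicts the two-class set
{moderate, severe} at total 5; how that ambiguity is resolved is an
explicit policy, never an implicit choice:

pessimistic (default)
    the ambiguous patient is called severe (favours detection);
optimistic
    called moderate (favours avoiding over-treatment);
exclude
    dropped from the evaluated set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ThalscoreError
from .genotype_io import SEVERITY_ORDER, Cohort, Severity
from .risk_score import RiskScoreResult, ScoringModel, ScoringSystem, score_cohort

POLICIES = ("pessimistic", "optimistic", "exclude")

_LABELS = [s.label for s in SEVERITY_ORDER]


def resolve_ambiguous(
    prediction: frozenset[Severity] | set[Severity], policy: str = "pessimistic"
) -> Severity | None:
    """Collapse a prediction set to one class (or ``None`` = excluded)."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if not prediction:
        raise ThalscoreError("empty prediction set")
    if len(prediction) == 1:
        return next(iter(prediction))
    if policy == "pessimistic":
        return max(prediction)
    if policy == "optimistic":
        return min(prediction)
    return None


@dataclass(frozen=True)
class EvaluationResult:
    """Metrics for one model on one cohort after ambiguity resolution.

    ``confusion`` is a 3x3 DataFrame, rows = true class, columns =
    predicted class, counting evaluated patients only.  A metric whose
    denominator is empty (a true class absent from the cohort) is NaN,
    not zero.
    """

    model_name: str
    cohort_name: str
    policy: str
    confusion: pd.DataFrame
    sensitivity: float
    specificity: float
    accuracy: float
    n_evaluated: int
    n_excluded_ambiguous: int
    n_excluded_missing: int

    def as_row(self) -> dict[str, object]:
        return {
            "model": self.model_name,
            "cohort": self.cohort_name,
            "policy": self.policy,
            "n": self.n_evaluated,
            "sensitivity_pct": round(100 * self.sensitivity, 1),
            "specificity_pct": round(100 * self.specificity, 1),
            "accuracy_pct": round(100 * self.accuracy, 1),
        }


def confusion_matrix(
    pairs: Sequence[tuple[Severity, Severity]]
) -> pd.DataFrame:
    """Tally (true, predicted) pairs into a 3x3 count matrix."""
    counts = np.zeros((3, 3), dtype=int)
    for truth, pred in pairs:
        counts[int(truth), int(pred)] += 1
    return pd.DataFrame(counts, index=_LABELS, columns=_LABELS)


def metrics_from_confusion(confusion: pd.DataFrame) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with severe one-vs-rest."""
    m = confusion.to_numpy()
    sev = int(Severity.SEVERE)
    n = m.sum()
    n_severe = m[sev, :].sum()
    n_not_severe = n - n_severe
    sensitivity = m[sev, sev] / n_severe if n_severe else math.nan
    tn = m[:sev, :].sum() - m[:sev, sev].sum()  # not-severe predicted not-severe
    specificity = tn / n_not_severe if n_not_severe else math.nan
    accuracy = np.trace(m) / n if n else math.nan
    return float(sensitivity), float(specificity), float(accuracy)


def evaluate_model(
    scored: Sequence[RiskScoreResult],
    cohort: Cohort,
    model: ScoringModel,
    policy: str = "pessimistic",
    lenient_accuracy: bool = False,
    n_excluded_missing: int = 0,
) -> EvaluationResult:
    """Evaluate one scoring model against the cohort's true labels.

    ``scored`` are the complete-genotype patients (from
    :func:`thalscore.risk_score.score_cohort`); ``n_excluded_missing``
    carries the count dropped there for bookkeeping.  With
    ``lenient_accuracy`` a patient is counted correct when the true class
    lies anywhere in the (unresolved) prediction set; sensitivity and
    specificity still use the resolved class.
    """
    truth = {p.patient_id: p.severity for p in cohort}
    pairs: list[tuple[Severity, Severity]] = []
    n_ambiguous_excluded = 0
    n_lenient_correct = 0
    for r in scored:
        pred_set = r.predictions.get(model.name) or model.predict(r.total)
        if truth[r.patient_id] in pred_set:
            n_lenient_correct += 1
        resolved = resolve_ambiguous(pred_set, policy)
        if resolved is None:
            n_ambiguous_excluded += 1
            continue
        pairs.append((truth[r.patient_id], resolved))
    confusion = confusion_matrix(pairs)
    sensitivity, specificity, accuracy = metrics_from_confusion(confusion)
    if lenient_accuracy:
        accuracy = n_lenient_correct / len(scored) if scored else math.nan
    return EvaluationResult(
        model_name=model.name,
        cohort_name=cohort.name,
        policy=policy,
        confusion=confusion,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        n_evaluated=len(pairs),
        n_excluded_ambiguous=n_ambiguous_excluded,
        n_excluded_missing=n_excluded_missing,
    )


def evaluate_all(
    cohorts: Mapping[str, Cohort] | Sequence[Cohort],
    system: ScoringSystem,
    policy: str = "pessimistic",
    lenient_accuracy: bool = False,
) -> list[EvaluationResult]:
    """One EvaluationResult per model x cohort."""
    if isinstance(cohorts, Mapping):
        named = list(cohorts.values())
        for name, c in cohorts.items():
            c.name = name
    else:
        named = list(cohorts)
    results = []
    for cohort in named:
        scored, excluded = score_cohort(cohort, system)
        for model in system.models:
            results.append(
                evaluate_model(
                    scored,
                    cohort,
                    model,
                    policy=policy,
                    lenient_accuracy=lenient_accuracy,
                    n_excluded_missing=len(excluded),
                )
            )
    return results


def results_frame(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Flatten evaluation results into the canonical output table."""
    return pd.DataFrame([r.as_row() for r in results])
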