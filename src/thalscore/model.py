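"""Model/Results interface over the functional layer.

Two fit-style entry points, in the spirit of statsmodels:

``SeverityAssociation``
    built from a genotype-frequency table (or tabulated from a cohort);
    ``fit()`` runs the per-genotype odds-ratio scan and returns
    :class:`AssociationResults` with estimates, Woolf intervals, exact
    p-values, a ``summary()`` table and a data-driven comparison against
    a published reference table.

``RiskScoreAnalysis``
    built from a labelled cohort and a scoring system; ``fit()`` scores
    every complete-genotype patient, applies each interpretation model and
    returns :class:`RiskScoreResults` with per-patient scores, confusion
    matrices and sensitivity/specificity/accuracy.  Simulation hangs off
    the model class via :meth:`RiskScoreAnalysis.from_simulation`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .association import OrResult, risk_genotype_scan, scan_to_frame
from .evaluation import (
    EvaluationResult,
    evaluate_model,
    results_frame,
)
from .genotype_io import (
    Cohort,
    GenotypeFrequencyTable,
    read_frequency_table,
)
from .risk_score import (
    ExcludedPatient,
    RiskScoreResult,
    ScoringSystem,
    default_scoring_system,
    score_cohort,
)
from .synthetic_cohort import SimulationConfig, simulate_cohort

REFERENCE_RESOURCE = "cohort1_reference_odds_ratios.csv"
FREQUENCY_RESOURCE = "cohort1_genotype_frequencies.csv"

#: printed reference values are 2 d.p.; CI bounds in the source are
#: truncated rather than rounded, so "agrees at 2 d.p." means within one
#: unit in the last place.
TWO_DP_TOL = 0.01


def load_reference_frequencies() -> GenotypeFrequencyTable:
    """The packaged discovery-cohort genotype-frequency table."""
    ref = resources.files("thalscore.data").joinpath(FREQUENCY_RESOURCE)
    with resources.as_file(ref) as path:
        return read_frequency_table(path)


def load_reference_odds_ratios() -> pd.DataFrame:
    """The packaged published OR/CI/p reference table (27 rows)."""
    ref = resources.files("thalscore.data").joinpath(REFERENCE_RESOURCE)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


class SeverityAssociation:
    """Per-genotype odds-ratio model over severity groups."""

    def __init__(self, frequency_table: GenotypeFrequencyTable):
        self.frequency_table = frequency_table

    @classmethod
    def from_csv(cls, path: str | Path) -> "SeverityAssociation":
        return cls(read_frequency_table(path))

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, system: ScoringSystem | None = None
    ) -> "SeverityAssociation":
        if system is None:
            system = default_scoring_system()
        return cls(GenotypeFrequencyTable.from_cohort(cohort, system.snps))

    @classmethod
    def reference(cls) -> "SeverityAssociation":
        """Model over the packaged discovery-cohort table."""
        return cls(load_reference_frequencies())

    def fit(self, alpha: float = 0.05) -> "AssociationResults":
        results = risk_genotype_scan(self.frequency_table, alpha=alpha)
        return AssociationResults(model=self, results=results, alpha=alpha)


@dataclass
class AssociationResults:
    model: SeverityAssociation
    results: list[OrResult]
    alpha: float

    @property
    def table(self) -> pd.DataFrame:
        return scan_to_frame(self.results)

    def compare_reference(self, reference: pd.DataFrame | None = None) -> pd.DataFrame:
        """Side-by-side comparison with a published reference table.

        Adds ``or_match``/``ci_match`` flags (2 d.p. agreement; CI bounds
        within one printed unit) and the ratio of the computed exact
        p-value to the reference p-value.  P-values get no match flag: the
        source's test procedure is unnamed, so they are verification
        references, not reproduction targets.
        """
        if reference is None:
            reference = load_reference_odds_ratios()
        merged = self.table.merge(
            reference,
            on=["snp_id", "genotype", "comparison"],
            how="inner",
            suffixes=("", "_ref"),
        )
        if len(merged) != len(reference):
            raise ValueError(
                "reference rows not matched by the scan; check SNP/genotype labels"
            )
        merged["or_match"] = (merged["or"].round(2) - merged["or_ref"]).abs() < 1e-9
        merged["ci_match"] = (
            (merged["ci_low"] - merged["ci_low_ref"]).abs() < TWO_DP_TOL + 1e-12
        ) & ((merged["ci_high"] - merged["ci_high_ref"]).abs() < TWO_DP_TOL + 1e-12)
        merged["p_ratio"] = merged["p"] / merged["p_ref"]
        return merged

    def summary(self) -> str:
        frame = self.table.copy()
        for col in ("or", "ci_low", "ci_high"):
            frame[col] = frame[col].map("{:.2f}".format)
        frame["p"] = frame["p"].map("{:.3g}".format)
        level = int(round(100 * (1 - self.alpha)))
        header = (
            f"Per-genotype odds ratios (genotype vs. rest), Woolf {level}% CI, "
            "two-sided Fisher exact p\n"
        )
        return header + frame.to_string(index=False)


class RiskScoreAnalysis:
    """Three-SNP risk scoring and model evaluation on one cohort."""

    def __init__(
        self,
        cohort: Cohort,
        system: ScoringSystem | None = None,
    ):
        self.cohort = cohort
        self.system = system if system is not None else default_scoring_system()

    @classmethod
    def from_simulation(
        cls,
        config: SimulationConfig,
        system: ScoringSystem | None = None,
    ) -> "RiskScoreAnalysis":
        system = system if system is not None else default_scoring_system()
        return cls(simulate_cohort(config, system), system)

    def fit(
        self, policy: str = "pessimistic", lenient_accuracy: bool = False
    ) -> "RiskScoreResults":
        scored, excluded = score_cohort(self.cohort, self.system)
        evaluations = [
            evaluate_model(
                scored,
                self.cohort,
                model,
                policy=policy,
                lenient_accuracy=lenient_accuracy,
                n_excluded_missing=len(excluded),
            )
            for model in self.system.models
        ]
        return RiskScoreResults(
            analysis=self,
            scored=scored,
            excluded=excluded,
            evaluations=evaluations,
            policy=policy,
        )


@dataclass
class RiskScoreResults:
    analysis: RiskScoreAnalysis
    scored: list[RiskScoreResult]
    excluded: list[ExcludedPatient]
    evaluations: list[EvaluationResult]
    policy: str

    @property
    def scores(self) -> pd.DataFrame:
        """Per-patient score table with one prediction column per model."""
        system = self.analysis.system
        rows = []
        for r in self.scored:
            row: dict[str, object] = {"patient_id": r.patient_id}
            for snp_id in system.snp_ids:
                row[f"score_{snp_id}"] = r.per_snp_scores[snp_id]
            row["total"] = r.total
            for m in system.models:
                row[m.name] = "|".join(
                    s.label for s in sorted(r.predictions[m.name])
                )
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def metrics(self) -> pd.DataFrame:
        return results_frame(self.evaluations)

    def confusion(self, model_name: str) -> pd.DataFrame:
        for ev in self.evaluations:
            if ev.model_name == model_name:
                return ev.confusion
        raise KeyError(model_name)

    def summary(self) -> str:
        lines = [
            f"Cohort {self.analysis.cohort.name}: {len(self.scored)} patients "
            f"scored, {len(self.excluded)} excluded (missing genotypes); "
            f"policy={self.policy}",
            "",
            self.metrics.to_string(index=False),
        ]
        return "\n".join(lines)
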