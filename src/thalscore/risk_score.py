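"""Three-SNP severity risk score and its interpretation models.

Each predictive SNP contributes a per-genotype score of 0, 1 or 2 (low to
high risk of severe disease); the total over the three SNPs runs 0-6.
Three interpretation models bin the total into predicted severity classes.
They differ only in where total 5 goes: model 1 predicts {moderate, severe}
(the bins deliberately overlap), model 2 predicts severe, model 3 predicts
moderate.  The system is config-driven so other SNP panels can reuse the
engine; the packaged YAML is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError, ScoreRangeError, UndefinedScoreError
from .genotype_io import (
    SEVERITY_ORDER,
    Cohort,
    Severity,
    SnpDefinition,
    normalize_genotype,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG_RESOURCE = "scoring_system.yaml"


@dataclass(frozen=True)
class ScoringModel:
    """Maps each total score to a non-empty, contiguous set of classes.

    Bins must cover every total, and both the minimal and maximal class of
    the predicted set must be non-decreasing in the score.
    """

    name: str
    bins: Mapping[int, frozenset[Severity]]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ConfigError(f"{self.name}: no score bins defined")
        totals = sorted(self.bins)
        if totals != list(range(totals[0], totals[-1] + 1)) or totals[0] != 0:
            raise ConfigError(f"{self.name}: bins must cover 0..max contiguously")
        prev_min = prev_max = Severity.MILD
        for t in totals:
            classes = self.bins[t]
            if not classes:
                raise ConfigError(f"{self.name}: empty prediction at total {t}")
            lo, hi = min(classes), max(classes)
            if set(classes) != {s for s in SEVERITY_ORDER if lo <= s <= hi}:
                raise ConfigError(
                    f"{self.name}: prediction at total {t} is not contiguous"
                )
            if lo < prev_min or hi < prev_max:
                raise ConfigError(f"{self.name}: bins not monotone at total {t}")
            prev_min, prev_max = lo, hi
        object.__setattr__(self, "bins", dict(self.bins))

    @property
    def max_score(self) -> int:
        return max(self.bins)

    def predict(self, total: int) -> frozenset[Severity]:
        try:
            return frozenset(self.bins[total])
        except KeyError:
            raise ScoreRangeError(
                f"{self.name}: total {total} outside 0..{self.max_score}"
            ) from None

    @classmethod
    def from_ranges(
        cls, name: str, ranges: Mapping[str | Severity, Sequence[int]]
    ) -> "ScoringModel":
        """Build from per-class inclusive (low, high) total-score ranges.

        Overlapping ranges produce multi-class predictions, which is how
        model 1's shared total of 5 is represented.
        """
        bins: dict[int, set[Severity]] = {}
        for cls_label, (lo, hi) in ranges.items():
            sev = cls_label if isinstance(cls_label, Severity) else Severity.parse(cls_label)
            for t in range(int(lo), int(hi) + 1):
                bins.setdefault(t, set()).add(sev)
        return cls(name=name, bins={t: frozenset(s) for t, s in bins.items()})


@dataclass(frozen=True)
class ScoringSystem:
    """A SNP panel with score maps plus the interpretation models."""

    snps: tuple[SnpDefinition, ...]
    models: tuple[ScoringModel, ...]

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(snp.snp_id for snp in self.snps)

    @property
    def max_score(self) -> int:
        return 2 * len(self.snps)

    def snp(self, snp_id: str) -> SnpDefinition:
        for snp in self.snps:
            if snp.snp_id == snp_id:
                return snp
        raise KeyError(snp_id)

    def model(self, name: str) -> ScoringModel:
        for m in self.models:
            if m.name == name:
                return m
        raise KeyError(name)


def load_scoring_system(path: str | Path) -> ScoringSystem:
    """Load a scoring-system YAML (SNP panel + model bins)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return _system_from_payload(payload, source=str(path))


def default_scoring_system() -> ScoringSystem:
    """The packaged three-SNP system (BCL11A / HBS1L-MYB / HBE1)."""
    ref = resources.files("thalscore.data").joinpath(DEFAULT_CONFIG_RESOURCE)
    payload = yaml.safe_load(ref.read_text())
    return _system_from_payload(payload, source=DEFAULT_CONFIG_RESOURCE)


def _system_from_payload(payload: object, source: str) -> ScoringSystem:
    if not isinstance(payload, dict) or "snps" not in payload or "models" not in payload:
        raise ConfigError(f"{source}: expected mapping with 'snps' and 'models'")
    try:
        snps = tuple(
            SnpDefinition(
                snp_id=entry["snp_id"],
                gene=entry.get("gene", ""),
                chromosome=str(entry.get("chromosome", "")),
                position=int(entry.get("position", 1)),
                alleles=tuple(entry["alleles"]),
                score_map=dict(entry["scores"]),
            )
            for entry in payload["snps"]
        )
        models = tuple(
            ScoringModel.from_ranges(name, ranges)
            for name, ranges in payload["models"].items()
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{source}: malformed scoring config ({exc})") from None
    max_total = 2 * len(snps)
    for m in models:
        if m.max_score != max_total:
            raise ConfigError(
                f"{source}: model {m.name} covers 0..{m.max_score}, "
                f"panel needs 0..{max_total}"
            )
    return ScoringSystem(snps=snps, models=models)


def score_genotype(snp: SnpDefinition, genotype: str | None) -> int:
    """Per-SNP risk score; a missing genotype leaves the score undefined."""
    if genotype is None:
        raise UndefinedScoreError(f"{snp.snp_id}: genotype missing")
    if genotype not in snp.score_map:
        genotype = normalize_genotype(genotype, snp)
    return snp.score_map[genotype]


def total_score(
    genotypes: Mapping[str, str | None], snps: Sequence[SnpDefinition]
) -> int:
    """Sum of per-SNP scores over the panel; undefined if any SNP missing."""
    return sum(score_genotype(snp, genotypes.get(snp.snp_id)) for snp in snps)


@dataclass(frozen=True)
class RiskScoreResult:
    patient_id: str
    per_snp_scores: Mapping[str, int]
    total: int
    predictions: Mapping[str, frozenset[Severity]] = field(default_factory=dict)


@dataclass(frozen=True)
class ExcludedPatient:
    patient_id: str
    reason: str


def score_cohort(
    cohort: Cohort,
    system: ScoringSystem,
    models: Sequence[ScoringModel] | None = None,
) -> tuple[list[RiskScoreResult], list[ExcludedPatient]]:
    """Score every patient with complete genotypes; report exclusions.

    Patients missing any predictive SNP have no defined total and are
    returned in the exclusion list with the offending SNPs named.
    """
    if models is None:
        models = system.models
    results: list[RiskScoreResult] = []
    excluded: list[ExcludedPatient] = []
    for p in cohort:
        missing = [s.snp_id for s in system.snps if p.genotypes.get(s.snp_id) is None]
        if missing:
            excluded.append(
                ExcludedPatient(p.patient_id, f"missing genotype at {','.join(missing)}")
            )
            continue
        per_snp = {
            snp.snp_id: score_genotype(snp, p.genotypes[snp.snp_id])
            for snp in system.snps
        }
        total = sum(per_snp.values())
        results.append(
            RiskScoreResult(
                patient_id=p.patient_id,
                per_snp_scores=per_snp,
                total=total,
                predictions={m.name: m.predict(total) for m in models},
            )
        )
    logger.info(
        "scored %d/%d patients (%d excluded for missing genotypes)",
        len(results), len(cohort), len(excluded),
    )
    if not results:
        logger.warning("no scorable patients in cohort %r", cohort.name)
    return results, excluded
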