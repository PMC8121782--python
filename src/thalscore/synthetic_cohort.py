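"""Synthetic cohorts with the statistical structure the analysis assumes.

No individual-level data accompany the published severity analysis, only
per-group genotype percentages.  This generator draws patients group by
group from those multinomial marginals, so every pipeline stage is
exercisable end to end.  Across SNPs the default joint structure is
independence (the joint distribution is unpublished); a Gaussian-copula
mode induces LD-like rank dependence between the per-SNP risk scores while
preserving the marginals, for robustness checks.  Under independence the
classification metrics also have a closed form — an exact enumeration over
the 27 genotype combinations per group — used as the oracle for the
Monte-Carlo pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

from .errors import ConfigError
from .evaluation import resolve_ambiguous
from .genotype_io import (
    SEVERITY_ORDER,
    Cohort,
    GenotypeFrequencyTable,
    Patient,
    Severity,
)
from .risk_score import ScoringModel, ScoringSystem, default_scoring_system


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the discovery-cohort design: group sizes come from the
    frequency table (180/181/307 for the packaged table), no missingness,
    independent SNPs.
    """

    frequency_table: GenotypeFrequencyTable
    group_sizes: dict[Severity, int] | None = None
    seed: int = 0
    missing_rate: float = 0.0
    joint_mode: str = "independent"
    copula_correlation: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.joint_mode not in ("independent", "copula"):
            raise ConfigError(f"unknown joint_mode {self.joint_mode!r}")
        if not -1.0 < self.copula_correlation < 1.0:
            raise ConfigError("copula_correlation must lie in (-1, 1)")
        if self.group_sizes is None:
            self.group_sizes = dict(self.frequency_table.group_sizes)
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be positive")

    def resolved_groups(self) -> list[tuple[Severity, int]]:
        assert self.group_sizes is not None
        return [(g, self.group_sizes[g]) for g in SEVERITY_ORDER if g in self.group_sizes]


def _group_probabilities(
    table: GenotypeFrequencyTable, snp_id: str, group: Severity
) -> tuple[list[str], np.ndarray]:
    pct = table.percentages(snp_id, group)
    genotypes = list(pct)
    p = np.asarray([pct[g] for g in genotypes], dtype=float)
    if np.any(p < 0):
        raise ConfigError(f"{snp_id}/{group.label}: negative frequency")
    total = p.sum()
    if not np.isclose(total, 100.0, atol=GenotypeFrequencyTable.SUM_TOL):
        raise ConfigError(
            f"{snp_id}/{group.label}: frequencies sum to {total:.2f}, not 100"
        )
    return genotypes, p / total


def _score_ordered(
    genotypes: list[str], p: np.ndarray, snp_score: dict[str, int]
) -> tuple[list[str], np.ndarray]:
    order = sorted(range(len(genotypes)), key=lambda i: snp_score[genotypes[i]])
    return [genotypes[i] for i in order], p[order]


def simulate_cohort(
    config: SimulationConfig, system: ScoringSystem | None = None
) -> Cohort:
    """Draw a labelled cohort from per-group multinomial genotype marginals.

    Independent mode draws each SNP separately.  Copula mode draws one
    latent Gaussian vector per patient with common pairwise correlation,
    maps each coordinate through its marginal inverse CDF with genotypes
    ordered by risk score, so positive correlation concentrates jointly
    high-risk (and jointly low-risk) profiles without changing marginals.
    Missingness is applied uniformly at random per (patient, SNP).  The
    draw is fully determined by ``config.seed``.
    """
    if system is None:
        system = default_scoring_system()
    table = config.frequency_table
    rng = np.random.default_rng(config.seed)
    snp_ids = [s for s in table.snp_ids if s in set(system.snp_ids)] or list(
        table.snp_ids
    )
    patients: list[Patient] = []
    for group, n in config.resolved_groups():
        columns: dict[str, np.ndarray] = {}
        if config.joint_mode == "independent":
            for snp_id in snp_ids:
                genotypes, p = _group_probabilities(table, snp_id, group)
                idx = rng.choice(len(genotypes), size=n, p=p)
                columns[snp_id] = np.asarray(genotypes, dtype=object)[idx]
        else:
            k = len(snp_ids)
            cov = np.full((k, k), config.copula_correlation)
            np.fill_diagonal(cov, 1.0)
            z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
            u = stats.norm.cdf(z)
            for j, snp_id in enumerate(snp_ids):
                genotypes, p = _group_probabilities(table, snp_id, group)
                genotypes, p = _score_ordered(
                    genotypes, p, dict(system.snp(snp_id).score_map)
                )
                edges = np.cumsum(p)
                idx = np.searchsorted(edges, u[:, j], side="right")
                idx = np.clip(idx, 0, len(genotypes) - 1)
                columns[snp_id] = np.asarray(genotypes, dtype=object)[idx]
        if config.missing_rate > 0:
            for snp_id in snp_ids:
                mask = rng.random(n) < config.missing_rate
                col = columns[snp_id].copy()
                col[mask] = None
                columns[snp_id] = col
        for i in range(n):
            patients.append(
                Patient(
                    patient_id=f"{group.label}-{i + 1:05d}",
                    genotypes={s: columns[s][i] for s in snp_ids},
                    severity=group,
                )
            )
    return Cohort(patients=patients, name=f"simulated-seed{config.seed}")


@dataclass(frozen=True)
class ExpectedMetrics:
    """Exact classification metrics under the independence model."""

    sensitivity: float
    specificity: float
    accuracy: float


def expected_metrics(
    config: SimulationConfig,
    model: ScoringModel,
    policy: str = "pessimistic",
    system: ScoringSystem | None = None,
) -> ExpectedMetrics:
    """Closed-form metrics by enumerating genotype combinations per group.

    Each of the 3^k genotype combinations has probability equal to the
    product of its marginal genotype probabilities (independence); the
    combination maps to a total score, a predicted set and a resolved
    class.  Group probability masses are weighted by the configured group
    sizes.  Under the exclude policy, metrics condition on the evaluated
    (non-excluded) mass.
    """
    if config.joint_mode != "independent":
        raise ConfigError("expected_metrics requires joint_mode='independent'")
    if system is None:
        system = default_scoring_system()
    table = config.frequency_table
    snp_ids = [s for s in table.snp_ids if s in set(system.snp_ids)] or list(
        table.snp_ids
    )
    groups = config.resolved_groups()
    n_total = sum(n for _, n in groups)

    # joint mass over (true class, resolved predicted class | not excluded)
    mass = np.zeros((3, 3))
    excluded_mass = 0.0
    for group, n in groups:
        weight = n / n_total
        marginals = []
        for snp_id in snp_ids:
            genotypes, p = _group_probabilities(table, snp_id, group)
            score_map = dict(system.snp(snp_id).score_map)
            marginals.append([(score_map[g], p[i]) for i, g in enumerate(genotypes)])
        for combo in product(*marginals):
            prob = float(np.prod([pr for _, pr in combo]))
            total = sum(sc for sc, _ in combo)
            resolved = resolve_ambiguous(model.predict(total), policy)
            if resolved is None:
                excluded_mass += weight * prob
                continue
            mass[int(group), int(resolved)] += weight * prob

    evaluated = mass.sum()
    sev = int(Severity.SEVERE)
    p_true_severe = mass[sev, :].sum()
    p_true_not = evaluated - p_true_severe
    sensitivity = mass[sev, sev] / p_true_severe if p_true_severe > 0 else float("nan")
    tn = mass[:sev, :].sum() - mass[:sev, sev].sum()
    specificity = tn / p_true_not if p_true_not > 0 else float("nan")
    accuracy = np.trace(mass) / evaluated if evaluated > 0 else float("nan")
    return ExpectedMetrics(
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        accuracy=float(accuracy),
    )
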