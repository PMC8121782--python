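"""Risk-genotype association: per-genotype odds ratios between severity groups.

For each SNP, each diploid genotype is contrasted against the other two
genotypes pooled (genotype vs. rest) in a 2x2 table between two severity
groups.  Effect size is the odds ratio with a Woolf (log-normal) confidence
interval; significance is the two-sided Fisher exact test.  The scan over
3 SNPs x 3 genotypes x 3 ordered group comparisons yields 27 results.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log, sqrt
from typing import Sequence

import pandas as pd
from scipy import stats

from .genotype_io import (
    GenotypeFrequencyTable,
    Severity,
    counts_from_frequencies,
)

#: Ordered pairwise comparisons, first-named group in the numerator.
DEFAULT_COMPARISONS: tuple[tuple[Severity, Severity], ...] = (
    (Severity.MILD, Severity.MODERATE),
    (Severity.MILD, Severity.SEVERE),
    (Severity.MODERATE, Severity.SEVERE),
)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (a, b) = carriers/non-carriers in group A; (c, d) in B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def has_zero(self) -> bool:
        return 0 in self.cells

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe correction: +0.5 per cell iff any cell is zero."""
        if self.has_zero:
            return tuple(x + 0.5 for x in self.cells)  # type: ignore[return-value]
        return self.cells

    def swapped(self) -> "ContingencyTable":
        """The table with groups A and B exchanged."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


def odds_ratio(t: ContingencyTable) -> float:
    """Odds ratio ad/bc; group A odds over group B odds.

    When any raw cell is zero the Haldane-Anscombe corrected counts are
    used, so the result is always finite and positive.
    """
    a, b, c, d = t.corrected()
    return (a * d) / (b * c)


def woolf_ci(t: ContingencyTable, alpha: float = 0.05) -> tuple[float, float]:
    """Woolf confidence interval for the odds ratio at level 1 - alpha.

    Normal approximation on the log scale with
    SE = sqrt(1/a + 1/b + 1/c + 1/d), on corrected counts if any raw cell
    is zero.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    a, b, c, d = t.corrected()
    log_or = log((a * d) / (b * c))
    se = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return exp(log_or - z * se), exp(log_or + z * se)


def exact_p(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value on the raw counts.

    Sums hypergeometric probabilities (margins fixed) of every table at
    most as probable as the observed one; never exceeds 1.
    """
    p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]]).pvalue
    return min(float(p), 1.0)


@dataclass(frozen=True)
class OrResult:
    """One genotype-vs-rest comparison between two severity groups."""

    snp_id: str
    genotype: str
    comparison: tuple[Severity, Severity]
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def comparison_label(self) -> str:
        a, b = self.comparison
        return f"{a.label}_vs_{b.label}"


def genotype_vs_rest_table(
    table: GenotypeFrequencyTable,
    snp_id: str,
    genotype: str,
    group_a: Severity,
    group_b: Severity,
) -> ContingencyTable:
    """Build the 2x2 carrier/non-carrier table from reconstructed counts."""
    counts_a = counts_from_frequencies(table, snp_id, group_a)
    counts_b = counts_from_frequencies(table, snp_id, group_b)
    a = counts_a[genotype]
    c = counts_b[genotype]
    return ContingencyTable(
        a=a,
        b=sum(counts_a.values()) - a,
        c=c,
        d=sum(counts_b.values()) - c,
    )


def risk_genotype_scan(
    table: GenotypeFrequencyTable,
    alpha: float = 0.05,
    comparisons: Sequence[tuple[Severity, Severity]] | None = None,
) -> list[OrResult]:
    """Full per-genotype odds-ratio scan over all SNPs and group pairs."""
    if comparisons is None:
        present = set(table.groups)
        comparisons = [
            (a, b) for a, b in DEFAULT_COMPARISONS if a in present and b in present
        ]
    if not comparisons:
        raise ValueError("need at least two severity groups to compare")
    results = []
    for snp_id in table.snp_ids:
        for genotype in table.genotypes(snp_id):
            for group_a, group_b in comparisons:
                t = genotype_vs_rest_table(table, snp_id, genotype, group_a, group_b)
                lo, hi = woolf_ci(t, alpha)
                results.append(
                    OrResult(
                        snp_id=snp_id,
                        genotype=genotype,
                        comparison=(group_a, group_b),
                        table=t,
                        odds_ratio=odds_ratio(t),
                        ci_low=lo,
                        ci_high=hi,
                        p_value=exact_p(t),
                    )
                )
    return results


def scan_to_frame(results: Sequence[OrResult]) -> pd.DataFrame:
    """Flatten scan results into the canonical output table."""
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "snp_id": r.snp_id,
                "genotype": r.genotype,
                "comparison": r.comparison_label,
                "n_a": t.a + t.b,
                "n_b": t.c + t.d,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "or": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_value,
            }
        )
    return pd.DataFrame(rows)
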