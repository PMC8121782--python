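"""Domain types and file I/O for genotype data.

The analysis operates on three kinds of tabular input: per-severity-group
genotype-frequency tables (percentages plus group sizes), individual-level
cohorts (patient x SNP diploid genotypes with a clinical severity label,
as CSV or minimal VCF), and biallelic SNP definitions with their
genotype-to-score maps.  This module defines the containers and the
readers/writers; the arithmetic that turns published percentages back into
integer counts (and counts into allele frequencies) also lives here because
every downstream stage depends on it.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import (
    CohortError,
    FormatError,
    InvalidGenotypeError,
    TableValidationError,
    UndefinedFrequencyError,
)

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", ".", "./.", ".|.", "NA", "NN"}


class Severity(enum.IntEnum):
    """Clinical severity class, totally ordered mild < moderate < severe.

    Labels are assigned upstream by a clinical instrument and consumed
    here as given.
    """

    MILD = 0
    MODERATE = 1
    SEVERE = 2

    @classmethod
    def parse(cls, label: str) -> "Severity":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise CohortError(
                f"unknown severity label {label!r}; expected one of "
                f"{[s.label for s in cls]}"
            ) from None

    @property
    def label(self) -> str:
        return self.name.lower()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


SEVERITY_ORDER: tuple[Severity, ...] = (
    Severity.MILD,
    Severity.MODERATE,
    Severity.SEVERE,
)


@dataclass(frozen=True)
class SnpDefinition:
    """A biallelic SNP with its per-genotype risk scores.

    ``alleles`` is an ordered pair; the three canonical genotypes are
    hom-first, het (first allele printed first), hom-second.  ``score_map``
    assigns each genotype a distinct score in {0, 1, 2}, low to high risk
    of severe disease.
    """

    snp_id: str
    gene: str
    chromosome: str
    position: int
    alleles: tuple[str, str]
    score_map: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive")
        a1, a2 = self.alleles
        if a1 == a2:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if self.score_map:
            if set(self.score_map) != set(self.genotypes):
                raise ValueError(
                    f"{self.snp_id}: score map keys {sorted(self.score_map)} "
                    f"do not match genotypes {list(self.genotypes)}"
                )
            if sorted(self.score_map.values()) != [0, 1, 2]:
                raise ValueError(
                    f"{self.snp_id}: scores must cover 0,1,2 exactly once"
                )

    @property
    def genotypes(self) -> tuple[str, str, str]:
        a1, a2 = self.alleles
        return (a1 + a1, a1 + a2, a2 + a2)


@dataclass(frozen=True)
class Patient:
    """One individual: id, per-SNP genotype (``None`` = missing), label."""

    patient_id: str
    genotypes: Mapping[str, str | None]
    severity: Severity


@dataclass
class Cohort:
    """An individual-level cohort with true severity labels."""

    patients: list[Patient]
    name: str = "cohort"

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[Patient]:
        return iter(self.patients)

    def group_sizes(self) -> dict[Severity, int]:
        sizes = {s: 0 for s in SEVERITY_ORDER}
        for p in self.patients:
            sizes[p.severity] += 1
        return sizes

    def to_dataframe(self, snp_ids: Sequence[str]) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.patient_id,
                **{s: (p.genotypes.get(s) or "") for s in snp_ids},
                "severity": p.severity.label,
            }
            for p in self.patients
        ]
        return pd.DataFrame(rows, columns=["patient_id", *snp_ids, "severity"])


def normalize_genotype(raw: str, snp: SnpDefinition) -> str:
    """Return the canonical diploid genotype for ``raw`` at ``snp``.

    Accepts the two allele characters in any order and case, optionally
    separated by "/" or "|"; the canonical form orders alleles as declared
    in the SNP definition (the het is always first-allele + second-allele).
    """
    cleaned = raw.strip().upper().replace("/", "").replace("|", "")
    if len(cleaned) != 2:
        raise InvalidGenotypeError(
            f"{snp.snp_id}: cannot parse genotype {raw!r} (need two alleles)"
        )
    order = {a: i for i, a in enumerate(snp.alleles)}
    for ch in cleaned:
        if ch not in order:
            raise InvalidGenotypeError(
                f"{snp.snp_id}: allele {ch!r} in genotype {raw!r} is not one "
                f"of {snp.alleles}"
            )
    return "".join(sorted(cleaned, key=order.__getitem__))


@dataclass
class GenotypeFrequencyTable:
    """Per-severity-group genotype percentages with group sizes.

    ``frame`` is indexed by (snp_id, genotype) with one column per severity
    label; percentages are kept at their input precision.  Within each SNP
    and group the percentages must sum to 100 within +/-0.05 (the slack a
    2-decimal published table can accumulate).
    """

    frame: pd.DataFrame
    group_sizes: dict[Severity, int]

    SUM_TOL = 0.05

    def __post_init__(self) -> None:
        self.validate()

    @property
    def snp_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for snp_id, _ in self.frame.index:
            seen.setdefault(snp_id, None)
        return tuple(seen)

    @property
    def groups(self) -> tuple[Severity, ...]:
        return tuple(Severity.parse(c) for c in self.frame.columns)

    def genotypes(self, snp_id: str) -> tuple[str, ...]:
        return tuple(self.frame.loc[snp_id].index)

    def percentages(self, snp_id: str, group: Severity) -> dict[str, float]:
        col = self.frame.loc[snp_id][group.label]
        return dict(col)

    def validate(self) -> None:
        for g in self.groups:
            if self.group_sizes.get(g, 0) <= 0:
                raise TableValidationError(f"group size for {g.label} missing or <= 0")
        for snp_id in self.snp_ids:
            for g in self.groups:
                total = sum(self.percentages(snp_id, g).values())
                if abs(total - 100.0) > self.SUM_TOL:
                    raise TableValidationError(
                        f"{snp_id}/{g.label}: genotype percentages sum to "
                        f"{total:.2f}, not 100"
                    )

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, Mapping[str, Mapping[Severity, int]]],
        group_sizes: Mapping[Severity, int],
    ) -> "GenotypeFrequencyTable":
        """Build a table from raw integer counts (exact percentages kept)."""
        rows = []
        for snp_id, per_geno in counts.items():
            for geno, per_group in per_geno.items():
                row: dict[str, object] = {"snp_id": snp_id, "genotype": geno}
                for g, n in per_group.items():
                    row[g.label] = 100.0 * n / group_sizes[g]
                rows.append(row)
        frame = pd.DataFrame(rows).set_index(["snp_id", "genotype"])
        return cls(frame=frame, group_sizes=dict(group_sizes))

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, snps: Sequence[SnpDefinition]
    ) -> "GenotypeFrequencyTable":
        """Tabulate a complete-case cohort into a frequency table."""
        sizes = {g: 0 for g in SEVERITY_ORDER}
        counts: dict[str, dict[str, dict[Severity, int]]] = {
            snp.snp_id: {g: {sev: 0 for sev in SEVERITY_ORDER} for g in snp.genotypes}
            for snp in snps
        }
        n_skipped = 0
        for p in cohort:
            if any(p.genotypes.get(snp.snp_id) is None for snp in snps):
                n_skipped += 1
                continue
            sizes[p.severity] += 1
            for snp in snps:
                counts[snp.snp_id][p.genotypes[snp.snp_id]][p.severity] += 1
        if n_skipped:
            logger.info("from_cohort: skipped %d incomplete patients", n_skipped)
        present = {g: n for g, n in sizes.items() if n > 0}
        trimmed = {
            snp_id: {
                geno: {g: per_group[g] for g in present}
                for geno, per_group in per_geno.items()
            }
            for snp_id, per_geno in counts.items()
        }
        return cls.from_counts(trimmed, present)


def read_frequency_table(path: str | Path) -> GenotypeFrequencyTable:
    """Read a genotype-frequency CSV.

    Layout: header ``snp_id,genotype,<group>,...``; a first data row with
    snp_id ``__n__`` carries the group sizes; remaining rows carry
    percentages.  Lines starting with ``#`` are comments.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, comment="#", dtype={"snp_id": str, "genotype": str})
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a readable frequency CSV ({exc})") from None
    required = {"snp_id", "genotype"}
    if not required.issubset(raw.columns) or len(raw.columns) < 3:
        raise FormatError(
            f"{path}: expected columns snp_id, genotype and one per group; "
            f"got {list(raw.columns)}"
        )
    group_cols = [c for c in raw.columns if c not in ("snp_id", "genotype")]
    size_rows = raw[raw["snp_id"] == "__n__"]
    if len(size_rows) != 1:
        raise FormatError(f"{path}: expected exactly one __n__ group-size row")
    group_sizes = {
        Severity.parse(c): int(size_rows.iloc[0][c]) for c in group_cols
    }
    body = raw[raw["snp_id"] != "__n__"].copy()
    body[group_cols] = body[group_cols].astype(float)
    frame = body.set_index(["snp_id", "genotype"])[group_cols]
    return GenotypeFrequencyTable(frame=frame, group_sizes=group_sizes)


def write_frequency_table(table: GenotypeFrequencyTable, path: str | Path) -> None:
    path = Path(path)
    cols = [g.label for g in table.groups]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["snp_id", "genotype", *cols])
        writer.writerow(["__n__", "", *[table.group_sizes[g] for g in table.groups]])
        for (snp_id, geno), row in table.frame.iterrows():
            writer.writerow([snp_id, geno, *[row[c] for c in cols]])


def counts_from_frequencies(
    table: GenotypeFrequencyTable, snp_id: str, group: Severity
) -> dict[str, int]:
    """Reconstruct integer genotype counts from published percentages.

    Each percentage is scaled to the group size and rounded to the nearest
    integer; any residual (the rounded counts not summing to n) is repaired
    by largest-remainder adjustment, one unit at a time, on the genotype
    with the greatest rounding residual.  The returned counts always sum to
    the group size.
    """
    n = table.group_sizes[group]
    pct = table.percentages(snp_id, group)
    raw = {g: p / 100.0 * n for g, p in pct.items()}
    counts = {g: int(round(v)) for g, v in raw.items()}
    genotypes = list(pct)
    while sum(counts.values()) < n:
        g = max(genotypes, key=lambda g: (raw[g] - counts[g], -genotypes.index(g)))
        counts[g] += 1
    while sum(counts.values()) > n:
        g = min(
            (g for g in genotypes if counts[g] > 0),
            key=lambda g: (raw[g] - counts[g], genotypes.index(g)),
        )
        counts[g] -= 1
    return counts


def allele_frequencies(counts: Mapping[str, int]) -> dict[str, float]:
    """Allele frequencies from diploid genotype counts.

    Each genotype string contributes its two allele characters; the result
    is invariant to genotype label order and sums to 1.
    """
    total = sum(counts.values())
    if total == 0:
        raise UndefinedFrequencyError("allele frequencies undefined for 0 genotypes")
    tally: dict[str, int] = {}
    for geno, n in counts.items():
        for allele in geno:
            tally[allele] = tally.get(allele, 0) + n
    return {a: c / (2 * total) for a, c in sorted(tally.items()) if c > 0}


def _parse_csv_genotype(
    cell: str, snp: SnpDefinition
) -> str | None:
    cell = cell.strip()
    if cell.upper() in _MISSING_TOKENS:
        return None
    return normalize_genotype(cell, snp)


def read_cohort(
    genotype_path: str | Path,
    snps: Sequence[SnpDefinition],
    format: str = "csv",
    labels_path: str | Path | None = None,
    name: str | None = None,
) -> Cohort:
    """Read an individual-level cohort.

    CSV dialect: one row per patient with columns ``patient_id``, one per
    rsID, and ``severity``.  VCF dialect: one record per SNP (matched by
    ID), GT per sample, with severity labels supplied in a two-column CSV
    via ``labels_path``.  Missing calls (empty cell, "./.") are preserved
    as missing.
    """
    genotype_path = Path(genotype_path)
    if name is None:
        name = genotype_path.stem
    if format == "csv":
        return _read_cohort_csv(genotype_path, snps, name)
    if format == "vcf":
        if labels_path is None:
            raise CohortError("VCF cohorts require a labels file")
        return _read_cohort_vcf(genotype_path, snps, Path(labels_path), name)
    raise ValueError(f"unknown cohort format {format!r}")


def _read_cohort_csv(
    path: Path, snps: Sequence[SnpDefinition], name: str
) -> Cohort:
    try:
        frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a readable cohort CSV ({exc})") from None
    missing_cols = {"patient_id", "severity"} - set(frame.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing columns {sorted(missing_cols)}")
    by_id = {snp.snp_id: snp for snp in snps}
    absent = [s for s in by_id if s not in frame.columns]
    if absent:
        raise FormatError(f"{path}: missing SNP columns {absent}")
    patients = []
    for _, row in frame.iterrows():
        genotypes = {
            snp_id: _parse_csv_genotype(row[snp_id], snp)
            for snp_id, snp in by_id.items()
        }
        patients.append(
            Patient(
                patient_id=row["patient_id"],
                genotypes=genotypes,
                severity=Severity.parse(row["severity"]),
            )
        )
    logger.info("read %d patients from %s", len(patients), path)
    return Cohort(patients=patients, name=name)


def _read_cohort_vcf(
    path: Path, snps: Sequence[SnpDefinition], labels_path: Path, name: str
) -> Cohort:
    import pysam

    labels = _read_labels(labels_path)
    by_id = {snp.snp_id: snp for snp in snps}
    calls: dict[str, dict[str, str | None]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for sample in samples:
            if sample not in labels:
                raise CohortError(
                    f"sample {sample!r} present in VCF but absent from "
                    f"labels file {labels_path}"
                )
            calls[sample] = {snp_id: None for snp_id in by_id}
        for record in vcf:
            snp = by_id.get(record.id or "")
            if snp is None:
                continue
            if record.alts is None or len(record.alts) != 1:
                raise FormatError(
                    f"{path}: record {record.id} is not biallelic"
                )
            site_alleles = (record.ref, record.alts[0])
            for sample in samples:
                gt = record.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                raw = "".join(site_alleles[a] for a in gt)
                calls[sample][snp.snp_id] = normalize_genotype(raw, snp)
    patients = [
        Patient(patient_id=s, genotypes=calls[s], severity=labels[s])
        for s in calls
    ]
    logger.info("read %d samples from %s", len(patients), path)
    return Cohort(patients=patients, name=name)


def _read_labels(path: Path) -> dict[str, Severity]:
    try:
        frame = pd.read_csv(path, comment="#", dtype=str)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a readable labels CSV ({exc})") from None
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: labels file needs (sample id, severity) columns")
    id_col, sev_col = frame.columns[:2]
    return {
        row[id_col]: Severity.parse(row[sev_col]) for _, row in frame.iterrows()
    }


def write_cohort(
    cohort: Cohort, path: str | Path, snp_ids: Sequence[str]
) -> None:
    """Write a cohort as CSV (missing genotypes become empty cells)."""
    cohort.to_dataframe(snp_ids).to_csv(path, index=False)


def validate_cohort(cohort: Cohort, snps: Iterable[SnpDefinition]) -> None:
    """Check every non-missing genotype is canonical for its SNP."""
    by_id = {snp.snp_id: snp for snp in snps}
    for p in cohort:
        for snp_id, geno in p.genotypes.items():
            if geno is None or snp_id not in by_id:
                continue
            if geno not in by_id[snp_id].genotypes:
                raise InvalidGenotypeError(
                    f"patient {p.patient_id}: genotype {geno!r} is not "
                    f"canonical for {snp_id}"
                )
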