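"""Exception hierarchy. Everything raised on purpose derives from ThalscoreError."""


class ThalscoreError(Exception):
    """Base class for all package errors."""


class InvalidGenotypeError(ThalscoreError):
    """A genotype string uses an allele the SNP does not carry."""


class TableValidationError(ThalscoreError):
    """A genotype-frequency table violates its invariants."""


class FormatError(ThalscoreError):
    """An input file is structurally unreadable."""


class CohortError(ThalscoreError):
    """An individual-level cohort is inconsistent (labels, sample ids)."""


class UndefinedFrequencyError(ThalscoreError):
    """Allele frequencies requested from an empty count table."""


class UndefinedScoreError(ThalscoreError):
    """A risk score is undefined because a predictive genotype is missing."""


class ScoreRangeError(ThalscoreError):
    """A total score falls outside the range a scoring model covers."""


class ConfigError(ThalscoreError):
    """A scoring-system or simulation configuration is invalid."""
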