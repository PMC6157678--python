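"""Exception hierarchy shared across the package."""


class MateChoiceError(Exception):
    """Base class for all package-specific errors."""


class InvalidSequenceError(MateChoiceError):
    """Nucleotide sequence contains characters other than A/C/G/T."""


class PseudogeneError(MateChoiceError):
    """Translation hit an internal stop codon."""

    def __init__(self, codon_index: int, message: str | None = None):
        self.codon_index = codon_index
        super().__init__(
            message or f"internal stop codon at codon index {codon_index}"
        )


class AlignmentError(MateChoiceError):
    """Sequences of unequal length (or out-of-range mask) where an
    aligned, indel-free comparison was required."""


class MissingDataError(MateChoiceError):
    """A genotype or metric needed for a computation is missing; the
    caller should exclude the individual/pair from that analysis."""


class FrequencyTableError(MateChoiceError):
    """An allele is absent from the supplied frequency table."""


class ConfigError(MateChoiceError):
    """Invalid or internally inconsistent configuration."""


class ValidationError(MateChoiceError):
    """Dataset failed integrity validation; carries the full report."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "dataset validation failed:\n" + "\n".join(f"  - {p}" for p in problems)
        )


class InsufficientDataError(MateChoiceError):
    """Too few rows/columns/counts for the requested statistic."""
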