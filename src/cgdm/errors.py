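"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 2, data/format errors -> 3,
configuration errors -> 4.
"""


class CgdmError(Exception):
    """Base class for all package errors."""


class UsageError(CgdmError):
    """The caller asked for something malformed (empty filter, bad flag)."""


class ConfigurationError(CgdmError):
    """Bad or missing configuration: unknown dialect, unregistered dosing
    function, unreadable knowledge table."""


class DataError(CgdmError):
    """Input data violates a contract (schema mismatch, inconsistent zygosity
    evidence, identity alleles)."""


class FormatError(DataError):
    """A file could not be understood at the format level (missing VCF header,
    missing MAF columns)."""


class ReferenceContextError(DataError):
    """A reference window does not cover the span a normalization step needs.

    Carries the span so callers can fetch a wider window.
    """

    def __init__(self, chromosome: str, start: int, end: int, message: str = ""):
        self.chromosome = chromosome
        self.start = start
        self.end = end
        super().__init__(
            message
            or f"reference window must cover {chromosome}:{start}-{end}"
        )


class ReferenceMismatchError(DataError):
    """The REF allele of a record disagrees with the reference sequence."""


class GenotypeUnknownError(DataError):
    """A pharmacogenetic calculation was requested for an unknown genotype.

    The message instructs the caller to use the clinical (non-genetic) model.
    """


class ParseError(DataError):
    """Unparseable nomenclature text; ``position`` is the 0-based offset at
    which parsing failed."""

    def __init__(self, text: str, position: int, message: str):
        self.text = text
        self.position = position
        super().__init__(f"{message} (at offset {position} in {text!r})")
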