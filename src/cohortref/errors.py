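"""Exception hierarchy for cohortref.

All package-specific failures derive from :class:`CohortRefError` so callers
can catch one base class at CLI boundaries.
"""


class CohortRefError(Exception):
    """Base class for all cohortref errors."""


class InvalidInputError(CohortRefError, ValueError):
    """Malformed user input: bad characters, empty sequences, bad arguments."""


class CatalogMismatchError(CohortRefError, ValueError):
    """An alignment or count refers to a genome absent from the catalog."""


class ContractViolationError(CohortRefError, ValueError):
    """An internal precondition was violated (e.g. mixed read ids)."""


class CigarParseError(CohortRefError, ValueError):
    """A CIGAR string could not be parsed."""


class CorruptStreamError(CohortRefError, ValueError):
    """An encoded-read container is internally inconsistent."""


class ReferenceChecksumError(CorruptStreamError):
    """The reference supplied for decoding differs from the one used to encode."""


class ExternalToolNotFoundError(CohortRefError, RuntimeError):
    """A requested external compressor binary is not on PATH."""
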