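"""Exception hierarchy shared across the package.

The split matters for the CLI, which maps parse, validation and internal
failures onto distinct exit codes.
"""


class PksmithError(Exception):
    """Base class for all package errors."""


class ParseError(PksmithError):
    """A file or string could not be parsed (bad FASTA/GenBank/JSON/CSV)."""


class ValidationError(PksmithError):
    """Inputs parsed but violate a model invariant or precondition."""


class UnalignableDomainError(PksmithError):
    """Domain sequence aligns to its reference scaffold below the identity floor."""


class NoAmpliconError(PksmithError):
    """Primer pair produces no amplicon on the template."""


class AmbiguousAmpliconError(PksmithError):
    """Primer pair produces more than one candidate amplicon."""
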