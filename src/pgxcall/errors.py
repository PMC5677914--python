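"""Exception hierarchy."""


class PgxError(Exception):
    """Base class for all package errors."""


class FormatError(PgxError):
    """A file could not be parsed (names the file and, where known, the line)."""


class ValidationError(PgxError):
    """Parsed content violates a model invariant."""


class GenotypeDataError(PgxError):
    """An observed allele is not among the panel's ref/alt for its locus."""
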