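"""Exception hierarchy."""


class ProkannotError(Exception):
    """Base class for all package errors."""


class FormatError(ProkannotError):
    """Malformed or invalid input file."""


class UnsupportedLocationError(FormatError):
    """Feature location (join/multi-exon) outside the prokaryotic CDS model."""


class DomainError(ProkannotError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class IntegrityError(ProkannotError):
    """Internal consistency violation, e.g. an in-frame stop inside an ORF."""
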