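"""Exception hierarchy shared across the package."""


class PhagecompError(Exception):
    """Base class for all package errors."""


class FormatError(PhagecompError):
    """Malformed input file (FASTA/GFF3/GenBank/TSV)."""


class ValidationError(PhagecompError):
    """Inputs are well-formed but violate a precondition."""
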