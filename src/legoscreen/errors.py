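"""Exception hierarchy shared across the pipeline."""


class LegoError(Exception):
    """Base class for all package errors."""


class ParseError(LegoError):
    """A standard-format file (FASTA/FASTQ/TSV) could not be parsed."""


class ValidationError(LegoError):
    """An in-memory object violates a domain invariant."""


class ConfigurationError(LegoError):
    """A configuration value is inconsistent with the enzymatic geometry."""
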