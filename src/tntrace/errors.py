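"""Exception hierarchy.

``TntraceError`` is the base; ``ConfigError`` maps to CLI exit code 2,
everything else data-related maps to exit code 3.
"""


class TntraceError(Exception):
    """Base class for all package errors."""


class FormatError(TntraceError):
    """Malformed input file (FASTA/FASTQ/SAM/GFF/BED)."""


class ValidationError(TntraceError):
    """Input parsed but violates a documented invariant."""


class ConfigError(TntraceError):
    """Invalid run configuration."""
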