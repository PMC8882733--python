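"""Exception hierarchy shared across the package."""


class CircVerifyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CircVerifyError):
    """A malformed input file (FASTA/GTF/SAM/TSV)."""


class ConfigError(CircVerifyError):
    """An invalid simulation or run configuration."""


class BoundsError(CircVerifyError):
    """A coordinate outside the reference it refers to."""


class ConsistencyError(CircVerifyError):
    """Internally inconsistent inputs (e.g. verified set not a subset of assembled)."""
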