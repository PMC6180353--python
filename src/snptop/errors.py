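"""Exception hierarchy for the snptop pipeline.

Every failure mode a caller may want to distinguish — malformed text,
codec overflow, cryptographic rejection, framing damage — has its own
class so the CLI can map them to precise exit messages.
"""


class SnptopError(Exception):
    """Base class for all snptop errors."""


class VcfFormatError(SnptopError):
    """A VCF line does not match the 8-field dialect (carries the line number)."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class VcfFieldError(VcfFormatError):
    """A field value is outside the dialect (chromosome, base, TYPE...)."""


class VcfOrderingError(SnptopError):
    """Records violate the sorted-by-(chromosome, position) invariant."""


class CodecError(SnptopError):
    """A record cannot be represented in the 80-bit packed format."""


class CorruptRecordError(CodecError):
    """Packed bytes decode to field values no valid record can produce."""


class AuthenticationError(SnptopError):
    """AES-GCM tag verification failed: the block was tampered with."""


class FramingError(SnptopError):
    """An encrypted file is truncated or carries trailing garbage."""


class ManifestError(SnptopError):
    """A cohort manifest is unusable (missing label, unreadable file...)."""


class ConfigError(SnptopError):
    """Invalid engine or CLI configuration."""
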