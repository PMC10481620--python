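"""Exception types shared across the package."""


class CySGANError(Exception):
    """Base class for package-specific errors."""


class VolumeIOError(CySGANError):
    """Unreadable file or unsupported on-disk layout."""


class ShapeError(CySGANError):
    """Array shape incompatible with the requested operation."""


class UsageError(CySGANError):
    """Operation invoked with semantically invalid arguments."""


class GenerationError(CySGANError):
    """Synthetic phantom generation could not satisfy its constraints."""


class QuarantineError(CySGANError):
    """Attempted access to target-domain labels from a training context."""


class TrainingError(CySGANError):
    """Non-finite loss or otherwise unrecoverable optimisation state."""
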