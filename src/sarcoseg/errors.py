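"""Exception hierarchy shared across the package."""


class SarcosegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SarcosegError, ValueError):
    """An input violates a documented precondition or invariant."""


class DegenerateInputError(SarcosegError, ValueError):
    """Numerically degenerate input (constant slice, zero-norm vector, ...)."""


class AnnotationError(SarcosegError, ValueError):
    """A tumor box annotation is inconsistent with the image it refers to."""


class InsufficientSlicesError(SarcosegError, ValueError):
    """A volume has fewer slices than the extraction window requires."""


class TransferError(SarcosegError, ValueError):
    """Pretrained weights are incompatible with the target model."""
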