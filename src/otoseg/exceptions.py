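"""Typed errors raised across the toolkit."""


class OtosegError(Exception):
    """Base class for all otoseg errors."""


class ConfigurationError(OtosegError):
    """A spec or config is internally inconsistent (e.g. geometry out of bounds)."""


class DomainError(OtosegError):
    """An argument lies outside its documented domain."""


class SeedingError(OtosegError):
    """A class is too small to place the requested seeds."""


class DegenerateContourError(OtosegError):
    """An active contour collapsed to empty or grew to the full frame."""


class UnsupportedImageError(OtosegError):
    """Input image file is not 8-bit grayscale-convertible."""
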