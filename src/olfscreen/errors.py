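"""Exception hierarchy shared across the package."""


class OlfscreenError(Exception):
    """Base class for all package errors."""


class EmptyLibraryError(OlfscreenError):
    """A compound source contained no valid records."""


class InvalidStructureError(OlfscreenError):
    """A structure failed chemical sanitization (e.g. a valence error)."""


class MissingGeometryError(OlfscreenError):
    """An operation needing 3D coordinates was called on a compound without a conformer."""


class ConfigurationError(OlfscreenError):
    """Inconsistent or unknown parameters (bad descriptor name, wrong anchor count, ...)."""


class GeometryError(OlfscreenError):
    """A geometric precondition failed (occluded seed point, unaligned pose, ...)."""


class InsufficientDataError(OlfscreenError):
    """Too few records for the requested fit or clustering."""


class DataIntegrityError(OlfscreenError):
    """Packaged fixture data failed validation."""
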