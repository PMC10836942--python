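"""Exception hierarchy shared across shmkit modules."""


class ShmkitError(Exception):
    """Base class for all shmkit errors."""


class SVGParseError(ShmkitError):
    """Malformed XML or non-SVG input."""


class ValidationError(ShmkitError):
    """Input violates a documented invariant (duplicate ids, bad shapes, ...)."""


class DimensionError(ShmkitError):
    """SVG canvas dimensions could not be determined."""


class CapabilityError(ShmkitError):
    """An optional backend (e.g. UMAP) is not available."""
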