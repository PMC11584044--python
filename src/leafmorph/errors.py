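"""Exception hierarchy shared across the pipeline stages."""


class LeafmorphError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LeafmorphError, ValueError):
    """A parameter is outside its documented range."""


class FormatError(LeafmorphError, ValueError):
    """An input file could not be parsed as an outline or table."""


class GeometryError(LeafmorphError, ValueError):
    """An outline or configuration is geometrically degenerate."""


class CorrespondenceError(LeafmorphError, ValueError):
    """Two landmark configurations cannot be put in point correspondence."""


class CoverageError(LeafmorphError, ValueError):
    """A weather window is not covered by the available daily series."""


class JoinError(LeafmorphError, ValueError):
    """Tables could not be joined because of unmatched identifiers."""


class ComparabilityError(LeafmorphError, ValueError):
    """Model fits are not comparable (different responses or case counts)."""
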