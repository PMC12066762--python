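"""Exception types raised across the toolkit."""


class SeedtrackError(Exception):
    """Base class for all toolkit errors."""


class EmptyViewError(SeedtrackError):
    """A silhouette view contains no foreground component."""


class AmbiguityError(SeedtrackError):
    """Segmentation found more than one plausible foreground object."""

    def __init__(self, count: int, message: str | None = None):
        self.count = count
        super().__init__(message or f"ambiguous segmentation: {count} large components")


class CarveFailureError(SeedtrackError):
    """The silhouettes are mutually inconsistent (empty visual hull)."""


class DegenerateShapeError(SeedtrackError):
    """Hull too small for morphometric measurement."""


class DetectionFailureError(SeedtrackError):
    """Fewer grid crossings detected than the tray layout requires."""

    def __init__(self, found: int, required: int):
        self.found = found
        self.required = required
        super().__init__(f"detected {found} crossings, layout requires {required}")


class GridFitError(SeedtrackError):
    """Crossing points are degenerate (e.g. collinear); no grid can be fitted."""


class IntegrityError(SeedtrackError):
    """Referential-integrity violation in the tracking tables."""


class DomainError(SeedtrackError, ValueError):
    """An input is outside the mathematical domain of the operation."""
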