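"""Exception hierarchy for craniotome.

All errors raised deliberately by the library derive from :class:`CraniotomeError`
so callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class CraniotomeError(Exception):
    """Base class for all craniotome errors."""


class ValidationError(CraniotomeError, ValueError):
    """Input violates a documented precondition or invariant."""


class MeshIOError(CraniotomeError, IOError):
    """A mesh or contour file could not be read or written."""


class ProjectionError(CraniotomeError):
    """A drawn point is too far from the target surface to project."""


class ContourNotClosedError(CraniotomeError):
    """Region growing requires a closed projected contour."""


class SeedInvalidError(CraniotomeError):
    """The region-growing seed lies on a barrier edge or off the surface."""


class GrowthLeakError(CraniotomeError):
    """Region growing escaped the contour (gap in the barrier)."""


class NumericalInstabilityError(CraniotomeError):
    """The mass-spring integration produced NaN/overflow positions."""
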