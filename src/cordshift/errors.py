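"""Exception hierarchy.

Validation problems (bad geometry, malformed fixtures, out-of-domain
parameters) are kept distinct from computation failures so the CLI can map
them onto distinct exit codes.
"""


class CordshiftError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CordshiftError):
    """Malformed input: bad fixture schema, missing keys, non-finite data."""


class GeometryError(ValidationError):
    """Invalid contour or structure geometry (too few vertices, self-intersection)."""


class DomainError(ValidationError):
    """Parameter outside its mathematical domain (e.g. shrink >= 1, SSA <= 0)."""


class EmptyRegionError(CordshiftError):
    """A region selection contains no contour slices."""


class EmptyStructureError(CordshiftError):
    """A rasterized structure produced an empty voxel mask."""


class InsufficientVolumeError(CordshiftError):
    """Mask volume is smaller than the requested DVH volume threshold."""


class OutOfExtentError(CordshiftError):
    """A (displaced) structure leaves the dose-grid extent."""


class DegenerateInputError(CordshiftError):
    """Statistical input with no usable variation (e.g. constant regressor)."""
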