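"""Exception types shared across the package.

Every error message starts with a stable machine-checkable phrase so the CLI
can map failures to diagnostics without string surgery.
"""


class DtplanError(ValueError):
    """Base class for all domain errors."""


class GeometryError(DtplanError):
    """Shape placed (partly) outside the voxel grid."""


class EmptyStructureError(DtplanError):
    """Operation requires a non-empty voxel mask."""


class PathfindingError(DtplanError):
    """No feasible path through the cost map."""


class DoseError(DtplanError):
    """Invalid or degenerate dose input."""


class LogError(DtplanError):
    """Malformed delivery log."""


class ConfigError(DtplanError):
    """Invalid run configuration or unresolvable references."""
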