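"""Exception hierarchy.

All package errors derive from :class:`VoxFparError` so callers (and the CLI)
can distinguish configuration, data-format, and numeric problems.
"""


class VoxFparError(Exception):
    """Base class for all voxfpar errors."""


class ConfigurationError(VoxFparError):
    """Invalid parameter or run configuration."""


class FormatError(VoxFparError):
    """Malformed input file (LAS, raster, CSV schema)."""


class InsufficientDataError(VoxFparError):
    """Too few points / rows / groups for the requested operation."""


class DegenerateDataError(VoxFparError):
    """Input is degenerate (collinear control points, zero-variance stand...)."""


class PipelineError(VoxFparError):
    """Missing upstream artifact or broken stage contract."""
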