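"""Typed exceptions shared across the package."""


class AnisosegError(Exception):
    """Base class for package errors."""


class ConfigError(AnisosegError):
    """Invalid configuration value or schema violation."""


class DomainError(AnisosegError):
    """Operation applied to a volume in the wrong intensity domain."""


class ShapeError(AnisosegError):
    """Array shapes incompatible with the requested operation."""


class PlacementError(AnisosegError):
    """Synthetic lesion does not fit inside the phantom volume."""


class EmptyMaskError(AnisosegError):
    """A mask that must contain foreground voxels is empty."""


class TrainingError(AnisosegError):
    """Training aborted (non-finite loss or inconsistent inputs)."""
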