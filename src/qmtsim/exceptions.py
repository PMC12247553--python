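"""Exception hierarchy shared across the package."""


class QmtError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(QmtError):
    """A configuration value (step counts, schema, ...) is invalid."""


class NumericalError(QmtError):
    """A numerical routine failed (root not bracketed, non-finite result)."""


class DegenerateDynamicsError(NumericalError):
    """The cycle map has no unique periodic fixed point."""


class SingularFisherError(NumericalError):
    """Fisher matrix is numerically singular; carries the worst column pair."""

    def __init__(self, message, worst_pair=None):
        super().__init__(message)
        self.worst_pair = worst_pair


class DegenerateVoxelError(QmtError):
    """A voxel observation cannot be fitted (all-zero, zero first coefficient)."""
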