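"""Named error types raised across the package.

Every user-facing precondition failure maps onto one of these so that the
command-line layer can translate them into stable exit codes
(config -> 2, data -> 3, numerics -> 4).
"""


class DCFCNNError(Exception):
    """Base class for all package errors."""


class ConfigError(DCFCNNError, ValueError):
    """An invalid configuration value or an unknown configuration key."""


class DataError(DCFCNNError, ValueError):
    """Invalid or missing input data (images, manifests, folds)."""


class InvalidCategoryError(DataError):
    """A scene category outside {no_cancer, partial_cancer, full_cancer}."""


class ChannelMismatchError(ConfigError):
    """Residual structure asked to preserve shape with unequal channel counts."""


class FusionShapeError(ConfigError):
    """Branch-fusion inputs have different shapes; names both shapes."""

    def __init__(self, spatial_shape, channel_shape):
        self.spatial_shape = tuple(spatial_shape)
        self.channel_shape = tuple(channel_shape)
        super().__init__(
            "cannot fuse branches element-wise: spatial branch produces "
            f"{self.spatial_shape} but channel branch produces {self.channel_shape}; "
            "check n_mlf / rs1_first_stride / input size"
        )


class UnknownUnitError(DataError):
    """A feature-map capture point that does not exist in the network."""

    def __init__(self, name, valid):
        self.name = name
        self.valid = tuple(valid)
        super().__init__(
            f"unknown unit {name!r}; valid units are: {', '.join(self.valid)}"
        )


class NumericalError(DCFCNNError, ArithmeticError):
    """Non-finite loss or activations during optimisation."""
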