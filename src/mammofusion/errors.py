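"""Exception types shared across the package."""


class MammofusionError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MammofusionError, ValueError):
    """A data object (image, dataset, batch) violates a precondition."""


class InvalidConfigError(MammofusionError, ValueError):
    """A configuration object violates a precondition."""


class ConstructionError(MammofusionError, ValueError):
    """A network cannot be assembled from the given configuration."""
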