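"""Exception types shared across build stages."""


class WulffgraftError(Exception):
    """Base class for all package errors."""


class FormatError(WulffgraftError):
    """A file is missing required tags or cannot be parsed."""


class GeometryError(WulffgraftError):
    """A geometric construction is infeasible (unbounded shape, bad length)."""


class TopologyError(WulffgraftError):
    """Bond list inconsistent with the structure."""


class CapacityError(WulffgraftError):
    """A site request exceeds what the surface offers."""


class PlacementError(WulffgraftError):
    """A molecule cannot be placed without steric clash."""


class ConfigurationError(WulffgraftError):
    """An analysis or build configuration is internally inconsistent."""
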