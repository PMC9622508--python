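"""Exception types shared across the pipeline."""


class GridMismatchError(ValueError):
    """Two rasters or a raster and a grid do not share the same geometry."""


class DataRangeError(ValueError):
    """A raster holds values outside its documented domain."""


class AllocationError(RuntimeError):
    """Footprint or activity growth could not be allocated.

    Carries the name of the zone that ran out of allocatable cells.
    """

    def __init__(self, zone: str, message: str | None = None):
        self.zone = zone
        super().__init__(message or f"no allocatable cells remain in zone {zone!r}")


class GenerationError(RuntimeError):
    """The synthetic landscape generator could not satisfy a structural constraint."""


class ConfigurationError(ValueError):
    """A model or run configuration is incomplete or inconsistent."""
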