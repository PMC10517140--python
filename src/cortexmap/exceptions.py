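"""Exception hierarchy used across the package."""


class CortexmapError(Exception):
    """Base class for package-specific errors."""


class ArgumentError(CortexmapError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDataError(CortexmapError):
    """The input data cannot support the requested computation (rank, constancy, ...)."""


class ConfigurationError(CortexmapError):
    """A design/analysis configuration is internally inconsistent."""


class SingularMatrixError(CortexmapError):
    """A matrix inversion was requested on a (numerically) singular matrix."""


class UnreachableError(CortexmapError):
    """Two vertices lie in different connected components of the surface graph."""

    def __init__(self, src_component: int, dst_component: int):
        self.src_component = src_component
        self.dst_component = dst_component
        super().__init__(
            f"vertices lie in different components ({src_component} vs {dst_component})"
        )
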