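"""Exception types shared across the package."""


class AxonMorphError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AxonMorphError, ValueError):
    """A model or configuration parameter violates its domain."""


class IncompatibleObservablesError(AxonMorphError, ValueError):
    """The (g_MRI, V) pair admits no model solution within bounds.

    Raised by the inverse solvers when the observable combination lies
    outside the band of values the forward model can produce for any
    admissible parameter set (cf. the compatibility map).
    """


class EstimationError(AxonMorphError, RuntimeError):
    """A fitting routine failed to converge to an acceptable solution."""


class QuadratureError(AxonMorphError, RuntimeError):
    """Numerical integration failed to reach the requested accuracy."""


class PeakDetectionError(AxonMorphError, RuntimeError):
    """No usable activation peak could be located in a time course."""
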