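"""Exception types shared across the pipeline."""


class BarcodesimError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(BarcodesimError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(BarcodesimError, ValueError):
    """Input is structurally valid but degenerate (e.g. zero-diameter tree,
    all pairwise distances equal) so the operation has no meaningful result."""


class SaturationError(BarcodesimError, ValueError):
    """A mismatch proportion at or beyond 3/4, where the Jukes-Cantor
    correction is undefined."""


class SimulationFailureError(BarcodesimError, RuntimeError):
    """A stochastic procedure failed to satisfy its contract within the
    documented iteration cap."""


class FitFailureError(BarcodesimError, RuntimeError):
    """Nonlinear fitting failed to converge."""


class ConfigurationError(BarcodesimError, ValueError):
    """Inconsistent configuration (e.g. estimator requires an alignment but
    only a distance matrix was supplied)."""
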