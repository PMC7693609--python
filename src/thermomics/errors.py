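"""Exception types shared across the thermomics pipeline."""


class ThermomicsError(Exception):
    """Base class for all thermomics errors."""


class ValidationError(ThermomicsError, ValueError):
    """Invalid inputs, shapes, or physical parameters."""


class StabilityError(ThermomicsError, ValueError):
    """Explicit time step violates the finite-difference stability bound."""


class ConfigError(ThermomicsError, ValueError):
    """Malformed or incomplete run configuration."""


class ConvergenceWarning(UserWarning):
    """An iterative solver stopped at max_iter before reaching tol."""
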