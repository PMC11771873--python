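"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A model parameter is outside its admissible domain."""


class VariantMismatchError(ParameterError):
    """Kernel parameters are inconsistent with the declared model variant."""


class DegenerateFieldError(ValueError):
    """A Fisher-information field has non-positive values and cannot define a transform."""


class DegenerateDataError(ValueError):
    """Data carry no information about the quantity being estimated."""


class ConvergenceError(RuntimeError):
    """No optimizer restart converged."""


class ConfigurationError(ValueError):
    """Invalid analysis configuration (e.g., patch larger than frame)."""
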