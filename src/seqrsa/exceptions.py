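"""Exception types shared across the package."""


class DesignValidationError(ValueError):
    """An experiment design, mask or table violates a structural invariant."""


class DegeneratePredictorError(ValueError):
    """A predictor (or outcome) has zero variance where variance is required."""


class GenerationError(RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""


class PhaseMismatchError(ValueError):
    """Pre/post phase labels of two inputs are inconsistent."""
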