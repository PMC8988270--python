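"""Exception types raised across the pipeline."""


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """Input data violate a contract (e.g. an item score outside 0-3)."""


class EstimationError(RuntimeError):
    """Network estimation failed (degenerate input or non-convergence)."""


class GenerationError(RuntimeError):
    """The synthetic-cohort generator could not produce a valid model."""
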