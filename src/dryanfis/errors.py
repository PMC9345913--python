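"""Exception hierarchy shared across the package."""


class DryAnfisError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DryAnfisError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateCurveError(DryAnfisError, ValueError):
    """A drying curve cannot support the requested computation
    (e.g. initial moisture equals equilibrium moisture)."""


class InsufficientDataError(DryAnfisError, ValueError):
    """Fewer usable points than the operation requires."""


class DegenerateInputError(DryAnfisError, ValueError):
    """No fuzzy rule fires for an input vector (all firing strengths zero)."""


class InvalidConfigError(DryAnfisError, ValueError):
    """A configuration object violates its invariants."""


class SchemaError(DryAnfisError, ValueError):
    """An input table is missing required columns or is malformed."""
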