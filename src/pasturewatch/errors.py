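"""Exception hierarchy shared across the pipeline stages."""


class PasturewatchError(Exception):
    """Base class for all package-specific errors."""


class DesignError(PasturewatchError, ValueError):
    """Experimental design and herd are inconsistent (e.g. herd size mismatch)."""


class SchemaError(PasturewatchError, KeyError):
    """An input table is missing required columns or identifiers."""


class SingularFitError(PasturewatchError, ValueError):
    """A regression fit is singular (e.g. all sward heights identical)."""


class InfeasibleAllocationError(PasturewatchError, ValueError):
    """No positive net herbage per hectare; a paddock area cannot be computed."""


class EmptyInputError(PasturewatchError, ValueError):
    """An aggregation was requested over an empty set of records."""


class UndefinedBoutLengthError(PasturewatchError, ValueError):
    """Positive rumination time recorded without any rumination bouts."""
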