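"""Exception hierarchy shared across the package."""


class PaleonetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PaleonetError):
    """A required column or field is missing from an input table."""


class InputDataError(PaleonetError):
    """Input data violate a precondition (empty table, empty selection, ...)."""


class ParameterError(PaleonetError):
    """An operation parameter is out of its valid range."""


class UndefinedMetricError(PaleonetError):
    """A statistic is mathematically undefined for the given input.

    Raised instead of silently returning 0 or NaN, e.g. for the degree
    assortativity of a regular graph (zero variance at link endpoints) or
    modularity of an edgeless network.
    """
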