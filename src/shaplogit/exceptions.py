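"""Exception hierarchy shared across the package."""


class ShaplogitError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ShaplogitError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(ShaplogitError, ValueError):
    """Column names, alignment, or file layout do not match expectations."""


class DegenerateOutcomeError(ShaplogitError, ValueError):
    """The outcome vector contains a single class where two are required."""


class CapabilityError(ShaplogitError, TypeError):
    """The model does not support the requested operation."""


class FeatureLimitError(ShaplogitError, ValueError):
    """Too many features for brute-force coalition enumeration."""


class IntegrityError(ShaplogitError, ValueError):
    """An internal consistency check failed (e.g. asymmetric tensor)."""


class UndefinedMetricError(ShaplogitError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class AUROC)."""


class StratificationError(ShaplogitError, ValueError):
    """Not enough members of a class to build the requested folds."""
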