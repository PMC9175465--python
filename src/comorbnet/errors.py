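"""Exception types shared across the package."""


class ComorbnetError(Exception):
    """Base class for package errors."""


class InvalidConfigError(ComorbnetError, ValueError):
    """A configuration value is out of its legal range."""


class InvalidPairError(ComorbnetError, ValueError):
    """A condition dyad is malformed (e.g. x == y)."""


class UndefinedMeasureError(ComorbnetError, ZeroDivisionError):
    """An association measure is undefined for this contingency table."""


class UndefinedDensityError(ComorbnetError, ValueError):
    """Density is undefined for networks with fewer than two nodes."""


class InvalidNetworkError(ComorbnetError, ValueError):
    """A network violates a precondition (missing attributes, bad weights)."""


class InvalidPartitionError(ComorbnetError, ValueError):
    """A partition does not cover the node set it is applied to."""


class UndefinedARIError(ComorbnetError, ValueError):
    """Adjusted Rand index is undefined on fewer than two nodes."""
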