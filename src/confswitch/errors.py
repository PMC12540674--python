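"""Exception hierarchy used across the toolkit."""


class ConfSwitchError(Exception):
    """Base class for all toolkit errors."""


class FormatError(ConfSwitchError):
    """A file does not conform to the expected dialect."""


class SchemaError(ConfSwitchError):
    """A table is missing required columns or fields."""


class SelectionError(ConfSwitchError):
    """An atom selection is empty or out of range."""


class DegeneracyError(ConfSwitchError):
    """Input is geometrically or statistically degenerate."""


class ParameterError(ConfSwitchError):
    """A parameter is outside its admissible range."""


class ProviderError(ConfSwitchError):
    """A pluggable provider failed to supply a required value."""


class ConvergenceError(ConfSwitchError):
    """An iterative estimator did not converge within its budget."""
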