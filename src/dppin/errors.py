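"""Exception hierarchy.

Two broad classes matter to callers: validation problems (bad arguments or
configuration, exit code 2 from the CLI) and data problems (inputs that parse
but cannot support the requested analysis, exit code 3).
"""


class DPPINError(Exception):
    """Base class for all package errors."""


class ValidationError(DPPINError):
    """Invalid argument, option or configuration value."""


class DataError(DPPINError):
    """Input data cannot support the requested operation."""


class DesignMismatchError(DataError):
    """Sample design references samples absent from the expression table."""


class EmptyInputError(DataError):
    """An input table or edge list is empty after parsing/filtering."""


class EmptyNetworkError(DataError):
    """No edges remain after induction/filtering."""


class MissingGroupError(DataError):
    """A required condition/time-point group has no samples."""


class InsufficientReplicatesError(DataError):
    """Too few replicates for a variance-based test."""


class DegenerateDesignError(DataError):
    """Too few samples to fit the association model."""
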