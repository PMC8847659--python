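"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors → 1, data validation → 2,
convergence / statistical failures → 3.
"""


class UbistratError(Exception):
    """Base class for package errors."""


class DataValidationError(UbistratError):
    """Malformed or out-of-contract input data."""


class ConvergenceError(UbistratError):
    """An iterative fit or a statistical procedure failed."""
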