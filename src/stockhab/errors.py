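"""Exception hierarchy.

``ValidationError`` marks bad user input (CLI exit code 1); everything else
that goes wrong at run time surfaces as ``ComputationError`` or a plain
exception (CLI exit code 2).
"""


class StockhabError(Exception):
    """Base class for all package errors."""


class ValidationError(StockhabError, ValueError):
    """Invalid input data, scenario, or configuration."""


class ComputationError(StockhabError, RuntimeError):
    """A well-formed request that cannot be computed (e.g. ASP = 0)."""
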