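"""Exception hierarchy.

Exit codes (used by the CLI) distinguish the three failure families:
validation of inputs/configs, fit failures, and numerical/integrator
failures.
"""


class TandemsiteError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(TandemsiteError):
    """Invalid parameters, malformed input files, or inconsistent designs."""

    exit_code = 2


class FitError(TandemsiteError):
    """Non-convergence or degenerate data in a regression."""

    exit_code = 3


class NumericalError(TandemsiteError):
    """Integrator failure, instability, or loss of conservation."""

    exit_code = 4
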