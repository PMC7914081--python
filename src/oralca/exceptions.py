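"""Exception hierarchy for oralca."""


class OralCAError(Exception):
    """Base class for all oralca errors."""


class ConfigurationError(OralCAError):
    """A configuration value is missing, malformed or infeasible."""


class DivergenceError(OralCAError):
    """Numerical integration blew up.

    Carries the step index at which the overflow guard tripped.
    """

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"integration diverged at step {step}")


class InsufficientDataError(OralCAError):
    """Not enough samples / species / occupied sites for the requested analysis."""


class DegenerateInputError(OralCAError):
    """Input is formally valid but carries no usable variation."""
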