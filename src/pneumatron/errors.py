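"""Exception taxonomy shared across the package.

Each CLI exit code maps onto one of these families: configuration
problems (exit 2), file/format problems (exit 3) and unreliable-plateau
results (exit 4).
"""


class PneumatronError(Exception):
    """Base class for all package errors."""


class ConfigError(PneumatronError):
    """Invalid or incomplete run configuration."""


class FormatError(PneumatronError):
    """A file does not conform to the expected dialect."""


class InsufficientDataError(PneumatronError):
    """Too few cycles / points for the requested computation."""


class FlaggedCycleError(PneumatronError):
    """A physical computation was requested on a flagged cycle."""


class DegenerateNormalizationError(PneumatronError):
    """PGD normalisation impossible because GDmax <= GDmin."""


class FitError(PneumatronError):
    """Nonlinear fit failed or violated the sign convention."""

    def __init__(self, message: str, initial_estimates=None):
        super().__init__(message)
        self.initial_estimates = initial_estimates


class PlateauWarning(UserWarning):
    """No terminal GDmax plateau: the experiment likely stopped too early."""
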