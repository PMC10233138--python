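"""Exception hierarchy shared across the toolkit."""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class FormatError(MRKitError):
    """A tabular input is malformed (e.g. a required column is missing)."""


class ValidationError(MRKitError):
    """A record violates a domain invariant; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class FixtureLookupError(MRKitError, KeyError):
    """Unknown packaged-fixture name."""


class CoverageError(MRKitError):
    """The LD matrix does not cover every SNP in the table."""


class EmptyInstrumentError(MRKitError):
    """Harmonization matched zero SNPs between exposure and outcome."""


class DegenerateInstrumentError(MRKitError):
    """A Wald ratio was requested for a SNP with zero exposure effect."""


class InsufficientInstrumentsError(MRKitError):
    """An estimator needs more SNPs than the instrument set provides."""


class ConvergenceError(MRKitError):
    """An iterative optimizer failed to converge; carries the gradient norm."""

    def __init__(self, message: str, grad_norm: float | None = None):
        self.grad_norm = grad_norm
        if grad_norm is not None:
            message = f"{message} (gradient norm {grad_norm:.3e})"
        super().__init__(message)


class ConfigError(MRKitError):
    """Invalid run or simulation configuration."""
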