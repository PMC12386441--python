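"""Exception hierarchy shared across the package."""


class EpibeslError(Exception):
    """Base class for all package errors."""


class FormatError(EpibeslError):
    """A file does not follow the expected dialect (missing columns, bad FASTA...)."""


class ValidationError(EpibeslError):
    """Input values violate a documented contract."""


class EmptyInputError(EpibeslError):
    """A reader received a file with no records."""


class SignalLookupError(EpibeslError):
    """A signal query addressed an unknown chromosome or ran past its end."""


class TransPairError(ValidationError):
    """Enhancer and promoter lie on different chromosomes; pairs must be cis."""


class ConfigError(EpibeslError):
    """Inconsistent run configuration (mismatched k, missing track...)."""


class ModelStateError(EpibeslError):
    """An operation requires a fitted/trained model that is not available."""


class DivergenceError(EpibeslError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class UndefinedMetricError(EpibeslError):
    """A metric is undefined for the given label composition."""
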