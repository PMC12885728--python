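"""Exception hierarchy shared across the pipeline stages."""


class MirMRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MirMRError):
    """A config file, column mapping, or parameter set is invalid."""


class EmptyInputError(MirMRError):
    """An input table yielded zero usable records."""


class DomainError(MirMRError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class AlignmentError(MirMRError):
    """Two per-SNP vectors that must be aligned have different lengths."""


class InsufficientInstrumentsError(MirMRError):
    """Too few SNPs survive for the requested estimator."""

    def __init__(self, needed: int, got: int, what: str = "estimator"):
        self.needed, self.got = needed, got
        super().__init__(f"{what} requires >= {needed} SNPs, got {got}")


class DegenerateInstrumentError(MirMRError):
    """An instrument has a zero exposure effect, so its Wald ratio is undefined."""
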