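"""Exception hierarchy shared across the package."""


class MRColocError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRColocError, ValueError):
    """A run configuration or input file header is invalid."""


class FormatError(MRColocError, ValueError):
    """An input file violates the expected on-disk format."""


class EmptyOverlapError(MRColocError, ValueError):
    """No variant is shared between the supplied tables."""


class MissingVariantsError(MRColocError, KeyError):
    """Variants required by an operation are absent from an input."""

    def __init__(self, variant_ids, where=""):
        self.variant_ids = list(variant_ids)
        msg = f"variants missing from {where or 'input'}: {', '.join(self.variant_ids)}"
        super().__init__(msg)


class MissingEAFError(MRColocError, ValueError):
    """A diagnostic needs an effect-allele frequency that was not reported."""


class InsufficientInstrumentsError(MRColocError, ValueError):
    """Too few instruments for the requested estimator."""
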