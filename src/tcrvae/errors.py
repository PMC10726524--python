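"""Exception hierarchy."""


class TcrVaeError(Exception):
    """Base class for all package errors."""


class FormatError(TcrVaeError):
    """Malformed input file (e.g. a required column is missing)."""


class EmptyInputError(TcrVaeError):
    """An input that must contain records is empty."""


class PairingError(TcrVaeError):
    """No barcode is shared between the RNA and TCR modalities."""


class AlphabetError(TcrVaeError):
    """A CDR3 sequence contains a letter outside the 20-residue alphabet."""


class LengthError(TcrVaeError):
    """A CDR3 sequence exceeds the configured maximum length."""


class VocabularyError(TcrVaeError):
    """A V or J gene label is absent from the training vocabulary."""


class ConfigError(TcrVaeError):
    """Inconsistent architecture/shape configuration."""


class MetricError(TcrVaeError):
    """A metric's preconditions are not met (e.g. a single label)."""


class NoFeasiblePointError(TcrVaeError):
    """Grid search found no candidate satisfying both constraints."""

    def __init__(self, message: str, table=None):
        super().__init__(message)
        self.table = table
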