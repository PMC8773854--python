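"""Exception types shared across the package."""


class MBEEGError(Exception):
    """Base class for all package errors."""


class ValidationError(MBEEGError, ValueError):
    """An input violates a documented invariant (bad shape, label, value...)."""


class FormatError(MBEEGError, IOError):
    """An on-disk artifact does not conform to the expected layout."""


class SpecError(MBEEGError, ValueError):
    """A model specification cannot be compiled into a network."""


class TrainingError(MBEEGError, RuntimeError):
    """Training failed (non-finite loss, ...)."""


class EpochWindowError(MBEEGError, IndexError):
    """An epoch window falls outside the recording bounds."""
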