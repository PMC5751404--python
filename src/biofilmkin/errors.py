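"""Exception types shared across the package."""


class BiofilmkinError(Exception):
    """Base class for package errors."""


class ConfigurationError(BiofilmkinError):
    """A model specification or config document is internally inconsistent."""


class FitError(BiofilmkinError):
    """An estimation routine failed to produce a usable fit."""


class ParseError(BiofilmkinError):
    """An input file could not be parsed."""


class SolverError(BiofilmkinError):
    """Numerical integration failed; carries the last accepted time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time
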