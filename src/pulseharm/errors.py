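"""Exception types shared across the pipeline stages."""


class PulseharmError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(PulseharmError, ValueError):
    """A configuration field failed validation; the message names the field."""


class WaveformParseError(PulseharmError, ValueError):
    """A waveform file could not be parsed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class InsufficientBeatsError(PulseharmError, ValueError):
    """Fewer accepted beats than the minimum required for summarization."""


class SeparationError(PulseharmError, RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


class SingularDesignError(PulseharmError, ValueError):
    """Rank-deficient design matrix; carries the collinear column names."""

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        super().__init__(f"singular design matrix; collinear columns: {self.columns}")
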