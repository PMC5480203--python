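"""Exception hierarchy for vsperf."""


class VsperfError(Exception):
    """Base class for all vsperf errors."""


class InvalidInputError(VsperfError, ValueError):
    """Raised when an argument violates a documented precondition."""


class InfeasibleDesignError(VsperfError, RuntimeError):
    """Raised when no gradient waveform satisfies the hardware limits."""


class FitError(VsperfError, RuntimeError):
    """Raised for unrecoverable failures of a least-squares fit."""


class FormatError(VsperfError, IOError):
    """Raised for malformed input files (image headers, configs)."""


class ConfigError(VsperfError, ValueError):
    """Raised when a run configuration fails schema validation."""
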