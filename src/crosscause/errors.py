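"""Exception hierarchy for crosscause."""


class CrossCauseError(Exception):
    """Base class for all package-specific errors."""


class SimulationError(CrossCauseError):
    """A simulated trajectory diverged or could not be generated."""


class ConfigError(CrossCauseError):
    """An experiment configuration failed validation."""


class DataError(CrossCauseError):
    """Input series violate a method precondition (constant channel,
    too short for the requested embedding, missing/non-numeric cells, ...)."""
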