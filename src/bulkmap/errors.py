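"""Exception hierarchy for bulkmap."""


class BulkmapError(Exception):
    """Base class for all bulkmap errors."""


class ConfigError(BulkmapError):
    """Invalid simulation or run configuration."""


class ParseError(BulkmapError):
    """Malformed input file; carries file position context in the message."""


class SamplingError(BulkmapError):
    """A requested random sample cannot be drawn (e.g. bulk larger than class)."""


class UndefinedValueError(BulkmapError):
    """A statistic is undefined for the given input (e.g. zero pool depth)."""


class ConflictError(BulkmapError):
    """Fine-mapping consistency sets have an empty intersection."""

    def __init__(self, message, individuals=()):
        super().__init__(message)
        self.individuals = list(individuals)


class StageError(BulkmapError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
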