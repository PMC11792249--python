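"""Exception hierarchy for the twinsteroid pipeline."""


class TwinsteroidError(Exception):
    """Base class for all package errors."""


class ConfigError(TwinsteroidError, ValueError):
    """Invalid configuration value; message names the offending field."""


class DomainError(TwinsteroidError, ValueError):
    """Input outside the mathematical domain of an operation."""


class InsufficientDataError(TwinsteroidError, ValueError):
    """Too few observations to compute the requested statistic."""


class ParseError(TwinsteroidError, ValueError):
    """Malformed input file; message carries the 1-based line number."""


class UndefinedStatisticError(TwinsteroidError, ValueError):
    """Statistic undefined for this input (e.g. zero co-called SNPs)."""


class PipelineStageError(TwinsteroidError, RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""
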