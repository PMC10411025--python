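"""Exception hierarchy for rarelens."""


class RarelensError(Exception):
    """Base class for all package errors."""


class ConfigError(RarelensError, ValueError):
    """Invalid configuration; the message names the offending field."""


class ValidationError(RarelensError, ValueError):
    """Invalid input data (lexicon, tables, domains)."""


class ComputationError(RarelensError, RuntimeError):
    """A well-formed input on which the requested quantity is undefined."""


class FitError(RarelensError, RuntimeError):
    """Model fitting failed (e.g. rank-deficient design)."""


class PipelineError(RarelensError, RuntimeError):
    """An end-to-end run failed; the message names the stage."""
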