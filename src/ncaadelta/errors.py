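"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: configuration problems exit 2,
malformed or inconsistent data exit 3, anything else exits 1.
"""


class PipelineError(Exception):
    """Base class for all ncaadelta errors."""

    exit_code = 1


class ConfigurationError(PipelineError):
    """Invalid configuration value (bad range, nonpositive count, ...)."""

    exit_code = 2


class GenerationError(PipelineError):
    """The synthetic generator cannot satisfy a request (e.g. no site with
    the target residue exists in the proteome)."""

    exit_code = 3


class FormatError(PipelineError):
    """A table is structurally unusable: missing required column, etc."""

    exit_code = 3


class DataError(PipelineError):
    """Semantically invalid data inside a structurally valid table."""

    exit_code = 3
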