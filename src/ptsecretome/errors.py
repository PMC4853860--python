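"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the command line interface:
configuration errors -> 2, input parse errors -> 3, stage failures -> 4.
"""


class PipelineError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 4


class ConfigurationError(PipelineError):
    """Invalid parameters, design tables, or run configuration."""

    exit_code = 2


class ParseError(PipelineError):
    """Malformed input file; message names the offending file/line."""

    exit_code = 3
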