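"""Exception hierarchy for the feedmark pipeline.

Errors are grouped so the CLI can map them to distinct exit codes:
input-format problems (bad files), configuration problems (bad
parameters), and analysis problems (valid inputs that cannot be
processed, e.g. a degenerate feeding mark).
"""


class FeedmarkError(Exception):
    """Base class for all feedmark errors."""


class InputFormatError(FeedmarkError):
    """An input file or directory does not match the expected format."""


class ConfigError(FeedmarkError):
    """A parameter or threshold specification is invalid or inconsistent."""


class AnalysisError(FeedmarkError):
    """Valid inputs could not be analysed (insufficient data, etc.)."""


class UnsupportedROIError(InputFormatError):
    """An ImageJ ROI record is not a plain rectangle."""


class ScriptValidationError(ConfigError):
    """A synthetic behavior script is internally inconsistent."""


class DegenerateMarkError(AnalysisError):
    """A feeding event produced an empty mark mask."""
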