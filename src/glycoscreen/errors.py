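"""Exception hierarchy shared across the package.

Every error raised by glycoscreen derives from :class:`GlycoscreenError`, so
callers (and the CLI) can map error classes to exit codes without matching on
message text.
"""


class GlycoscreenError(Exception):
    """Base class for all glycoscreen errors."""


class InputError(GlycoscreenError):
    """A required input file is missing or cannot be parsed."""


class FastaParseError(InputError):
    """A FASTA record has a malformed header or an invalid sequence."""


class IntegrityError(GlycoscreenError):
    """Internal consistency violated (duplicate ids, mismatched intervals...)."""


class BoundsError(GlycoscreenError):
    """An interval lies outside its transcript or is degenerate."""


class BelowDetectionError(GlycoscreenError):
    """A blot spot signal is at or below the detection floor."""


class InsufficientControlsError(GlycoscreenError):
    """Fewer than two control measurements for a probe."""


class DegenerateControlsError(GlycoscreenError):
    """Control measurements have zero variance; z-scores are undefined."""


class DegenerateVarianceError(GlycoscreenError):
    """Zero pooled variance with unequal means; the t statistic is undefined."""


class IncompleteDesignError(GlycoscreenError):
    """A fraction x condition cell is missing from a fractionation design."""


class ConfigError(GlycoscreenError):
    """Invalid simulation or pipeline configuration."""
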