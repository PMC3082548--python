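"""Exception hierarchy shared across the pipeline."""


class DyeSwapError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DyeSwapError):
    """A configuration value is outside its documented domain."""


class ParseError(DyeSwapError):
    """An input file violates its dialect or an invariant of its type."""


class PipelineError(DyeSwapError):
    """A stage cannot proceed (too few spots, degenerate statistic, ...)."""


class DegenerateStatisticError(PipelineError):
    """Zero denominator with a nonzero numerator in a test statistic."""
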