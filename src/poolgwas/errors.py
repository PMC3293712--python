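"""Exception hierarchy for the pooled-GWAS pipeline.

``FormatError`` and ``ValidationError`` signal bad user input (CLI exit
code 1); anything else that escapes a stage is a runtime failure (exit
code 2).
"""


class PoolGwasError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PoolGwasError):
    """A table is structurally malformed (e.g. a required column is missing)."""


class ValidationError(PoolGwasError):
    """A table parses but violates a content constraint (bad value, duplicate
    key, replicate unknown to the design, ...)."""


class DesignError(PoolGwasError):
    """The pool design cannot support the requested analysis (e.g. fewer than
    two pools in a group for the nested ANOVA)."""


class ConfigError(PoolGwasError):
    """Invalid pipeline or simulation configuration."""
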