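"""Exception hierarchy.

All package-level errors derive from :class:`MinpverseError` so callers (and
the CLI) can distinguish user-facing problems from genuine bugs.
"""


class MinpverseError(Exception):
    """Base class for all errors raised by minpverse."""


class ConfigurationError(MinpverseError):
    """A grid, generator, or study configuration is invalid."""


class DegenerateDataError(MinpverseError):
    """The data are too degenerate for the requested operation
    (e.g. dropping incomplete rows leaves too few surgeries)."""


class StrategyFailedError(MinpverseError):
    """A single analysis strategy could not produce a p-value.

    Carries a human-readable reason (constant coded exposure, perfect
    separation, non-convergence, ...). Grid-level execution converts this
    into a per-strategy failure flag rather than aborting the run.
    """


class AlignmentError(MinpverseError):
    """Two objects that must share strategy order/columns do not."""
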