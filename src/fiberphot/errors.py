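"""Exception hierarchy.

Every error the library raises derives from :class:`FiberphotError`, so
callers (and the CLI) can catch one type at stage boundaries.
"""


class FiberphotError(Exception):
    """Base class for all fiberphot errors."""


class ConfigError(FiberphotError, ValueError):
    """Invalid simulation or run configuration."""


class ValidationError(FiberphotError, ValueError):
    """A data container violated one of its invariants."""


class ResamplingError(FiberphotError, ValueError):
    """Requested resampling ratio is not achievable."""


class DegenerateRegressorError(FiberphotError, ValueError):
    """Isosbestic regressor has zero variance."""


class ParseError(FiberphotError, ValueError):
    """Malformed input file; the message names the offending line."""


class AnalysisError(FiberphotError, ValueError):
    """A contract of an analysis operation was violated."""
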