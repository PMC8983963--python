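"""Exception hierarchy.

All package errors derive from :class:`RoastairError` so callers can catch
one base class; each also derives from the closest builtin so idiomatic
``except ValueError`` style handling keeps working.
"""


class RoastairError(Exception):
    """Base class for all roastair errors."""


class InvalidParameterError(RoastairError, ValueError):
    """A physical parameter violates its domain (negative mass, GSD < 1, ...)."""


class DegenerateParameterError(RoastairError, ValueError):
    """Parameters hit a removable singularity of a model (e.g. k == N)."""


class InsufficientDataError(RoastairError, ValueError):
    """Too few observations for the requested estimate."""


class ScheduleError(RoastairError, ValueError):
    """A work schedule fails validation (durations, locations, sources)."""


class ParseError(RoastairError, ValueError):
    """A data file does not conform to the expected schema."""


class ConfigError(RoastairError, ValueError):
    """A configuration document is malformed or incomplete."""


class MonteCarloError(RoastairError, RuntimeError):
    """A Monte Carlo run failed (too many draw failures, bad spec)."""
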