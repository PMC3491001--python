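"""Exception hierarchy.

All domain errors derive from :class:`SmokesimError` so callers can catch the
package's failures in one clause; validation-type errors also derive from
``ValueError`` for idiomatic use.
"""


class SmokesimError(Exception):
    """Base class for all smokesim errors."""


class ValidationError(SmokesimError, ValueError):
    """An input violates a documented invariant (range, sum, sign)."""


class GridMismatchError(SmokesimError, ValueError):
    """Two age x gender structures do not share the same grid."""


class ConfigError(SmokesimError, ValueError):
    """A configuration file or policy schedule is malformed."""


class ScheduleError(ConfigError):
    """A policy schedule does not cover the simulated period or uses an
    unknown level label."""


class InternalError(SmokesimError):
    """An internal consistency check failed (e.g. a negative compartment
    count), indicating invalid rates rather than bad user input."""
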