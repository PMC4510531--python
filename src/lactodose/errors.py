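"""Exception hierarchy.

Configuration problems (bad inputs, missing parameters, malformed files) and
numerical problems (solver instability, ill-conditioned inversions) are kept
on separate branches so the command-line layer can map them to distinct exit
codes (2 and 3 respectively).
"""

from __future__ import annotations


class LactodoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LactodoseError):
    """Invalid configuration: unknown compartment, missing parameter, bad value."""


class ValidationError(ConfigurationError):
    """A domain object failed its invariant checks."""


class ParseError(ConfigurationError):
    """A data file could not be parsed; message carries the offending line."""


class NumericalError(LactodoseError):
    """Numerical failure during integration or inversion."""


class StabilityError(NumericalError):
    """Fixed integration step too large for the fastest transfer in the model."""


class RangeError(LactodoseError):
    """A time or window falls outside the span of the available data."""


class InversionError(NumericalError):
    """Bioassay-to-intake inversion is ill-conditioned."""
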