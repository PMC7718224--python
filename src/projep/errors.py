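"""Exceptions and warnings shared across the package."""


class ProjepError(Exception):
    """Base class for package errors."""


class ConfigurationError(ProjepError):
    """A required physical parameter is missing or inconsistent."""


class NoSolutionError(ProjepError):
    """A root-finding problem has no solution in the admissible bracket."""


class StabilityError(ProjepError):
    """The numerical solver produced a physically inadmissible state."""


class ExtrapolationWarning(UserWarning):
    """A calibrated model is being evaluated outside its calibration support."""
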