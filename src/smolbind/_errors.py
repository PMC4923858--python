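"""Exception hierarchy.

``SmolbindUserError`` subclasses signal problems with user input (bad
configuration, malformed files, infeasible requests) and map to CLI exit
code 1; anything else escaping the pipeline maps to exit code 2.
"""


class SmolbindError(Exception):
    """Base class for all package errors."""


class SmolbindUserError(SmolbindError):
    """Error attributable to user input (config, files, parameters)."""


class ConfigError(SmolbindUserError):
    """Invalid or inconsistent configuration."""


class PlacementError(SmolbindUserError):
    """Requested spot layout infeasible at the required separation."""


class DetectionError(SmolbindUserError):
    """Spot detection cannot run on the given stack."""


class BoundsError(SmolbindUserError):
    """Requested image region lies outside the stack."""


class ParseError(SmolbindUserError):
    """Malformed force-curve file or manifest."""


class CorrectionError(SmolbindError):
    """Baseline correction failed (degenerate fit)."""


class StateError(SmolbindError):
    """Operation called on data in the wrong state (e.g. uncorrected curve)."""


class FitError(SmolbindError):
    """Model fit failed or the input is degenerate for fitting."""


class InputError(SmolbindUserError):
    """Input data violates an operation's preconditions."""


class StatisticsError(SmolbindUserError):
    """Insufficient replication or groups for the requested test."""
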