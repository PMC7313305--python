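"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 1 (usage/configuration problems),
``DataError`` to exit code 2 (malformed or inconsistent data).
"""


class VitalwatchError(Exception):
    """Base class for all package errors."""


class ConfigError(VitalwatchError):
    """Invalid configuration, parameters, or rule definitions."""


class DataError(VitalwatchError):
    """Malformed input data or referential-integrity violations."""


class UnknownReferenceError(DataError):
    """A cross-reference (patient, sign, rule, observation) does not resolve."""


class DuplicateError(DataError):
    """An identifier that must be unique is already present."""


class NominalValueError(DataError):
    """A numeric operation was applied to a nominal-valued vital sign."""
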