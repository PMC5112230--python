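"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (usage 2, schema 3, insufficient data 4).
"""


class SVVDriftError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SVVDriftError, ValueError):
    """A numeric argument violates an operation's precondition."""


class ConfigurationError(SVVDriftError, ValueError):
    """A schedule/protocol/config object is internally inconsistent."""


class SchemaError(SVVDriftError, ValueError):
    """A CSV/JSON input does not match the documented schema."""


class InsufficientDataError(SVVDriftError, ValueError):
    """Too few trials/points/subjects for the requested estimate."""


class AlignmentError(SVVDriftError, ValueError):
    """Trial log and torsion trace do not cover compatible time spans."""
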