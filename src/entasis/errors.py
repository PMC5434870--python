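"""Exception hierarchy.

Every error raised by the package derives from :class:`EntasisError` so
callers can catch pipeline failures with a single except clause while the
subclasses keep the failure mode identifiable.
"""


class EntasisError(Exception):
    """Base class for all package errors."""


class ParseError(EntasisError):
    """Malformed input text (PDB, XYZ or table); message names the line/row."""


class EmptyInputError(EntasisError):
    """Input contained no usable records."""


class OrderingError(EntasisError):
    """Timestamps not strictly increasing."""


class SchemaError(EntasisError):
    """Heterogeneous or incomplete tabular records."""


class SelectionError(EntasisError):
    """Syntactically invalid atom-selection specification."""


class LookupError_(EntasisError):
    """An atom reference did not resolve to a unique atom."""


class DegenerateGeometryError(EntasisError):
    """Coincident or collinear atoms where the operation needs shape."""


class TrajectoryError(EntasisError):
    """Frames with inconsistent atom sets, or bad frame/time bookkeeping."""


class StateLabelError(EntasisError):
    """Oxidized/reduced labels missing, swapped or duplicated."""


class EmptyWindowError(EntasisError):
    """All frames fell before the equilibration cutoff."""


class UndefinedCorrelationError(EntasisError):
    """Pearson r requested on a constant series."""


class DomainError(EntasisError):
    """Physical-parameter domain violation (e.g. lambda <= 0, T <= 0)."""


class DimensionError(EntasisError):
    """Vector length does not match the model dimension."""


class ConfigError(EntasisError):
    """Pipeline configuration schema violation; message carries the field path."""
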