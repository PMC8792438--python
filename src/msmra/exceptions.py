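"""Error types raised by the msmra pipeline.

Each error maps to a distinct nonzero exit code on the command line
(see :mod:`msmra.cli`).
"""


class MsmraError(Exception):
    """Base class for all package-specific errors."""


class InvalidBandError(MsmraError):
    """A frequency band is malformed or exceeds the Nyquist limit."""


class TooShortError(MsmraError):
    """A signal is shorter than the filter warm-up requires."""


class DegenerateWindowError(MsmraError):
    """A window has zero sample variance; differential entropy diverges."""


class EmptyInputError(MsmraError):
    """An operation received no usable data (zero trials, empty domain list)."""


class AlreadyNormalizedError(MsmraError):
    """normalize_features called on an already-normalized tensor."""


class UnpairableError(MsmraError):
    """An odd number of source recordings cannot be grouped in pairs."""


class OverlapError(MsmraError):
    """The target recording also appears among the sources."""


class IncompleteGridError(MsmraError):
    """The subject x session grid has missing cells."""


class ShapeError(MsmraError):
    """Array dimensions do not match the declared contract."""


class InsufficientBatchError(MsmraError):
    """A kernel two-sample estimate needs at least two points per side."""


class RepresentationCountError(MsmraError):
    """Source and target provide different numbers of representations."""


class DomainCountError(MsmraError):
    """Per-domain lists disagree on the number of source domains."""


class InvalidConfigError(MsmraError):
    """A configuration value violates its invariant."""


class NotTrainedError(MsmraError):
    """Prediction requested from a model that has not been fitted."""


class MissingLabelsError(MsmraError):
    """A source domain lacks the labels the supervised loss requires."""


class DialectError(MsmraError):
    """Unknown feature-container dialect."""


class LayoutError(MsmraError):
    """Stored feature width disagrees with channels x bands."""


class ParseError(MsmraError):
    """A container file is truncated or otherwise unreadable."""
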