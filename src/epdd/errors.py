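"""Exception and warning types shared across the package."""


class EpddError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EpddError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InputError(EpddError, ValueError):
    """A curve or table fails a structural precondition (too few points, empty grid, ...)."""


class ParseError(EpddError, ValueError):
    """A CSV file or stream could not be parsed into a depth-dose curve."""


class NormalizationError(EpddError, ValueError):
    """A raw model curve is identically zero and cannot be scaled to max 100."""


class NotFoundError(EpddError, ValueError):
    """A requested feature (dose-level crossing, plateau, ...) does not exist on the curve."""


class SingularFitError(EpddError, ValueError):
    """A regression design matrix is singular (e.g. all energies identical)."""


class InconsistencyWarning(UserWarning):
    """Emitted when evaluating a published relation known to disagree with the
    measured values it claims to describe."""
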