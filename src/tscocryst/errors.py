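"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`TscocrystError`,
so callers (and the CLI) can catch one base class.
"""


class TscocrystError(ValueError):
    """Base class for all package errors."""


# --- spectra ---------------------------------------------------------------

class DegenerateSpectrum(TscocrystError):
    """Normalization of a constant spectrum (max == min) is undefined."""


class CoverageError(TscocrystError):
    """Resampling target grid extends beyond the measured wavenumber span."""


class EmptyRange(TscocrystError):
    """Range restriction left fewer than two grid points."""


class ConfigError(TscocrystError):
    """Invalid fingerprint-library configuration."""


class UnknownComponent(TscocrystError):
    """Coefficient refers to a name absent from the basis library."""


# --- unmix -----------------------------------------------------------------

class GridMismatch(TscocrystError):
    """Spectra do not share a common wavenumber grid."""


class ShapeError(TscocrystError):
    """Vector/matrix dimensions are inconsistent."""


class ZeroDenominator(TscocrystError):
    """Fingerprint linear coefficients sum to (numerically) zero."""


# --- design space / controller --------------------------------------------

class DomainError(TscocrystError):
    """Physical parameter outside its admissible domain."""


class EmptyInput(TscocrystError):
    """No estimates supplied."""


class BinningError(TscocrystError):
    """Requested binning cannot produce a usable design space."""


class OutOfBounds(TscocrystError):
    """Query point outside the design-space axes."""


class UnknownFingerprint(TscocrystError):
    """Target fingerprint absent from the design space."""


class EmptySpace(TscocrystError):
    """Design space has no occupied cell."""


# --- coexistence -----------------------------------------------------------

class MissingDescriptor(TscocrystError):
    """Descriptor lacks the field required by the chosen chi route."""


# --- rheology --------------------------------------------------------------

class InsufficientData(TscocrystError):
    """Too few data points for the requested fit."""


class MissingReference(TscocrystError):
    """Reference temperature T0 required but not set."""
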