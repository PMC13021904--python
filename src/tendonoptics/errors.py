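"""Exception hierarchy for tendonoptics."""


class TendonOpticsError(Exception):
    """Base class for all package-specific errors."""


class DomainError(TendonOpticsError, ValueError):
    """A physical parameter is outside its valid domain (e.g. |g| >= 1)."""


class DegenerateScanError(TendonOpticsError, ValueError):
    """An angular scan carries no usable angular structure (all-zero or
    flat/stray-light-only intensities)."""


class FitFailureError(TendonOpticsError, RuntimeError):
    """Optimization failed to converge. Carries the best candidate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class LUTCoverageError(TendonOpticsError, ValueError):
    """A (mua, musp) query falls outside the lookup-table grid.

    ``wavelength_nm`` names the offending wavelength when known, so the
    caller can rebuild the table on an extended grid.
    """

    def __init__(self, message, wavelength_nm=None):
        super().__init__(message)
        self.wavelength_nm = wavelength_nm


class ParseError(TendonOpticsError, ValueError):
    """A CSV/config input could not be parsed; message names the line."""


class GeometryMismatchError(TendonOpticsError, ValueError):
    """Two artifacts that must share geometry (thickness, volume) do not."""
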