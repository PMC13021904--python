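"""Recover tissue optical coefficients from integrating-sphere spectra.

The forward model for a slab of tendon of known thickness is

    mua(lambda)  = Wt * mua_water(lambda)            (water-scaled absorption)
    mus'(lambda) = a * (lambda / 500 nm)^(-b)        (scattering power law)

with Wt the water volume fraction (bounded above by 0.65, consistent with
~62% water in native tendon), ``a`` the reduced scattering at the 500-nm
reference wavelength [mm^-1] and ``b`` the scattering power.  Measured Rd
and Tt underestimate the true fractions because of port-edge losses, so the
*data* are scaled by a single factor K before comparison with the
Monte-Carlo lookup-table prediction; the bounded trust-region-reflective
least squares

    min over (Wt, a, b, K) of
        sum_lambda (K*Rd_meas - Rd_lut)^2 + (K*Tt_meas - Tt_lut)^2

recovers all four parameters.  Applying one K to both channels assumes both
are underestimated in equal proportion, which is an approximation (lateral
loss affects transmission more); it is kept because it is the standard
single-port-sphere correction, and is flagged in the docs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, GeometryMismatchError, LUTCoverageError
from .transport import LUT
from .water import WATER_KNOTS

__all__ = [
    "SpectrumMeasurement",
    "WaterAbsorptionTable",
    "ScatterModelFit",
    "DerivedScattering",
    "default_water_table",
    "water_mua",
    "mua_model",
    "musp_model",
    "predict_rd_tt",
    "invert_spectra",
    "derived_scattering",
]

REFERENCE_WAVELENGTH_NM = 500.0

#: optimizer bounds: Wt in [0, 0.65], a in (0, 100], b in [0, 6], K in [0.5, 2]
DEFAULT_BOUNDS = ((0.0, 1e-6, 0.0, 0.5), (0.65, 100.0, 6.0, 2.0))
DEFAULT_INIT = (0.65, 1.0, 1.5, 1.2)


@dataclass(frozen=True)
class SpectrumMeasurement:
    """Rd/Tt spectra of one sample group on an ascending wavelength grid."""

    wavelength_nm: np.ndarray
    rd: np.ndarray
    tt: np.ndarray
    thickness_mm: float
    orientation: str | None = None
    condition: str | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        rd = np.asarray(self.rd, dtype=float)
        tt = np.asarray(self.tt, dtype=float)
        if wl.ndim != 1 or wl.shape != rd.shape or wl.shape != tt.shape:
            raise ValueError("wavelength, Rd, Tt must be 1-D and equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if wl.min() < 250.0 or wl.max() > 2500.0:
            raise ValueError("wavelengths must lie within [250, 2500] nm")
        if np.any(rd < 0) or np.any(tt < 0):
            raise ValueError("Rd and Tt must be >= 0")
        if np.any(rd > 1.1) or np.any(tt > 1.1):
            raise ValueError("raw Rd/Tt above 1.1: not a physical fraction")
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be > 0")
        for a in (wl, rd, tt):
            a.setflags(write=False)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "rd", rd)
        object.__setattr__(self, "tt", tt)


@dataclass(frozen=True)
class WaterAbsorptionTable:
    """Knot table of pure-water absorption [mm^-1] vs wavelength [nm]."""

    wavelength_nm: np.ndarray
    mua_mm: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        mua = np.asarray(self.mua_mm, dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise ValueError("water-table wavelengths must be ascending")
        if np.any(mua <= 0):
            raise ValueError("water-table absorption values must be positive")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "mua_mm", mua)


def default_water_table() -> WaterAbsorptionTable:
    return WaterAbsorptionTable(WATER_KNOTS[:, 0], WATER_KNOTS[:, 1])


def water_mua(wavelength_nm, table: WaterAbsorptionTable | None = None):
    """Pure-water absorption [mm^-1] by log-linear interpolation of the table."""
    table = table or default_water_table()
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl < table.wavelength_nm[0]) or np.any(wl > table.wavelength_nm[-1]):
        raise DomainError(
            f"wavelength outside water-table coverage "
            f"[{table.wavelength_nm[0]:g}, {table.wavelength_nm[-1]:g}] nm"
        )
    out = np.exp(np.interp(wl, table.wavelength_nm, np.log(table.mua_mm)))
    return float(out) if np.isscalar(wavelength_nm) else out


def mua_model(wavelength_nm, wt: float, table: WaterAbsorptionTable | None = None):
    """Water-scaled tissue absorption mua = Wt * mua_water(lambda) [mm^-1]."""
    if not 0.0 <= wt <= 1.0:
        raise DomainError("water content Wt must lie in [0, 1]")
    if wt == 0.0:
        wl = np.asarray(wavelength_nm, dtype=float)
        return 0.0 if np.isscalar(wavelength_nm) else np.zeros_like(wl)
    return wt * water_mua(wavelength_nm, table)


def musp_model(wavelength_nm, a: float, b: float):
    """Reduced-scattering power law mus'(lambda) = a * (lambda/500)^(-b)."""
    if a <= 0:
        raise DomainError("scattering amplitude a must be > 0")
    wl = np.asarray(wavelength_nm, dtype=float)
    out = a * (wl / REFERENCE_WAVELENGTH_NM) ** (-b)
    return float(out) if np.isscalar(wavelength_nm) else out


@dataclass(frozen=True)
class ScatterModelFit:
    """Recovered (Wt, a, b, K) with per-wavelength coefficient spectra."""

    wt: float
    a: float
    b: float
    k: float
    residual: float
    wavelength_nm: np.ndarray
    mua: np.ndarray
    musp: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.wt <= 0.65 + 1e-9:
            raise ValueError("Wt must lie in [0, 0.65]")
        if self.a <= 0 or self.b < 0 or self.k <= 0:
            raise ValueError("require a > 0, b >= 0, K > 0")


@dataclass(frozen=True)
class DerivedScattering:
    """mus = mus'/(1-g) [mm^-1] and mean free path mfp = 1/mus [mm]."""

    mus: float
    mfp: float


def derived_scattering(musp: float, g: float) -> DerivedScattering:
    """Unlump the reduced scattering: mus = mus'/(1-g), mfp = 1/mus."""
    if not 0.0 <= g < 1.0:
        raise DomainError("anisotropy g must lie in [0, 1) here")
    if musp <= 0:
        raise DomainError("musp must be > 0")
    mus = musp / (1.0 - g)
    return DerivedScattering(mus=mus, mfp=1.0 / mus)


def predict_rd_tt(wavelength_nm, wt: float, a: float, b: float, lut: LUT,
                  table: WaterAbsorptionTable | None = None):
    """Model (Rd, Tt) spectra: power-law/water coefficients looked up in the
    LUT by bilinear interpolation.  Raises LUTCoverageError naming the first
    offending wavelength if a query leaves the grid."""
    wl = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
    mua = np.atleast_1d(mua_model(wl, wt, table))
    musp = np.atleast_1d(musp_model(wl, a, b))
    ok = lut.covers(mua, musp)
    if not np.all(ok):
        i = int(np.argmin(ok))
        raise LUTCoverageError(
            f"model query at {wl[i]:g} nm (mua={mua[i]:.4g}, musp={musp[i]:.4g} "
            "mm^-1) falls outside the LUT grid; extend the grid",
            wavelength_nm=float(wl[i]),
        )
    return lut.lookup(mua, musp)


def _clipped_lookup(lut: LUT, mua, musp):
    """LUT lookup with queries clipped to the grid (optimizer-internal only)."""
    mua = np.clip(mua, lut.mua_grid[0], lut.mua_grid[-1])
    musp = np.clip(musp, lut.musp_grid[0], lut.musp_grid[-1])
    return lut.lookup(mua, musp)


def invert_spectra(meas: SpectrumMeasurement, lut: LUT,
                   bounds=DEFAULT_BOUNDS, init=DEFAULT_INIT,
                   table: WaterAbsorptionTable | None = None,
                   n_starts: int = 4) -> ScatterModelFit:
    """Fit (Wt, a, b, K) to measured Rd/Tt spectra against LUT predictions.

    Multistart bounded least squares (trust-region reflective): the base
    initialization plus ``n_starts - 1`` perturbations of (a, b).  The LUT
    thickness must match the measurement thickness.
    """
    if meas.wavelength_nm.size < 10:
        raise ValueError("need at least 10 wavelengths to invert")
    if abs(lut.thickness_mm - meas.thickness_mm) > 1e-6:
        raise GeometryMismatchError(
            f"LUT thickness {lut.thickness_mm} mm != spectra thickness "
            f"{meas.thickness_mm} mm"
        )
    table = table or default_water_table()
    wl = meas.wavelength_nm
    mua_water_wl = water_mua(wl, table)

    def residuals(params):
        wt, a, b, k = params
        mua = wt * mua_water_wl
        musp = a * (wl / REFERENCE_WAVELENGTH_NM) ** (-b)
        rd_m, tt_m = _clipped_lookup(lut, mua, musp)
        return np.concatenate([k * meas.rd - rd_m, k * meas.tt - tt_m])

    lo = np.asarray(bounds[0], float)
    hi = np.asarray(bounds[1], float)
    base = np.clip(np.asarray(init, float), lo, hi)
    starts = [base]
    for fa, db in ((0.5, 0.5), (2.0, -0.5), (4.0, 1.0)):
        if len(starts) >= n_starts:
            break
        pert = base.copy()
        pert[1] = np.clip(base[1] * fa, lo[1], hi[1])
        pert[2] = np.clip(base[2] + db, lo[2], hi[2])
        starts.append(pert)

    best = None
    for x0 in starts:
        sol = least_squares(residuals, x0=x0, bounds=(lo, hi), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    wt, a, b, k = best.x
    # strict coverage check at the solution (clipping was optimizer-internal)
    predict_rd_tt(wl, wt, a, b, lut, table)
    return ScatterModelFit(
        wt=float(wt), a=float(a), b=float(b), k=float(k),
        residual=float(2 * best.cost),
        wavelength_nm=wl.copy(),
        mua=np.asarray(wt * mua_water_wl),
        musp=np.asarray(a * (wl / REFERENCE_WAVELENGTH_NM) ** (-b)),
    )
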