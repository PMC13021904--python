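"""Angular scattering: the two-lobe Henyey-Greenstein model and its inversion.

A goniometer records scattered power I(theta) over a limited polar range
(typically +/-50 deg).  Tendon scatters into a narrow near-axis lobe (large
collagen fibers) superposed on a broad lobe (fibrils and smaller structures),
so a single HG function underfits.  The model fitted here is

    p_fit(theta) = cos(theta) * (K1 * p_HG(theta, g1) + K2 * p_HG(theta, g2))

where the cosine accounts for the Lambertian pattern of flux escaping a
surface, and K1, K2 (a.u. * sr) scale the unit-normalized HG densities to the
detector's arbitrary units.  The single-scattering phase function is the
mixture p1 + p2 with the Lambertian factor removed, and the effective
anisotropy g_eff is its mean cosine over the full sphere.

Fitting minimizes the azimuthally weighted least-squares objective

    sum_theta [ w(theta) * (p_fit(theta) - I(theta)) ]^2,
    w(theta) = 2*pi*|sin(theta)|*dtheta,

so the on-axis sample (sin 0 = 0) carries zero weight -- deliberately, since
pinholes in 20-um sections can corrupt theta ~ 0.  Because the model is
linear in (K1, K2), each multistart solves the lobe scales by non-negative
linear least squares at fixed (g1, g2) (variable projection) before a bounded
trust-region polish of all four parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares, nnls

from .errors import DegenerateScanError, DomainError, FitFailureError

__all__ = [
    "AngularScan",
    "DoubleHGFit",
    "hg_phase",
    "double_hg_model",
    "phase_curve",
    "fit_double_hg",
    "fit_objective",
    "effective_anisotropy",
    "average_scans",
    "fold_scan",
]

logger = logging.getLogger(__name__)

_G_MAX = 0.9999


@dataclass(frozen=True)
class AngularScan:
    """A measured angular intensity profile.

    theta_deg : strictly increasing polar angles in degrees, within [-90, 90]
    intensity : detected power per angle, arbitrary units, finite and >= 0
                (negative detector-noise readings are clipped to 0 with a
                logged warning)
    """

    theta_deg: np.ndarray
    intensity: np.ndarray
    wavelength_nm: float = 633.0
    orientation: str | None = None
    condition: str | None = None

    def __post_init__(self):
        theta = np.asarray(self.theta_deg, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if theta.ndim != 1 or theta.shape != inten.shape:
            raise ValueError("theta_deg and intensity must be 1-D and equal length")
        if not np.all(np.isfinite(theta)) or not np.all(np.isfinite(inten)):
            raise ValueError("angles and intensities must be finite")
        if np.any(np.diff(theta) <= 0):
            raise ValueError("theta_deg must be strictly increasing")
        if theta.min() < -90.0 or theta.max() > 90.0:
            raise ValueError("theta_deg must lie within [-90, 90]")
        if np.any(inten < 0):
            n_neg = int(np.sum(inten < 0))
            logger.warning(
                "clipping %d negative intensity value(s) to 0 (detector noise floor)",
                n_neg,
            )
            inten = np.clip(inten, 0.0, None)
        theta.setflags(write=False)
        inten.setflags(write=False)
        object.__setattr__(self, "theta_deg", theta)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class DoubleHGFit:
    """Fitted two-lobe HG parameters and derived effective anisotropies.

    K1, K2 are lobe scale factors (a.u.*sr, >= 0); g1, g2 lie in (-1, 1) with
    the convention g1 >= g2 (lobe 1 is the narrow forward lobe).  g1_eff,
    g2_eff and g_eff are mean cosines of p1, p2 and p1+p2 over [0, pi];
    residual is the value of the weighted least-squares objective.
    """

    K1: float
    g1: float
    K2: float
    g2: float
    g1_eff: float = field(default=np.nan)
    g2_eff: float = field(default=np.nan)
    g_eff: float = field(default=np.nan)
    residual: float = field(default=np.nan)

    def __post_init__(self):
        for g in (self.g1, self.g2):
            if not -1.0 < g < 1.0:
                raise DomainError(f"anisotropy parameter {g} outside (-1, 1)")
        if self.K1 < 0 or self.K2 < 0:
            raise DomainError("lobe scales K1, K2 must be >= 0")


def hg_phase(theta, g):
    """Henyey-Greenstein phase function p_HG(theta; g), per steradian.

    Normalized so that  integral p_HG * 2*pi*sin(theta) dtheta over [0, pi]
    equals 1.  ``theta`` is in radians.
    """
    g = float(g)
    if not -1.0 < g < 1.0:
        raise DomainError(f"anisotropy g={g} outside (-1, 1)")
    theta = np.asarray(theta, dtype=float)
    return (1.0 - g * g) / (4.0 * np.pi * (1.0 + g * g - 2.0 * g * np.cos(theta)) ** 1.5)


def double_hg_model(theta, fit: DoubleHGFit):
    """Two-lobe model with the Lambertian escape factor.

    Returns cos(theta) * (K1*p_HG(theta,g1) + K2*p_HG(theta,g2)) for
    ``theta`` in radians.  Vanishes at theta = pi/2 by the cosine factor.
    """
    theta = np.asarray(theta, dtype=float)
    return np.cos(theta) * phase_curve(theta, fit)


def phase_curve(theta, fit: DoubleHGFit):
    """Single-scattering phase function p(theta) = p1 + p2 (Lambertian factor
    removed analytically), valid over the full [0, pi] range."""
    theta = np.asarray(theta, dtype=float)
    return fit.K1 * hg_phase(theta, fit.g1) + fit.K2 * hg_phase(theta, fit.g2)


def _hg_mean_cosine(g: float) -> float:
    """Mean cosine of a single HG lobe by adaptive quadrature in mu=cos."""

    def num(mu):
        return mu * 0.5 * (1 - g * g) / (1 + g * g - 2 * g * mu) ** 1.5

    val, _ = quad(num, -1.0, 1.0, limit=400, epsabs=1e-10, epsrel=1e-10)
    return val


def effective_anisotropy(fit: DoubleHGFit) -> tuple[float, float, float]:
    """Effective anisotropies (g1_eff, g2_eff, g_eff) of a fitted model.

    Each value is the mean cosine  <cos theta>  of the corresponding phase
    function integrated with the 2*pi*sin(theta) solid-angle weight over
    [0, pi]: g1_eff and g2_eff from the individual lobes, g_eff from the
    mixture p1 + p2.  Since each HG lobe is unit-normalized, g_eff equals the
    K-weighted mean of the lobe mean-cosines.
    """
    g1_eff = _hg_mean_cosine(fit.g1)
    g2_eff = _hg_mean_cosine(fit.g2)
    ktot = fit.K1 + fit.K2
    if ktot <= 0:
        raise DomainError("g_eff undefined for K1 = K2 = 0")
    g_eff = (fit.K1 * g1_eff + fit.K2 * g2_eff) / ktot
    return g1_eff, g2_eff, g_eff


def average_scans(scans: list[AngularScan]) -> AngularScan:
    """Average a replicate group of scans sharing a common angle grid."""
    if not scans:
        raise ValueError("no scans to average")
    theta = scans[0].theta_deg
    for s in scans[1:]:
        if s.theta_deg.shape != theta.shape or not np.allclose(s.theta_deg, theta):
            raise ValueError("scans in a replicate group must share the angle grid")
    mean = np.mean([s.intensity for s in scans], axis=0)
    return replace(scans[0], intensity=mean)


def fold_scan(scan: AngularScan) -> tuple[np.ndarray, np.ndarray, float]:
    """Fold signed angles onto [0, max|theta|] by averaging symmetric pairs.

    Returns (theta_deg >= 0 ascending, folded intensity, relative asymmetry).
    The asymmetry (mean |I(+t) - I(-t)| / mean I over paired angles) is
    logged: wide-angle stray light shows up as a left/right tail imbalance.
    """
    theta = scan.theta_deg
    inten = scan.intensity
    folded: dict[float, list[float]] = {}
    for t, i in zip(theta, inten):
        folded.setdefault(round(abs(t), 9), []).append(i)
    tgrid = np.array(sorted(folded))
    mean_i = np.array([np.mean(folded[t]) for t in tgrid])
    paired = [folded[t] for t in tgrid if len(folded[t]) == 2]
    if paired and np.mean([np.mean(p) for p in paired]) > 0:
        asym = float(
            np.mean([abs(p[0] - p[1]) for p in paired])
            / np.mean([np.mean(p) for p in paired])
        )
    else:
        asym = 0.0
    if asym > 0.05:
        logger.warning("left/right scan asymmetry %.1f%% (stray light?)", 100 * asym)
    return tgrid, mean_i, asym


def _weights(theta_deg: np.ndarray) -> np.ndarray:
    """Azimuthal weights w = 2*pi*|sin(theta)|*dtheta on a (near-)uniform grid."""
    theta = np.radians(theta_deg)
    dtheta = np.median(np.diff(theta)) if theta.size > 1 else 1.0
    return 2.0 * np.pi * np.abs(np.sin(theta)) * dtheta


def fit_objective(scan: AngularScan, fit: DoubleHGFit) -> float:
    """Weighted least-squares objective for a parameter set on a scan."""
    tgrid, data, _ = fold_scan(scan)
    w = _weights(tgrid)
    model = double_hg_model(np.radians(tgrid), fit)
    return float(np.sum((w * (model - data)) ** 2))


def _residuals(params, theta_rad, data, w):
    k1, g1, k2, g2 = params
    model = np.cos(theta_rad) * (k1 * hg_phase(theta_rad, min(g1, _G_MAX))
                                 + k2 * hg_phase(theta_rad, min(g2, _G_MAX)))
    return w * (model - data)


def _nnls_scales(g1, g2, theta_rad, data, w):
    """Optimal (K1, K2) >= 0 at fixed lobe shapes, plus the objective."""
    basis = np.column_stack(
        [
            w * np.cos(theta_rad) * hg_phase(theta_rad, g1),
            w * np.cos(theta_rad) * hg_phase(theta_rad, g2),
        ]
    )
    coef, rnorm = nnls(basis, w * data)
    return coef, rnorm**2


# Coarse (g1, g2) lattice for the multistart: narrow forward lobe x broad lobe.
_G1_STARTS = (0.80, 0.90, 0.95, 0.98)
_G2_STARTS = (0.20, 0.40, 0.60, 0.75)


def fit_double_hg(scan: AngularScan, n_polish: int = 3) -> DoubleHGFit:
    """Fit the two-lobe HG model to an angular scan.

    The scan must span at least 40 distinct angles covering both signs of
    theta.  Signed angles are folded (symmetric pairs averaged) before
    fitting.  Raises :class:`DegenerateScanError` for all-zero or flat
    (stray-light-only) scans and :class:`FitFailureError`, carrying the best
    candidate, if no multistart converges.
    """
    if scan.theta_deg.size < 40:
        raise ValueError("scan must cover at least 40 distinct angles")
    if scan.theta_deg.min() >= 0 or scan.theta_deg.max() <= 0:
        raise ValueError("scan must span both signs of theta")
    tgrid, data, _ = fold_scan(scan)
    peak = data.max()
    if peak <= 0:
        raise DegenerateScanError("all intensities are zero")
    if (peak - data.min()) / peak < 0.1:
        raise DegenerateScanError(
            "scan has no angular structure (flat within 10%); stray-light floor?"
        )
    theta_rad = np.radians(tgrid)
    w = _weights(tgrid)

    starts = []
    for g1 in _G1_STARTS:
        for g2 in _G2_STARTS:
            (k1, k2), obj = _nnls_scales(g1, g2, theta_rad, data, w)
            starts.append((obj, (k1, g1, k2, g2)))
    starts.sort(key=lambda s: s[0])

    best = None
    for _, x0 in starts[:n_polish]:
        try:
            sol = least_squares(
                _residuals,
                x0=np.array(x0),
                bounds=([0.0, 0.0, 0.0, 0.0], [np.inf, _G_MAX, np.inf, _G_MAX]),
                args=(theta_rad, data, w),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        obj = float(2 * sol.cost)
        # tie-break: lowest residual, then larger narrow-lobe g1
        key = (round(obj, 14), -max(sol.x[1], sol.x[3]))
        if best is None or key < best[0]:
            best = (key, sol.x, obj, sol.success)
    if best is None:
        raise FitFailureError("all multistarts failed", best=starts[0][1])
    _, x, obj, success = best
    k1, g1, k2, g2 = x
    if g2 > g1:  # lobe-ordering convention: lobe 1 is the forward lobe
        k1, g1, k2, g2 = k2, g2, k1, g1
    fit = DoubleHGFit(K1=float(k1), g1=float(g1), K2=float(k2), g2=float(g2),
                      residual=obj)
    if not success:
        raise FitFailureError("optimizer did not report convergence", best=fit)
    g1_eff, g2_eff, g_eff = effective_anisotropy(fit)
    return replace(fit, g1_eff=g1_eff, g2_eff=g2_eff, g_eff=g_eff)
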