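"""Instrument-realistic synthetic data with known ground truth.

Two generators emulate the two instruments of the measurement chain:

* :func:`gen_goniometer_scan` draws angular scans from a known two-lobe HG
  truth, with multiplicative detector noise (default 2% relative s.d.) and
  an additive stray-light floor (default 0.2% of the on-axis peak) -- of the
  order seen as shot-to-shot variability and wide-angle offsets on real
  goniometer data;
* :func:`gen_spectra` composes the water/power-law coefficient models with
  the forward slab Monte Carlo, divides both channels by a loss factor
  K_true (mimicking sphere port losses that make measured Rd + Tt fall short
  of unity), and adds relative detector noise (default 1%).

All generators are pure functions of (truth, seed).  The bundled presets
encode saline-soaked tendon conditions: lobe anisotropies 0.90/0.57 with
scale ratio 0.65:1 (transverse; effective anisotropy 0.70) and 0.94/0.65
with 1.0714:1 (longitudinal; 0.80), and spectra truths near (Wt=0.65,
a=1.5 mm^-1, b=2.1, K=1.22).  Glycerol-like presets shift toward higher g
and lower a; they are qualitative presets, not measurements.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .phase_function import AngularScan, DoubleHGFit, double_hg_model
from .spectral_inversion import (SpectrumMeasurement, default_water_table,
                                 mua_model, musp_model)
from .transport import OpticalProperties, SlabGeometry, run_slab

__all__ = [
    "GoniometerTruth",
    "SpectraTruth",
    "gen_goniometer_scan",
    "gen_spectra",
    "gen_fixture_suite",
    "GONIOMETER_PRESETS",
    "SPECTRA_PRESETS",
]


def _default_theta():
    return np.arange(-50.0, 51.0, 1.0)


@dataclass(frozen=True)
class GoniometerTruth:
    """Ground truth for an angular scan: two-lobe HG parameters plus noise."""

    K1: float
    g1: float
    K2: float
    g2: float
    noise_rel: float = 0.02
    stray_floor_frac: float = 0.002  # additive floor as a fraction of the peak
    theta_deg: np.ndarray = field(default_factory=_default_theta)

    def __post_init__(self):
        if self.noise_rel < 0 or self.stray_floor_frac < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def g_eff(self) -> float:
        """Exact mixture mean cosine (each HG lobe is unit-normalized)."""
        ktot = self.K1 + self.K2
        return (self.K1 * self.g1 + self.K2 * self.g2) / ktot if ktot > 0 else np.nan


@dataclass(frozen=True)
class SpectraTruth:
    """Ground truth for Rd/Tt spectra generated by the forward slab MC."""

    wt: float = 0.65
    a: float = 1.5
    b: float = 2.1
    k_true: float = 1.22
    g: float = 0.70
    thickness_mm: float = 1.5
    n_tissue: float = 1.40
    n_ambient: float = 1.0
    wavelength_nm: np.ndarray = field(
        default_factory=lambda: np.linspace(450.0, 1300.0, 25))
    photons_per_wl: int = 100_000
    noise_rel: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.wt <= 1.0:
            raise ValueError("Wt must lie in [0, 1]")
        if self.a <= 0 or self.k_true <= 0:
            raise ValueError("a and K_true must be > 0")
        if self.noise_rel < 0:
            raise ValueError("noise must be >= 0")


def gen_goniometer_scan(truth: GoniometerTruth, seed: int,
                        wavelength_nm: float = 633.0,
                        orientation: str | None = None,
                        condition: str | None = None) -> AngularScan:
    """Draw a noisy angular scan from a known two-lobe HG truth.

    intensity(theta) = model(theta) * (1 + eps) + floor, with eps seeded
    Gaussian of s.d. ``noise_rel`` and ``floor`` the stray-light offset.
    """
    rng = np.random.default_rng(seed)
    model_fit = DoubleHGFit(K1=truth.K1, g1=truth.g1, K2=truth.K2, g2=truth.g2)
    theta_rad = np.radians(truth.theta_deg)
    model = double_hg_model(np.abs(theta_rad), model_fit)
    floor = truth.stray_floor_frac * (model.max() if model.size else 0.0)
    eps = rng.standard_normal(model.shape) * truth.noise_rel
    intensity = model * (1.0 + eps) + floor
    return AngularScan(theta_deg=truth.theta_deg, intensity=intensity,
                       wavelength_nm=wavelength_nm, orientation=orientation,
                       condition=condition)


def gen_spectra(truth: SpectraTruth, seed: int,
                orientation: str | None = None,
                condition: str | None = None) -> SpectrumMeasurement:
    """Forward-simulate Rd/Tt spectra from a known (Wt, a, b, K_true) truth.

    Per wavelength, the slab MC is run with mua = Wt*mua_water(lambda) and
    mus = musp(lambda)/(1-g); both channels are divided by K_true (losses the
    sphere does not collect) and multiplied by seeded relative noise.
    """
    rng = np.random.default_rng(seed)
    table = default_water_table()
    geom = SlabGeometry(thickness_mm=truth.thickness_mm,
                        n_above=truth.n_ambient, n_below=truth.n_ambient)
    wl = np.asarray(truth.wavelength_nm, dtype=float)
    rd = np.empty_like(wl)
    tt = np.empty_like(wl)
    for i, lam in enumerate(wl):
        mua = mua_model(lam, truth.wt, table)
        musp = musp_model(lam, truth.a, truth.b)
        props = OpticalProperties(mua=mua, mus=musp / (1.0 - truth.g),
                                  g=truth.g, n=truth.n_tissue)
        res = run_slab(props, geom, truth.photons_per_wl,
                       seed=(seed * 1009 + i) % (2**31 - 1))
        rd[i] = res.rd
        tt[i] = res.tt
    rd = rd / truth.k_true * (1.0 + rng.standard_normal(wl.shape) * truth.noise_rel)
    tt = tt / truth.k_true * (1.0 + rng.standard_normal(wl.shape) * truth.noise_rel)
    return SpectrumMeasurement(
        wavelength_nm=wl, rd=np.clip(rd, 0.0, None), tt=np.clip(tt, 0.0, None),
        thickness_mm=truth.thickness_mm, orientation=orientation,
        condition=condition,
    )


# Saline presets encode the effective anisotropies of saline-soaked tendon
# (0.70 transverse / 0.80 longitudinal) through the exact mixture identity;
# glycerol-like presets shift toward higher g and lower a (qualitative).
GONIOMETER_PRESETS: dict[tuple[str, str], GoniometerTruth] = {
    ("transverse", "saline"): GoniometerTruth(K1=0.65, g1=0.90, K2=1.0, g2=0.57),
    ("longitudinal", "saline"): GoniometerTruth(K1=1.0714, g1=0.94, K2=1.0, g2=0.65),
    ("transverse", "glycerol60"): GoniometerTruth(K1=4.0, g1=0.985, K2=0.2, g2=0.7),
}

SPECTRA_PRESETS: dict[tuple[str, str], SpectraTruth] = {
    ("transverse", "saline"): SpectraTruth(wt=0.65, a=1.5, b=2.1, k_true=1.22,
                                           g=0.70),
    ("transverse", "glycerol60"): SpectraTruth(wt=0.65, a=0.12, b=2.6,
                                               k_true=1.01, g=0.98),
}


def _scan_to_csv(scan: AngularScan, path: Path) -> None:
    lines = [
        f"# wavelength_nm = {scan.wavelength_nm:g}",
        f"# orientation = {scan.orientation}",
        f"# condition = {scan.condition}",
        "theta_deg,intensity",
    ]
    lines += [f"{t:.4f},{i:.8e}" for t, i in zip(scan.theta_deg, scan.intensity)]
    path.write_text("\n".join(lines) + "\n")


def _spectra_to_csv(meas: SpectrumMeasurement, path: Path) -> None:
    lines = [
        f"# thickness_mm = {meas.thickness_mm:g}",
        f"# orientation = {meas.orientation}",
        f"# condition = {meas.condition}",
        "wavelength_nm,Rd,Tt",
    ]
    lines += [
        f"{w:.6f},{r:.8e},{t:.8e}"
        for w, r, t in zip(meas.wavelength_nm, meas.rd, meas.tt)
    ]
    path.write_text("\n".join(lines) + "\n")


def gen_fixture_suite(outdir, seed: int,
                      photons_per_wl: int = 20_000,
                      n_wavelengths: int = 12) -> dict:
    """Write a deterministic bundle of scans + spectra with a truth manifest.

    Returns the manifest (also written as ``manifest.json``): one entry per
    generated file mapping it to its ground-truth parameters and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "files": {}}
    for i, ((orient, cond), truth) in enumerate(sorted(GONIOMETER_PRESETS.items())):
        name = f"scan_{orient}_{cond}.csv"
        file_seed = seed + 101 * i
        scan = gen_goniometer_scan(truth, seed=file_seed, orientation=orient,
                                   condition=cond)
        _scan_to_csv(scan, outdir / name)
        entry = asdict(truth)
        entry["theta_deg"] = [float(truth.theta_deg[0]), float(truth.theta_deg[-1])]
        entry.update(kind="goniometer", seed=file_seed, g_eff=truth.g_eff)
        manifest["files"][name] = entry
    for i, ((orient, cond), preset) in enumerate(sorted(SPECTRA_PRESETS.items())):
        name = f"spectra_{orient}_{cond}.csv"
        file_seed = seed + 997 * (i + 1)
        truth = SpectraTruth(
            wt=preset.wt, a=preset.a, b=preset.b, k_true=preset.k_true,
            g=preset.g, thickness_mm=preset.thickness_mm,
            n_tissue=preset.n_tissue, n_ambient=preset.n_ambient,
            wavelength_nm=np.linspace(500.0, 1300.0, n_wavelengths),
            photons_per_wl=photons_per_wl, noise_rel=preset.noise_rel,
        )
        meas = gen_spectra(truth, seed=file_seed, orientation=orient,
                           condition=cond)
        _spectra_to_csv(meas, outdir / name)
        entry = asdict(truth)
        entry["wavelength_nm"] = [float(truth.wavelength_nm[0]),
                                  float(truth.wavelength_nm[-1]),
                                  int(n_wavelengths)]
        entry.update(kind="spectra", seed=file_seed)
        manifest["files"][name] = entry
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return manifest
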