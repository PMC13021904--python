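"""Slab and voxel-volume Monte-Carlo photon transport.

This module plays the role a general-purpose MC code (MCML/MCX) plays in an
integrating-sphere inversion workflow: it produces diffuse reflectance Rd and
total transmittance Tt for a slab, tabulates them over a (mua, mus') grid as
a lookup table, and scores volumetric fluence maps for light-dosimetry
scenarios.  Units are mm and mm^-1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import h5py
import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import linregress

from . import _mc_kernels as _k
from .errors import DomainError, GeometryMismatchError, LUTCoverageError

__all__ = [
    "OpticalProperties",
    "SlabGeometry",
    "VolumeGeometry",
    "SlabResult",
    "LUT",
    "FluenceMap",
    "sample_hg_deflection",
    "run_slab",
    "build_lut",
    "score_fluence",
]

W_MIN = 1e-4        # roulette threshold on packet weight
ROULETTE_P = 0.1    # survival probability (survivors get w / ROULETTE_P)
_SEED_MOD = 2**31 - 1


def _derive_seed(seed: int, *salts: int) -> int:
    s = int(seed) % _SEED_MOD
    for salt in salts:
        s = (s * 1000003 + int(salt) + 12345) % _SEED_MOD
    return s


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties: mua, mus [mm^-1], anisotropy g, index n."""

    mua: float
    mus: float
    g: float = 0.0
    n: float = 1.40

    def __post_init__(self):
        if self.mua < 0 or self.mus < 0:
            raise DomainError("mua and mus must be >= 0")
        if not -1.0 < self.g < 1.0:
            raise DomainError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise DomainError("refractive index must be >= 1")

    @property
    def musp(self) -> float:
        """Reduced scattering coefficient mus * (1 - g), mm^-1."""
        return self.mus * (1.0 - self.g)


@dataclass(frozen=True)
class SlabGeometry:
    """Laterally infinite slab: thickness [mm] and ambient indices."""

    thickness_mm: float = 1.5
    n_above: float = 1.0
    n_below: float = 1.0

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise DomainError("thickness must be > 0")
        if self.n_above < 1.0 or self.n_below < 1.0:
            raise DomainError("ambient refractive indices must be >= 1")


@dataclass(frozen=True)
class VolumeGeometry:
    """Finite rectangular volume with a fiber source on the z=0 face.

    ``boundary`` accepts "escape" or "matched"; both denote index-matched
    transmissive faces (photons crossing any face are terminated and
    tallied), emulating escape into surrounding tissue.
    ``detector_radius_mm`` limits the transmitted-weight tally on the far
    face; None means the entire exit face.
    """

    size_mm: tuple[float, float, float] = (13.8, 13.8, 50.0)
    voxel_mm: float = 0.2
    boundary: str = "escape"
    source_diameter_mm: float = 0.2
    detector_radius_mm: float | None = None

    def __post_init__(self):
        if self.voxel_mm <= 0:
            raise DomainError("voxel size must be > 0")
        for dim in self.size_mm:
            if dim <= 0:
                raise DomainError("volume dimensions must be > 0")
            ratio = dim / self.voxel_mm
            if abs(ratio - round(ratio)) > 1e-6:
                raise DomainError(
                    "volume dimensions must be positive multiples of the voxel size"
                )
        if self.boundary not in ("escape", "matched"):
            raise DomainError("boundary rule must be 'escape' or 'matched'")
        if self.source_diameter_mm <= 0:
            raise DomainError("source diameter must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(d / self.voxel_mm)) for d in self.size_mm)


class SlabResult(NamedTuple):
    """Fractions of delivered power: diffuse reflectance (specular excluded),
    total transmittance, absorbed, and the launch specular reflection."""

    rd: float
    tt: float
    absorbed: float
    specular: float


def sample_hg_deflection(g, u):
    """Cosine of the HG deflection angle by inverse-CDF sampling.

    ``u`` is a uniform variate in [0, 1); for g = 0 the result is 2u - 1.
    Vectorized over ``u``.
    """
    g = float(g)
    if not -1.0 < g < 1.0:
        raise DomainError(f"anisotropy g={g} outside (-1, 1)")
    u = np.asarray(u, dtype=float)
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)


def run_slab(props: OpticalProperties, geom: SlabGeometry,
             n_photons: int, seed: int) -> SlabResult:
    """Simulate a pencil beam normally incident on a slab.

    Rd excludes the specular component (the integrating-sphere configuration
    lets specular reflections exit).  Deterministic for fixed seed.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    rd, tt, absorbed, rsp = _k.slab_mc(
        props.mua, props.mus, props.g, geom.thickness_mm,
        props.n, geom.n_above, geom.n_below,
        int(n_photons), _derive_seed(seed), W_MIN, ROULETTE_P,
    )
    return SlabResult(rd=rd, tt=tt, absorbed=absorbed, specular=rsp)


@dataclass
class LUT:
    """Lookup table (mua, mus') -> (Rd, Tt) at fixed g, thickness, indices."""

    mua_grid: np.ndarray
    musp_grid: np.ndarray
    rd: np.ndarray
    tt: np.ndarray
    g: float
    thickness_mm: float
    n_tissue: float
    n_above: float
    n_below: float
    n_photons: int
    seed: int
    _interp: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.mua_grid = np.asarray(self.mua_grid, dtype=float)
        self.musp_grid = np.asarray(self.musp_grid, dtype=float)
        self.rd = np.asarray(self.rd, dtype=float)
        self.tt = np.asarray(self.tt, dtype=float)
        if np.any(np.diff(self.mua_grid) <= 0) or np.any(np.diff(self.musp_grid) <= 0):
            raise ValueError("LUT grids must be strictly ascending")
        expected = (self.mua_grid.size, self.musp_grid.size)
        if self.rd.shape != expected or self.tt.shape != expected:
            raise ValueError("table shapes must be (n_mua, n_musp)")
        if np.any(self.rd < 0) or np.any(self.rd > 1) or np.any(self.tt < 0) or np.any(self.tt > 1):
            raise ValueError("table entries must lie in [0, 1]")

    def covers(self, mua, musp) -> np.ndarray:
        mua = np.atleast_1d(mua)
        musp = np.atleast_1d(musp)
        return (
            (mua >= self.mua_grid[0]) & (mua <= self.mua_grid[-1])
            & (musp >= self.musp_grid[0]) & (musp <= self.musp_grid[-1])
        )

    def lookup(self, mua, musp) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear interpolation of (Rd, Tt) at (mua, musp) query points."""
        if self._interp is None:
            grids = (self.mua_grid, self.musp_grid)
            self._interp = (
                RegularGridInterpolator(grids, self.rd, method="linear"),
                RegularGridInterpolator(grids, self.tt, method="linear"),
            )
        pts = np.column_stack([np.atleast_1d(mua), np.atleast_1d(musp)])
        bad = ~self.covers(pts[:, 0], pts[:, 1])
        if np.any(bad):
            i = int(np.argmax(bad))
            raise LUTCoverageError(
                f"query (mua={pts[i, 0]:.4g}, musp={pts[i, 1]:.4g}) mm^-1 "
                "outside LUT grid; rebuild with an extended grid"
            )
        return self._interp[0](pts), self._interp[1](pts)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mua_grid", data=self.mua_grid)
            f.create_dataset("musp_grid", data=self.musp_grid)
            f.create_dataset("Rd", data=self.rd)
            f.create_dataset("Tt", data=self.tt)
            f.attrs.update(
                g=self.g, thickness_mm=self.thickness_mm, n_tissue=self.n_tissue,
                n_above=self.n_above, n_below=self.n_below,
                n_photons=self.n_photons, seed=self.seed,
            )

    @classmethod
    def load(cls, path) -> "LUT":
        with h5py.File(path, "r") as f:
            return cls(
                mua_grid=f["mua_grid"][:], musp_grid=f["musp_grid"][:],
                rd=f["Rd"][:], tt=f["Tt"][:],
                g=float(f.attrs["g"]), thickness_mm=float(f.attrs["thickness_mm"]),
                n_tissue=float(f.attrs["n_tissue"]), n_above=float(f.attrs["n_above"]),
                n_below=float(f.attrs["n_below"]),
                n_photons=int(f.attrs["n_photons"]), seed=int(f.attrs["seed"]),
            )

    def to_csv(self, path) -> None:
        """Long-format CSV export (mua, musp, Rd, Tt) for inspection."""
        import pandas as pd

        mm, ss = np.meshgrid(self.mua_grid, self.musp_grid, indexing="ij")
        pd.DataFrame(
            {
                "mua_mm^-1": mm.ravel(),
                "musp_mm^-1": ss.ravel(),
                "Rd": self.rd.ravel(),
                "Tt": self.tt.ravel(),
            }
        ).to_csv(path, index=False)


def default_mua_grid() -> np.ndarray:
    return np.geomspace(1e-4, 1.0, 25)


def default_musp_grid() -> np.ndarray:
    return np.geomspace(0.01, 30.0, 25)


def build_lut(g: float, geom: SlabGeometry, mua_grid=None, musp_grid=None,
              n_photons: int = 20_000, seed: int = 0,
              n_tissue: float = 1.40) -> LUT:
    """Tabulate (Rd, Tt) over a (mua, mus') grid by per-cell slab MC.

    Each cell simulates mus = musp / (1 - g) with a deterministic per-cell
    seed derived from ``seed``.
    """
    mua_grid = default_mua_grid() if mua_grid is None else np.asarray(mua_grid, float)
    musp_grid = default_musp_grid() if musp_grid is None else np.asarray(musp_grid, float)
    if np.any(musp_grid <= 0):
        raise DomainError("musp grid must be positive")
    rd = np.empty((mua_grid.size, musp_grid.size))
    tt = np.empty_like(rd)
    for i, mua in enumerate(mua_grid):
        for j, musp in enumerate(musp_grid):
            props = OpticalProperties(mua=mua, mus=musp / (1.0 - g), g=g, n=n_tissue)
            res = run_slab(props, geom, n_photons, _derive_seed(seed, i, j))
            rd[i, j] = res.rd
            tt[i, j] = res.tt
    return LUT(
        mua_grid=mua_grid, musp_grid=musp_grid, rd=rd, tt=tt,
        g=g, thickness_mm=geom.thickness_mm, n_tissue=n_tissue,
        n_above=geom.n_above, n_below=geom.n_below,
        n_photons=int(n_photons), seed=int(seed),
    )


@dataclass
class FluenceMap:
    """Voxelized fluence phi [mm^-2 per delivered photon] plus exit tallies."""

    phi: np.ndarray
    geometry: VolumeGeometry
    transmitted_fraction: float
    absorbed_fraction: float
    escaped_fraction: float
    n_photons: int
    seed: int
    props: OpticalProperties | None = None

    def z_centers(self) -> np.ndarray:
        dv = self.geometry.voxel_mm
        return (np.arange(self.phi.shape[2]) + 0.5) * dv

    def depth_profile(self, radius_mm: float = 0.6) -> tuple[np.ndarray, np.ndarray]:
        """On-axis fluence phi(z) at x=0, y=0 (beam axis), averaged over
        voxels within ``radius_mm`` of the axis to reduce variance."""
        nx, ny, _ = self.phi.shape
        dv = self.geometry.voxel_mm
        cx = self.geometry.size_mm[0] / 2.0
        cy = self.geometry.size_mm[1] / 2.0
        xs = (np.arange(nx) + 0.5) * dv - cx
        ys = (np.arange(ny) + 0.5) * dv - cy
        mask = (xs[:, None] ** 2 + ys[None, :] ** 2) <= radius_mm**2
        if not mask.any():  # radius smaller than a voxel: take the axis voxel
            mask = np.zeros((nx, ny), dtype=bool)
            mask[nx // 2, ny // 2] = True
        prof = self.phi[mask, :].mean(axis=0)
        return self.z_centers(), prof

    def fit_mueff(self, window_mm: tuple[float, float] = (5.0, 45.0),
                  radius_mm: float = 0.6) -> float:
        """Effective attenuation slope: -d ln(phi)/dz by linear regression of
        ln phi(z) over ``window_mm``, using only bins with positive counts."""
        z, prof = self.depth_profile(radius_mm)
        sel = (z >= window_mm[0]) & (z <= window_mm[1]) & (prof > 0)
        if sel.sum() < 3:
            raise ValueError("too few populated depth bins in the fit window")
        res = linregress(z[sel], np.log(prof[sel]))
        return float(-res.slope)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("phi", data=self.phi, compression="gzip")
            f.attrs.update(
                voxel_mm=self.geometry.voxel_mm,
                size_mm=np.asarray(self.geometry.size_mm),
                transmitted_fraction=self.transmitted_fraction,
                absorbed_fraction=self.absorbed_fraction,
                escaped_fraction=self.escaped_fraction,
                n_photons=self.n_photons, seed=self.seed,
            )

    def profile_to_csv(self, path, radius_mm: float = 0.6) -> None:
        import pandas as pd

        z, prof = self.depth_profile(radius_mm)
        pd.DataFrame({"z_mm": z, "phi_per_mm2": prof}).to_csv(path, index=False)


def score_fluence(props: OpticalProperties, geom: VolumeGeometry,
                  n_photons: int, seed: int) -> FluenceMap:
    """Run the voxel-volume MC and return the normalized fluence map.

    Fluence is accumulated with the collision estimator (w / mu_t per
    collision, divided by voxel volume and photon count); the weight ledger
    delivered = absorbed + escaped + transmitted holds to the roulette
    tolerance.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if geom.voxel_mm > 1.0:
        raise DomainError("voxel size must be <= 1 mm to resolve the beam")
    lx, ly, lz = geom.size_mm
    det_r = geom.detector_radius_mm
    if det_r is None:
        det_r = float(np.hypot(lx, ly))  # entire far face
    phi_raw, transmitted, absorbed, escaped = _k.volume_mc(
        props.mua, props.mus, props.g, lx, ly, lz, geom.voxel_mm,
        geom.source_diameter_mm / 2.0, det_r,
        int(n_photons), _derive_seed(seed), W_MIN, ROULETTE_P,
    )
    phi = phi_raw / (n_photons * geom.voxel_mm**3)
    return FluenceMap(
        phi=phi, geometry=geom,
        transmitted_fraction=float(transmitted),
        absorbed_fraction=float(absorbed),
        escaped_fraction=float(escaped),
        n_photons=int(n_photons), seed=int(seed), props=props,
    )
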