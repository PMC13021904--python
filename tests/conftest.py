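import numpy as np
import pytest

from tendonoptics import LUT, SlabGeometry, build_lut


@pytest.fixture(scope="session")
def slab_geom():
    """Default integrating-sphere slab: 1.5 mm, air on both sides."""
    return SlabGeometry(thickness_mm=1.5)


@pytest.fixture(scope="session")
def mc_lut(slab_geom):
    """Monte-Carlo lookup table at g = 0.70 covering the tendon-like
    coefficient range used by the synthetic spectra (450-1300 nm)."""
    return build_lut(
        g=0.70, geom=slab_geom,
        mua_grid=np.geomspace(1e-5, 0.1, 12),
        musp_grid=np.geomspace(0.1, 4.0, 14),
        n_photons=20_000, seed=42,
    )


def analytic_tables(mua_grid, musp_grid):
    """Synthetic smooth (Rd, Tt) surfaces with the right monotonicities:
    Rd increasing in musp and decreasing in mua, Tt decreasing in both.
    Not a transport solution -- a fast stand-in for optimizer/interp tests."""
    mm, ss = np.meshgrid(mua_grid, musp_grid, indexing="ij")
    rd = 0.45 * ss / (ss + 1.2) / (1.0 + 8.0 * mm)
    tt = np.exp(-5.0 * mm) / (1.0 + 0.9 * ss)
    return rd, tt


@pytest.fixture(scope="session")
def analytic_lut():
    """Dense synthetic LUT (see :func:`analytic_tables`) for inversion tests
    that do not need Monte-Carlo physics."""
    mua_grid = np.geomspace(1e-6, 0.2, 60)
    musp_grid = np.geomspace(0.05, 5.0, 80)
    rd, tt = analytic_tables(mua_grid, musp_grid)
    return LUT(
        mua_grid=mua_grid, musp_grid=musp_grid, rd=rd, tt=tt,
        g=0.70, thickness_mm=1.5, n_tissue=1.40, n_above=1.0, n_below=1.0,
        n_photons=0, seed=0,
    )
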