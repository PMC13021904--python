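"""Monte-Carlo transport: sampling, slab benchmarks, lookup tables, fluence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from tendonoptics import (DomainError, OpticalProperties, SlabGeometry,
                          VolumeGeometry, build_lut, run_slab,
                          sample_hg_deflection, score_fluence)
from tendonoptics.transport import LUT, _derive_seed

MATCHED = dict(n=1.0)


def hg_cos_cdf(c, g):
    """Analytic CDF of the HG deflection cosine."""
    return (1 - g * g) / (2 * g) * (
        1 / np.sqrt(1 + g * g - 2 * g * c) - 1 / (1 + g))


class TestHGDeflection:
    def test_uniform_cosine_for_g0(self):
        assert sample_hg_deflection(0.0, 0.75) == pytest.approx(0.5)
        assert sample_hg_deflection(0.0, 0.5) == pytest.approx(0.0)

    def test_mean_cosine_matches_g(self):
        rng = np.random.default_rng(11)
        c = sample_hg_deflection(0.9, rng.random(100_000))
        assert c.mean() == pytest.approx(0.90, abs=0.01)

    def test_distribution_matches_phase_function(self):
        rng = np.random.default_rng(12)
        c = sample_hg_deflection(0.7, rng.random(100_000))
        res = kstest(c, lambda x: hg_cos_cdf(x, 0.7))
        assert res.pvalue > 1e-3

    def test_domain_error(self):
        with pytest.raises(DomainError):
            sample_hg_deflection(1.0, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(g=st.floats(-0.999, 0.999), u=st.floats(0.0, 0.999999))
    def test_result_is_a_cosine(self, g, u):
        assert -1.0 <= sample_hg_deflection(g, u) <= 1.0


class TestSlab:
    def test_beer_lambert_limit(self):
        props = OpticalProperties(mua=0.1, mus=0.0, g=0.0, **MATCHED)
        res = run_slab(props, SlabGeometry(1.5), 1_000_000, seed=1)
        assert res.rd == 0.0
        assert res.tt == pytest.approx(np.exp(-0.15), rel=0.005)

    def test_no_absorption_conservation(self):
        props = OpticalProperties(mua=0.0, mus=5.0, g=0.7, **MATCHED)
        res = run_slab(props, SlabGeometry(1.5), 100_000, seed=2)
        assert res.rd + res.tt == pytest.approx(1.0, abs=1e-9)
        assert res.absorbed == 0.0

    def test_van_de_hulst_slab_benchmark(self):
        # albedo 0.9, g = 0.75, optical thickness 2, matched boundaries:
        # tabulated Rd = 0.09739, Tt = 0.66096
        props = OpticalProperties(mua=1.0, mus=9.0, g=0.75, **MATCHED)
        res = run_slab(props, SlabGeometry(0.2), 500_000, seed=3)
        assert res.rd == pytest.approx(0.09739, abs=0.001)   # ~2 MC s.e.
        assert res.tt == pytest.approx(0.66096, abs=0.0014)

    def test_energy_ledger_with_fresnel_boundaries(self):
        props = OpticalProperties(mua=0.05, mus=3.0, g=0.8, n=1.4)
        res = run_slab(props, SlabGeometry(1.5), 200_000, seed=4)
        total = res.rd + res.tt + res.absorbed + res.specular
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_seed_determinism(self):
        props = OpticalProperties(mua=0.02, mus=2.0, g=0.7, n=1.4)
        a = run_slab(props, SlabGeometry(1.5), 50_000, seed=5)
        b = run_slab(props, SlabGeometry(1.5), 50_000, seed=5)
        assert a == b

    def test_nonphysical_properties_rejected(self):
        with pytest.raises(DomainError):
            OpticalProperties(mua=-0.1, mus=1.0)
        with pytest.raises(DomainError):
            OpticalProperties(mua=0.1, mus=1.0, g=1.0)

    def test_reduced_scattering_consistency(self):
        p = OpticalProperties(mua=0.0, mus=10.0, g=0.7)
        assert p.musp == pytest.approx(3.0)


def brute_slab(mua, mus, d, n_photons, seed):
    """Independent oracle: analog (unweighted) isotropic-scattering slab MC,
    vectorized numpy, different RNG stream from the main kernel."""
    rng = np.random.default_rng(seed)
    mut = mua + mus
    albedo = mus / mut
    z = np.zeros(n_photons)
    uz = np.ones(n_photons)
    active = np.ones(n_photons, dtype=bool)
    rd = tt = 0
    while active.any():
        idx = np.flatnonzero(active)
        z[idx] += rng.exponential(1.0 / mut, idx.size) * uz[idx]
        out_top = z[idx] < 0
        out_bot = z[idx] > d
        rd += int(out_top.sum())
        tt += int(out_bot.sum())
        survive = rng.random(idx.size) < albedo
        keep = ~(out_top | out_bot) & survive
        active[idx] = keep
        uz[idx[keep]] = rng.uniform(-1.0, 1.0, int(keep.sum()))
    return rd / n_photons, tt / n_photons


class TestBruteForceCrossCheck:
    def test_diffusion_regime_agrees_with_independent_mc(self):
        # musp = 10 mm^-1 (g=0), mua = 0.01 mm^-1, matched 1.5-mm slab
        n = 200_000
        rd_b, tt_b = brute_slab(0.01, 10.0, 1.5, n, seed=31)
        props = OpticalProperties(mua=0.01, mus=10.0, g=0.0, **MATCHED)
        res = run_slab(props, SlabGeometry(1.5), n, seed=32)
        se = lambda p: np.sqrt(p * (1 - p) / n)
        for ours, brute in ((res.rd, rd_b), (res.tt, tt_b)):
            tol = 2.0 * np.sqrt(se(ours) ** 2 + se(brute) ** 2)
            assert abs(ours - brute) < tol


class TestGInsensitivity:
    def test_diffuse_regime_weakly_depends_on_g(self):
        # at fixed musp = 1 mm^-1 through a 1.5 mm slab, Rd/Tt move < 5%
        # as g goes 0.7 -> 0.9
        geom = SlabGeometry(1.5)
        out = {}
        for g in (0.7, 0.9):
            props = OpticalProperties(mua=0.01, mus=1.0 / (1 - g), g=g, n=1.4)
            out[g] = run_slab(props, geom, 200_000, seed=6)
        assert abs(out[0.9].rd - out[0.7].rd) / out[0.7].rd < 0.05
        assert abs(out[0.9].tt - out[0.7].tt) / out[0.7].tt < 0.05


class TestLUT:
    def test_single_cell_matches_direct_run(self, slab_geom):
        lut = build_lut(g=0.7, geom=slab_geom, mua_grid=[0.001],
                        musp_grid=[1.0], n_photons=20_000, seed=9)
        props = OpticalProperties(mua=0.001, mus=1.0 / 0.3, g=0.7, n=1.40)
        res = run_slab(props, slab_geom, 20_000, seed=_derive_seed(9, 0, 0))
        assert lut.rd[0, 0] == res.rd
        assert lut.tt[0, 0] == res.tt

    def test_tt_decreases_along_mua(self, slab_geom):
        lut = build_lut(g=0.7, geom=slab_geom,
                        mua_grid=[0.001, 0.01, 0.1, 0.5],
                        musp_grid=[1.0], n_photons=30_000, seed=10)
        assert np.all(np.diff(lut.tt[:, 0]) < 0)

    def test_qualitative_surfaces(self, mc_lut):
        # Rd increases with musp, Tt decreases with musp, at low absorption
        assert np.all(np.diff(mc_lut.rd[0, :]) > -0.01)
        assert mc_lut.rd[0, -1] > mc_lut.rd[0, 0]
        assert np.all(np.diff(mc_lut.tt[0, :]) < 0.01)
        assert mc_lut.tt[0, -1] < mc_lut.tt[0, 0]

    def test_entries_physical(self, mc_lut):
        assert np.all(mc_lut.rd >= 0) and np.all(mc_lut.rd <= 1)
        assert np.all(mc_lut.tt >= 0) and np.all(mc_lut.tt <= 1)
        assert np.all(mc_lut.rd + mc_lut.tt <= 1.0 + 3e-3)

    def test_hdf5_round_trip(self, mc_lut, tmp_path):
        path = tmp_path / "lut.h5"
        mc_lut.save(path)
        back = LUT.load(path)
        np.testing.assert_array_equal(back.rd, mc_lut.rd)
        np.testing.assert_array_equal(back.tt, mc_lut.tt)
        np.testing.assert_array_equal(back.mua_grid, mc_lut.mua_grid)
        assert back.g == mc_lut.g
        assert back.thickness_mm == mc_lut.thickness_mm
        assert back.seed == mc_lut.seed

    def test_csv_export(self, mc_lut, tmp_path):
        import pandas as pd

        path = tmp_path / "lut.csv"
        mc_lut.to_csv(path)
        df = pd.read_csv(path)
        assert len(df) == mc_lut.rd.size
        assert {"mua_mm^-1", "musp_mm^-1", "Rd", "Tt"} <= set(df.columns)


class TestFluence:
    def test_absorbing_only_beer_lambert_slope(self):
        geom = VolumeGeometry(size_mm=(10.0, 10.0, 20.0), voxel_mm=0.5)
        props = OpticalProperties(mua=0.1, mus=0.0, g=0.0, **MATCHED)
        fmap = score_fluence(props, geom, 400_000, seed=13)
        mueff = fmap.fit_mueff(window_mm=(1.0, 15.0), radius_mm=0.3)
        assert mueff == pytest.approx(0.1, rel=0.02)

    def test_weight_ledger(self):
        geom = VolumeGeometry(size_mm=(10.0, 10.0, 10.0), voxel_mm=0.5)
        props = OpticalProperties(mua=0.05, mus=2.0, g=0.7, **MATCHED)
        fmap = score_fluence(props, geom, 50_000, seed=14)
        total = (fmap.transmitted_fraction + fmap.absorbed_fraction
                 + fmap.escaped_fraction)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_fluence_nonnegative_and_deterministic(self):
        geom = VolumeGeometry(size_mm=(6.0, 6.0, 6.0), voxel_mm=0.5)
        props = OpticalProperties(mua=0.01, mus=1.0, g=0.5, **MATCHED)
        a = score_fluence(props, geom, 20_000, seed=15)
        b = score_fluence(props, geom, 20_000, seed=15)
        assert np.all(a.phi >= 0)
        np.testing.assert_array_equal(a.phi, b.phi)
        assert a.transmitted_fraction == b.transmitted_fraction

    def test_geometry_validation(self):
        with pytest.raises(DomainError):
            VolumeGeometry(size_mm=(10.0, 10.0, 10.3), voxel_mm=0.5)
        with pytest.raises(DomainError):
            VolumeGeometry(boundary="mirror")
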