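# tendonoptics

Tendon is optically anisotropic: light travels far more easily along the
collagen fibers than across them. Quantifying that anisotropy — and how
glycerol-based optical clearing changes it — matters for light dosimetry in
photobiomodulation therapy, where a tendon can act as a conduit that carries
near-infrared treatment light toward deeper targets.

`tendonoptics` is a Python package for the full measurement-to-model chain
used in this kind of study:

1. **Phase-function analysis** — goniometer scans of thin (single-scattering)
   sections are fitted with a two-lobe Henyey–Greenstein model,

   p_fit(θ) = cos θ · [K₁ p_HG(θ; g₁) + K₂ p_HG(θ; g₂)],

   where the cosine is the Lambertian pattern of flux escaping a surface and
   p_HG(θ; g) = (1 − g²) / (4π (1 + g² − 2g cos θ)^{3/2}). The effective
   anisotropy g_eff is the mean cosine of the mixture p₁ + p₂ over the full
   sphere.

2. **Monte-Carlo photon transport** — MCML-style weighted-packet transport
   (numba-compiled) through laterally infinite slabs with Fresnel boundaries,
   and through finite voxel volumes with escaping boundaries, scoring diffuse
   reflectance R_d, total transmittance T_t, and voxelized fluence φ [mm⁻²
   per delivered photon].

3. **Spectral inversion** — integrating-sphere R_d/T_t spectra (400–1600 nm)
   are inverted against MC lookup tables using the models
   μ_a(λ) = W_t · μ_a,water(λ) (water-scaled absorption, Hale–Querry table)
   and μ_s′(λ) = a (λ/500 nm)^(−b) (scattering power law), with a loss
   factor K that rescales the measured data for sphere port losses. Bounded
   trust-region least squares recovers (W_t, a, b, K) with W_t ≤ 0.65.

4. **Transmission simulation** — a ~200 μm fiber delivering 810-nm light into
   a 13.8 × 13.8 × 50 mm tendon volume, comparing delivery along versus
   across the fibers through fluence depth profiles and their effective
   attenuation slope μ_eff.

A synthetic-data module generates instrument-realistic goniometer scans and
R_d/T_t spectra from known ground truth, so the entire pipeline is testable
without instrument data.

## Worked example

```python
import numpy as np
from tendonoptics import (SlabGeometry, build_lut, invert_spectra,
                          fit_double_hg, derived_scattering, musp_model)
from tendonoptics.synthetic import (GONIOMETER_PRESETS, SpectraTruth,
                                    gen_goniometer_scan, gen_spectra)

# 1. fit a synthetic transverse-tendon goniometer scan
scan = gen_goniometer_scan(GONIOMETER_PRESETS[("transverse", "saline")], seed=1)
fit = fit_double_hg(scan)
print(f"g1_eff={fit.g1_eff:.2f} g2_eff={fit.g2_eff:.2f} g_eff={fit.g_eff:.2f}")
# -> g1_eff=0.90 g2_eff=0.53 g_eff=0.67

# 2. invert synthetic sphere spectra against a Monte-Carlo lookup table
lut = build_lut(g=0.70, geom=SlabGeometry(1.5),
                mua_grid=np.geomspace(1e-5, 0.1, 12),
                musp_grid=np.geomspace(0.1, 4.0, 14),
                n_photons=20_000, seed=42)
truth = SpectraTruth(wt=0.65, a=1.5, b=2.1, k_true=1.2, g=0.70,
                     photons_per_wl=100_000)
rec = invert_spectra(gen_spectra(truth, seed=7), lut)
print(f"Wt={rec.wt:.2f} a={rec.a:.2f} b={rec.b:.2f} K={rec.k:.2f}")
# -> Wt=0.65 a=1.54 b=2.15 K=1.20   (truth: 0.65, 1.5, 2.1, 1.2)

# 3. reduced scattering at 800 nm and the unlumped transport quantities
print(f"musp(800) = {musp_model(800, rec.a, rec.b):.2f} mm^-1")
# -> musp(800) = 0.56 mm^-1
d = derived_scattering(19.6, 0.80)
print(f"mus = {d.mus:.1f} mm^-1, mfp = {d.mfp*1000:.0f} um")
# -> mus = 98.0 mm^-1, mfp = 10 um
```

The first block recovers the lobe anisotropies of the transverse preset
(narrow forward lobe g₁ ≈ 0.90, broad lobe g₂ ≈ 0.57, overall g_eff ≈ 0.70
up to noise). The second recovers the spectral truth within a few percent
from Monte-Carlo-generated spectra, demonstrating that the lookup-table
inversion is well posed. The third evaluates the fitted power law and
converts a reduced scattering coefficient into the scattering coefficient
and mean free path for a given anisotropy.

The same workflow is scriptable from the shell:

```sh
tendonoptics synth fixtures/ --seed 3
tendonoptics fit-phase fixtures/scan_transverse_saline.csv -o fit.json
tendonoptics build-lut -g 0.70 --thickness 1.5 -o lut.h5
tendonoptics invert fixtures/spectra_transverse_saline.csv --lut lut.h5 -o inv.json
tendonoptics report scenario.yaml -o summary.json
```

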