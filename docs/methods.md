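# Methods

This note documents the models implemented in `tendonoptics`, their
assumptions, the numerical choices behind them, and what the synthetic-data
tests do and do not demonstrate about real instrument data.

## Phase-function model and effective anisotropy

A goniometer measures scattered power I(θ) over a limited polar range,
typically ±50°, for a thin tissue section. Tendon contains scatterers at two
very different length scales (collagen fibers and fibrils), so a single
Henyey–Greenstein (HG) lobe underfits; the fitted model is a two-lobe
mixture with a Lambertian escape factor:

    p_fit(θ) = cos θ · [K₁ p_HG(θ; g₁) + K₂ p_HG(θ; g₂)].

We implement the standard normalized HG density

    p_HG(θ; g) = (1 − g²) / (4π (1 + g² − 2 g cos θ)^{3/2}),

which satisfies ∫ p_HG · 2π sin θ dθ = 1 (a variant with a bare `g` in place
of `g²` in the denominator circulates in print; only the normalized form is
consistent with using the fitted lobes as probability densities, so that is
what the package uses). K₁, K₂ (a.u.·sr) absorb the detector's arbitrary
units; g₁, g₂ are fitting parameters, not Legendre moments.

**Objective.** The fit minimizes Σ_θ [w(θ) (p_fit − I)]² with azimuthal
weight w(θ) = 2π |sin θ| Δθ, i.e. a conventional least-squares comparison of
azimuthally integrated intensities under rotational symmetry. Signed angles
are folded onto [0°, 50°] by averaging symmetric pairs (left/right tail
asymmetry — a stray-light signature — is logged). The θ = 0 sample carries
zero weight (sin 0 = 0), which is deliberate: pinholes in 20-μm sections can
corrupt the on-axis point. Negative intensities (detector noise floor) are
clipped to zero with a logged warning.

**Optimization.** The model is linear in (K₁, K₂), so each start solves the
lobe scales by non-negative linear least squares at fixed (g₁, g₂) (variable
projection) on a coarse 4×4 (g₁, g₂) lattice; the best three candidates are
polished by bounded trust-region least squares over all four parameters
(g ∈ [0, 0.9999], K ≥ 0). Ties break toward the lower residual, then the
larger forward-lobe g₁ (the two-lobe model has a lobe-swap symmetry). The
returned fit orders g₁ ≥ g₂. Flat scans (relative range < 10%) and all-zero
scans raise a degenerate-input error rather than returning a meaningless
optimum.

**Effective anisotropy.** The single-scattering phase function is the
mixture p = p₁ + p₂, obtained by removing the Lambertian factor
analytically (dividing p_fit by |cos θ| is singular at 90°; the analytic
form is the removable-singularity equivalent). g_eff is the mean cosine of p
over [0, π] with solid-angle weight; g1_eff and g2_eff are the lobe mean
cosines. These integrals are evaluated by adaptive Gauss–Kronrod quadrature
in cos θ rather than a fixed angular grid: near g = 0.99 the HG peak width
in cos θ is (1 − g)² ≈ 10⁻⁴, which a fixed sub-degree grid cannot resolve to
the 10⁻⁴ tolerance the identities are tested at. For unit-normalized lobes,
g_eff equals the K-weighted mean (K₁g₁ + K₂g₂)/(K₁ + K₂) exactly; the
quadrature path is cross-checked against this identity in the tests.

Because only ±50° is observed, g_eff is an *effective* anisotropy: the
backscattered hemisphere is extrapolated by the fitted model. This is the
relevant quantity for forward-transport applications but need not equal the
true single-scattering mean cosine.

## Monte-Carlo photon transport

Weighted-packet (MCML-style) rules: step length −ln ξ / μ_t, per-collision
absorption deposit w·μ_a/μ_t, HG deflection sampled by inverse CDF with
uniform azimuth, Russian roulette below weight 10⁻⁴ with survival
probability 0.1. The RNG is seeded explicitly per run and per LUT cell, so
all tallies are bit-identical for identical (seed, n_photons, properties).
Kernels are numba-compiled; a laterally infinite slab and a finite voxel
volume are provided.

**Slab (integrating-sphere geometry).** Pencil beam at normal incidence;
unpolarized Fresnel reflection/refraction at both faces; the specular
reflection of the incident beam is deducted at launch and excluded from R_d,
matching a sphere configured to let specular reflections exit. Defaults:
n_tissue = 1.40, ambient 1.00, both configurable; the glass slide is not
modeled. Validation (in the test suite): Beer–Lambert limit to < 0.5% at
10⁶ photons; R_d + T_t = 1 exactly when μ_a = 0; energy ledger
R_sp + R_d + T_t + A = 1 to < 10⁻³ (roulette tolerance); the classic van de
Hulst slab benchmark (single-scattering albedo 0.9, g = 0.75, optical
thickness 2, matched boundaries: R_d = 0.09739, T_t = 0.66096) to within
two Monte-Carlo standard errors; and agreement with an independent analog
(unweighted, isotropic) MC written in plain numpy with a different RNG.

**Lookup tables.** (R_d, T_t) tabulated over ascending (μ_a, μ_s′) grids at
fixed (g, thickness, indices), each cell simulated with μ_s = μ_s′/(1 − g)
and a deterministic per-cell seed. Default grids are log-spaced,
μ_a ∈ [10⁻⁴, 1] mm⁻¹ (25 points) and μ_s′ ∈ [0.01, 30] mm⁻¹ (25 points);
queries outside the grid raise a coverage error naming the offending
wavelength so the caller can rebuild on an extended grid. Interpolation is
bilinear. Serialization is HDF5 with full metadata (g, thickness, indices,
photon count, seed) plus a CSV export.

**Voxel volume.** Homogeneous finite box, flat-top fiber source (default
200 μm diameter) centered on the entry face. All faces are index-matched
transmissive ("escape") boundaries: a photon crossing any face is terminated
and tallied, emulating escape into surrounding tissue; the geometry accepts
both the names `escape` and `matched` for this rule. Fluence is scored with
the collision estimator φ = Σ w/μ_t per voxel volume per delivered photon
[mm⁻²]; weight exiting the far face (optionally within a detector radius,
default the whole face) is the transmitted fraction. The depth profile
φ(z) at x = 0, y = 0 averages voxels within a configurable radius of the
beam axis (default 0.6 mm) to reduce variance, and μ_eff is the negative
slope of a linear regression of ln φ(z) over a depth window, default
z ∈ [5, 45] mm, using only bins with positive counts. In sparsely populated
deep regions the positive-bin restriction biases the profile high (a
Monte-Carlo noise floor); increase photons or the averaging radius when the
deep profile matters.

## Spectral inversion

Absorption is modeled as water scaled by the tissue water volume fraction,
μ_a(λ) = W_t · μ_a,water(λ). The packaged water table is a ~40-knot
compilation of pure-water absorption after the Hale & Querry data as
commonly tabulated in tissue optics, log-linearly interpolated; published
digitizations of this spectrum differ at the tens-of-percent level between
knots, which matters little here because tendon attenuation is
scattering-dominated outside the water bands. At 810 nm the table gives
0.65 × μ_a,water ≈ 0.0013 mm⁻¹. Reduced scattering follows the power law
μ_s′(λ) = a (λ/500 nm)^(−b); 500 nm is chosen as reference because water
absorption is minimal there.

Real single-port integrating-sphere data underestimate both R_d and T_t
(port-edge and lateral losses), so the measured spectra are rescaled by a
single factor K before comparison with the lookup-table prediction:

    min over (W_t, a, b, K):  Σ_λ (K·R_d,meas − R_d,lut)² + (K·T_t,meas − T_t,lut)².

Applying one K to both channels assumes both are underestimated in equal
proportion. That assumption is known to be imperfect — lateral loss affects
transmission more than reflectance, which can bias the recovered μ_s′ high —
but it is the standard correction and is kept deliberately; treat recovered
absolute magnitudes with corresponding care.

Bounds: W_t ∈ [0, 0.65] (native tendon is ~62% water; the bound is active in
practice and the fit pins W_t at it), a ∈ (0, 100] mm⁻¹, b ∈ [0, 6],
K ∈ [0.5, 2]. Initialization (W_t, a, b, K) = (0.65, 1.0, 1.5, 1.2) plus
three multistarts perturbing (a, b); the optimizer is scipy's trust-region
reflective bounded least squares. During optimization LUT queries are
clipped to the grid; the converged solution is re-checked strictly and a
coverage error propagates if it lies outside. Residuals are weighted
uniformly across wavelength. Derived quantities: μ_s = μ_s′/(1 − g) and
mean free path 1/μ_s.

The inversion is insensitive to the assumed g in the diffuse regime: for a
1.5-mm slab, rebuilding the LUT with g anywhere in 0.67–0.90 moves the
recovered μ_s′(633 nm) of transverse-like synthetic spectra by under 10%
(about 4% in our tests). This is why an effective anisotropy from a
forward-limited goniometer is an acceptable LUT input.

## Transmission scenarios

The bundled 810-nm property sets are transverse (light along fibers)
μ_a = 0.0013 mm⁻¹, μ_s = 1.87 mm⁻¹, g = 0.70 and longitudinal (light across
fibers) μ_a = 0.0013 mm⁻¹, μ_s = 43.4 mm⁻¹, g = 0.80, in the standard
13.8 × 13.8 × 50 mm volume with a 200-μm fiber. μ_a here is taken directly
as the water-scaled value at 810 nm rather than recomputed, keeping this
module independent of the water table.

A physical orientation point: with escaping lateral boundaries the fitted
transverse slope is dominated by lateral leakage, not absorption. A lowest
duct-mode diffusion estimate, κ = sqrt(μ_a/D + 2(π/L_eff)²) with
D = 1/(3(μ_a + μ_s′)) ≈ 0.59 mm and L_eff the lateral width plus two
extrapolation lengths, gives κ ≈ 0.28 mm⁻¹ for the transverse set — an
order of magnitude above the infinite-medium μ_eff = sqrt(3μ_a(μ_a + μ_s′))
≈ 0.047 mm⁻¹. The simulated slope (≈ 0.26–0.27 mm⁻¹ at 10⁶ photons) agrees
with the duct-mode estimate; the tests assert this physics through the
lateral-extent sensitivity check (halving the lateral size increases the
slope). Reported slopes therefore depend strongly on the lateral boundary
assumption, which is exactly why the geometry, window, and boundary rule are
explicit, configurable, and embedded in every output. The simulated
transmitted fraction through a 13.8-mm length of transverse-property tendon
is ≈ 0.03, within an order of magnitude of the 0.17 measured in bench
power-transmission experiments; mechanisms absent from a bulk-parameter MC
(fiber-scale light guiding, total internal reflection at fascicle
boundaries) plausibly account for the remainder.

## Synthetic data: what it does and does not show

The goniometer generator draws intensity(θ) = model(θ)(1 + ε) + floor with
seeded Gaussian ε (default 2% relative, of the order of shot-to-shot
variability on averaged scans) and a stray-light floor (default 0.2% of the
on-axis peak, emulating the ~0.1 μW wide-angle offsets real scans show).
The spectra generator runs the forward slab MC per wavelength, divides both
channels by a loss factor K_true (default 1.22, which puts raw R_d + T_t
near 0.82 at 500 nm, the magnitude of real sphere losses) and applies 1%
relative noise. All generators are pure functions of (truth, seed);
fixture bundles are byte-reproducible and ship a JSON truth manifest.

Passing round-trip tests on these data demonstrates that the estimators are
unbiased and well-conditioned under the modeled noise — multiplicative
detector noise, Monte-Carlo shot noise, uniform losses. They do not
exercise systematics real instruments add: non-uniform port losses (the
single-K assumption), detector-switch artifacts near 800 nm, hemoprotein
absorption at 415 nm, beam decollimation, or sample damage. One such
systematic is quantified in the tests: an unmodeled stray-light floor at
0.2% of peak biases recovered g_eff low by about 0.03, because the fit has
no background term — the recovery tolerances (g_eff within 0.02) hold for
noise-only scans, and fits of floor-contaminated scans should be read with
that bias in mind. No background subtraction is applied by default.

## Problem sizes and tolerances

Default test problem sizes were chosen so the full suite exercises every
claim at meaningful statistical power: slab benchmarks at 2×10⁵–10⁶
photons, lookup tables at 2×10⁴ photons/cell on 12×14 grids spanning the
synthetic-spectra coefficient range, spectra at 10⁵ photons/wavelength × 25
wavelengths, and volume scenarios at 0.6–2×10⁵ photons on 0.2-mm voxels
(the acceptance script uses 10⁶). Recovery tolerances quoted throughout
(a within 5%, b within 0.15, K within 0.05; g_eff within 0.02) are met with
margin at these sizes. The roulette threshold (10⁻⁴, survival 0.1) bounds
the energy-ledger defect below 10⁻³.

## Known limitations

* Anisotropy enters the transport only through orientation-specific bulk
  parameters; individual fibers, cylindrical scattering, polarization, and
  light guiding are not modeled.
* The single-K loss correction and water-only absorption are approximations
  inherited from the measurement model; both are flagged above.
* The water table is a compact digitization; inter-knot values are
  approximate at the tens-of-percent level.
* Volume boundaries are index-matched; Fresnel boundaries are implemented
  for the slab only.
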