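# Methods

## Scope and model family

`elastowave` models small-amplitude mechanical waves in soft biological
tissue represented as a linear elastic, nearly incompressible,
transversely isotropic (NITI) material that carries a static normal
prestress. Three geometries are covered, all with closed-form dispersion:

1. **Bulk** — an unbounded medium under triaxial normal prestress
   (σx, σy, σz, tension positive, no shear prestress): nine axis-aligned
   propagation/polarization pairs, and the angle-dependent slow/fast
   shear branches under uniaxial fiber-aligned stress.
2. **Plate** — a thin plate (thickness h ≪ shear wavelength, axis of
   isotropy normal to the plate) under in-plane biaxial tension σ: the
   2-D waveguide model for the cornea, where σ is the Laplace hoop
   stress P·r/(2h) induced by intraocular pressure.
3. **Beam** — a thin fiber-aligned rod under uniaxial tension: the 1-D
   waveguide model for slender muscle.

On top of the forward models sits a measurement-emulation and inversion
layer that fits stiffness and tension jointly from dispersion data.

## Material parameterization

A NITI material is (κ, μ⊥, η, φ, ζ, ρ):

| symbol | meaning | default / typical | units |
|---|---|---|---|
| κ | bulk modulus | 2.6 GPa (soft tissue; κ/μ⊥ ~ 1e6) | Pa |
| μ⊥ | shear storage modulus in plane of isotropy | 2.77 kPa (case study) | Pa |
| η | loss factor, Im/Re of both shear moduli | 0–0.15 | — |
| φ | shear anisotropy μ∥/μ⊥ − 1 | 1 (muscle-like) | — |
| ζ | tensile anisotropy E∥/E⊥ − 1 | 2 (muscle-like) | — |
| ρ | density | 1000 | kg/m³ |

Only three stiffness parameters beyond κ are independent:
E∥ = μ⊥(4ζ + 3) and E⊥ = E∥/(1 + ζ). Admissibility requires
1 + φ > 0, 4ζ + 3 > 0 and 1 + ζ > 0; negative φ, ζ are accepted down to
these bounds without clamping. A single helper returns the third-order
Landau coefficient A = −6μ for which finite-strain isotropic
acoustoelasticity reduces to this small-strain formulation.

### Stiffness-matrix entry derivation

The published form of the 6×6 stiffness matrix is typographically
ambiguous about how ζ groups inside the off-diagonal entries. The
entries used here,

    C11 = C22 = κ + μ⊥(4/3 + 4ζ/9)      C12 = κ − μ⊥(2/3 − 4ζ/9)
    C13 = C23 = κ − μ⊥(2/3 + 8ζ/9)      C33 = κ + μ⊥(4/3 + 16ζ/9)
    C44 = C55 = μ⊥(1 + φ)               C66 = μ⊥

were reconstructed to satisfy simultaneously (a) the coefficient
identities the governing equations of motion require,
C12 + C66 = κ + μ⊥(1/3 + 4ζ/9) and C13 + C55 = κ + μ⊥(1/3 + φ − 8ζ/9),
and (b) the zero-stress diagonal of the bulk plane-wave table
(C11/ρ, C33/ρ, C44/ρ, C66/ρ equal the corresponding axis-aligned ρc²/ρ).
Both consistency conditions are asserted in the test suite, as is
symmetric positive definiteness over wide random parameter ranges
(κ/μ⊥ ≥ 10, −0.7 < ζ ≤ 10, −0.9 < φ ≤ 10).

## Time convention and loss

All harmonic fields carry exp(i(γx − ωt)). Under this convention a
Kelvin–Voigt-type loss contributes a **negative** imaginary part to the
complex moduli, μc = μR(1 − iη): only then does the forward propagating
root k = ω√(ρ/μc) acquire Im(k) > 0 and decay in +x. The sign lives in
one constant (`materials.LOSS_IMAG_SIGN`); η is reported as the
magnitude ratio |Im|/Re. Loss is a single frequency-independent factor
applied to every modulus (μ⊥, μ∥, E⊥ hence D and Dxy, E∥) — no
rheological frequency dependence is modeled. For lossy media the
reported "phase speed" is ω/Re(k) with the root of positive real part;
attenuation is |Im(k)| in Np/m.

## Waveguide branch algebra and numerics

Both waveguides reduce to R γ⁴ + T γ² − m ω² = 0 with (R, T, m) =
(D, σh, ρh) for the plate and (E∥I, σA, ρA) for the beam; a single
shared core solves it. Writing ξ = T/(2R), a² = R/m and
s = √(ξ² + ω²/a²), the roots are ±α, ±iβ with α² = s − ξ, β² = s + ξ.

*Cancellation.* When ξ² ≫ ω²/a² (tension/membrane regime) the smaller
radicand s − |ξ| loses up to eight digits if evaluated literally. The
core instead computes the smaller root as (ω²/a²)/(s + |ξ|), which is
cancellation-free and makes the product identity α²β² = ω²/a² exact to
about one ulp. The difference identity β² − α² = 2ξ then holds to
relative 1e−10 whenever 2ξ is representable at the scale of the roots;
below eps·β² it is limited by floating point itself, which the tests
acknowledge with an absolute floor of 1e−12·(α² + β²).

*Lossy roots.* With complex R the principal square roots are the
analytic continuation of the lossless roots: α², β² rotate continuously
off the positive real axis as η grows and remain in the right
half-plane for any physical η, so no root re-matching or homotopy step
is needed; Re(α) > 0 and Im(α) > 0 (decay) are verified in tests, as is
continuity (the lossy Re(α) stays within a few percent of the lossless
α at η = 0.1).

*Compression.* σ < 0 is accepted; for ω > 0 both roots stay real and
positive. ω ≤ 0 is rejected. There is no buckling analysis anywhere in
the package: a bulk entry whose ρc² real part becomes non-positive
under compressive prestress raises an instability error naming the
offending propagation/polarization pair rather than returning an
imaginary speed.

*Limits.* c_ph = ω/Re(α) approaches √(σ/ρ) (membrane/string) when
σh ≫ 2D (σA ≫ 2E∥I) and ω^(1/2)(R/m)^(1/4) (classical plate /
Euler–Bernoulli beam) in the opposite limit; tests pin both at 0.1%
when ξ ≥ 100·ω/a resp. ξ ≤ 1e−4·ω/a. Neither limit coincides with the
bulk shear speed √((μ⊥(1+φ) + σ/2)/ρ) of the same material — the
waveguide effect is not a small correction, which is why `regime_index`
(ξ·a/ω with configurable thresholds 100 / 0.01) is exposed for the
beam. Rotational inertia is neglected (no Mindlin shear correction),
external load q = 0 (free waves), and there is no fluid loading or
foundation stiffness.

## Case-study presets

*Cornea.* Geometry r = 10 mm, h = 0.6 mm, ρ = 1000 kg/m³, νxy = 0.499
(in-plane near-incompressibility; D diverges at ν = 0.5, so ν ≤ 0.4999
is enforced). Two published stiffness configurations are shipped rather
than reconciled: E⊥ = 30 kPa (the tension-sweep configuration,
`CORNEA_PLATE_FIG_SWEEP`) and E⊥ = 50 kPa (the configuration whose
rigidity rounds to D = 1.2×10⁻⁶ N·m, `CORNEA_PLATE_BASE`). The preset
μ⊥ = E⊥/(2(1+ν)) ≈ E⊥/3 is the isotropic in-plane value; it enters only
the twisting rigidity Dxy and therefore none of the 1-D dispersion
results. mmHg→Pa is fixed at 133.322, which reproduces the printed hoop
stresses 5.56/11.11/16.67/22.22 kPa at IOP 5/10/15/20 mmHg after
rounding to two decimals. The sweep analyses are lossless over
100 Hz–5 kHz by default; both are configurable assumptions (no loss
factor or frequency band is prescribed for these sweeps).

*Muscle.* PCSA presets: cat soleus 1 cm² (circular section,
r = 5.64 mm, I = 7.96×10⁻¹⁰ m⁴), with human-range endpoints 0.68 cm²
and 21 cm². E∥ built from the NITI material via E∥ = μ⊥(4ζ + 3)
(30.47 kPa for the case-study material). Only fiber-aligned flexure is
modeled; torsional and longitudinal modes, Timoshenko shear correction
and active contraction are out of scope. At f = 10 Hz and σ ≥ 5 kPa
the soleus-like beam is within 2% of the string speed √(σ/ρ); at
σ = 2 kPa the bending term is no longer negligible and the deviation is
≈9% — the string approximation degrades at low tension, which the
regime index makes explicit.

## Synthetic measurements and inversion

These components are package-defined machinery (the waveguide models
themselves prescribe no inversion procedure); every choice below is a
package decision.

*Noise model.* Phase-speed samples are perturbed multiplicatively,
c → c·(1 + ε), ε ~ N(0, noise level) i.i.d. — elastography speed
estimates carry roughly relative error. An additive option (sd in m/s)
exists. All randomness flows through a caller-supplied integer seed via
`numpy.random.default_rng`; fixed (seed, parameters) reproduce
bit-for-bit.

What the generator deliberately does **not** emulate: frequency-
correlated errors, outliers from mode misidentification, finite
source/boundary effects, fluid loading, or spatial averaging of
heterogeneous tissue. Passing recovery tests therefore demonstrates the
estimator's correctness and conditioning under the stated noise model,
not field performance on real corneas or muscles.

*1-D wavefields.* `synth_wavefield_1d` superposes the four branch terms
Wj·exp(iγj·x); `estimate_phase_speed` recovers c = ω/(phase slope) by
least squares on the unwrapped phase, with a configurable window to
skip the evanescent near field. It requires ≥8 samples per wavelength
and a coherently advancing phase (≥ quarter cycle across the window,
residual scatter < 20% of the fitted span), raising a resolution error
otherwise; a 10% evanescent contamination fitted beyond three decay
lengths biases the estimate by < 1%.

*Fit.* Weighted nonlinear least squares of model c_ph(f; params) via
`scipy.optimize.least_squares` (TRF, bounded), residuals relative to
the data unless a per-point sd column supplies weights. Eight
multi-starts (first at the box center, the rest drawn uniformly in the
bounds from a dedicated rng; default seed 20220407), lowest residual
wins; non-convergence is flagged on the result rather than raised.
Standard errors come from the linearized covariance
s²(JᵀJ)⁻¹; identifiability is summarized by the condition number of the
column-scaled Jacobian, with 1e6 as the practical-non-identifiability
flag. An under-determined design (fewer distinct frequencies than free
parameters) raises an identifiability error up front.
`linearized_standard_errors` evaluates the same covariance at a given
truth so measurement designs (e.g. frequency bands) can be compared
without Monte-Carlo; because tension shapes the low-frequency end of
the curve, restricting data to 3–5 kHz strictly inflates the tension
standard error relative to the full 100 Hz–5 kHz band.

*Misattribution.* `apparent_shear_modulus` (ρc²) and
`misattribution_report` quantify what an observer assuming unstressed
bulk shear waves would conclude: in the string regime the apparent
modulus equals the tension σ regardless of the true moduli, and on a
tensioned plate it exceeds the zero-tension value at every frequency.

## Problem sizes and default study conditions

The recovery study design is: truth E⊥ = 30 kPa, σ = 11.11 kPa
(the 10 mmHg hoop stress), h = 0.6 mm, ρ = 1000 kg/m³; 25 frequencies
uniform on 100–5000 Hz; 1% multiplicative noise; 50 Monte-Carlo seeds.
Under these conditions the median absolute relative error of both
fitted parameters is ≈1%, and the Monte-Carlo spread agrees with the
linearized standard errors within a factor of two. Property tests use
1000 random parameter draws per invariant (500 plate + 500 beam).

## Known limitations

- Constant loss factor only; no poroelasticity or finite-strain
  hyperelastic strain-energy functions.
- No 2-D/3-D field solutions: point-source near fields, bounded-domain
  modes, fluid-loaded (Rayleigh–Lamb) plates and foundation-stiffness
  extensions are all out of scope.
- Branch names "slow"/"fast" follow the formulas, not a magnitude sort;
  the branches can cross for unusual (ζ − φ, σ) combinations.
- The inversion assumes the forward model's own family generated the
  data (no model-misspecification study).
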