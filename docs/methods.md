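# Methods

This note documents the models implemented in `vesiclense`, the numerical
choices behind them, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## The physical problem

Neutron spin echo (NSE) measures the normalized intermediate scattering
function S(q,t)/S(q,0) of lipid or surfactant vesicles over Fourier times
of nanoseconds to a microsecond, at wavevectors q ≈ 0.016–0.14 Å⁻¹.  In
that window the signal mixes three processes: thermally excited bending
undulations of the membrane, whole-vesicle translational diffusion, and,
through the normalization, the static size distribution of the ensemble.
The quantity of interest is the bending rigidity governing the
undulations.  Because at these scales the two leaflets cannot exchange
lipid fast enough to relax their density asymmetry, NSE probes an
*unrelaxed* rigidity κ̃ that is substantially larger than the relaxed κ of
quasi-static methods; the package keeps the two strictly apart.

## Mode spectrum of a finite vesicle

A quasi-spherical vesicle of radius R is expanded in spherical harmonics,
u(Ω,t) = R Σ a_lm(t) Y_lm(Ω).  With the Helfrich bending energy and a
lateral tension σ, the mode energy is

    E_lm = (κ̃/2)(l−1)(l+2)[l(l+1) + σ̄] |a_lm|²,  σ̄ = σR²/κ̃,

so equipartition gives the mean-square amplitudes

    ⟨|a_lm|²⟩ = k_BT / ( κ̃ (l−1)(l+2)[l(l+1)+σ̄] ).          (amplitudes)

Each mode relaxes exponentially with rate Γ_l = stiffness/friction.  The
friction was derived in-house by solving the Stokes equations inside
(viscosity η_in) and outside (η_out) the sphere for the kinematically
determined mode flow — the surface velocity is fixed by the radial motion
plus membrane incompressibility — and adding the Boussinesq–Scriven
dissipation of an incompressible membrane with surface shear viscosity
η_m.  Because the flow is fully determined by kinematics, the three
dissipation channels add exactly, giving

    Γ_l = κ̃ (l−1)(l+2)[l(l+1)+σ̄] · l(l+1) /
          { R³ [ η_in (l−1)(2l²+5l+5) + η_out (l+2)(2l²−l+2)
                 + 4 (η_m/R)(l−1)(l+2) ] }.                    (rates)

The derivation was performed symbolically (exact rationals, modes
l = 2…10, momentum balance and surface incompressibility asserted at every
step) and the closed forms above reproduce every exact value.  Checks:

* at η_in = η_out = η and η_m = 0 the bracket reduces exactly to the
  classical Milner–Safran denominator η(2l+1)(2l²+2l−1);
* the membrane-viscosity term decays relative to the solvent term as
  η_m/(η R l), so membrane viscosity matters least for large vesicles and
  decouples in the planar (large-l) limit, as it must for pure bending of
  a flat incompressible membrane;
* η_m enters the rates only, never the amplitudes.

The mode cutoff is l_max = floor(πR/δ) with δ the membrane thickness —
a shortest undulation wavelength of 2δ.  The relative mean-square
displacement is

    msd_rel(t) = Σ_{l=2}^{l_max} (2l+1)/(4π) ⟨|a_l|²⟩ (1 − e^{−Γ_l t}),

dimensionless; multiplying by 2R² gives the mean-square displacement of a
membrane point, whose t→∞ limit is twice the squared mean roughness
σ_R² = R² msd_rel(∞).  The correlation length reported alongside is
ξ = (κ̃/k_BT)^{1/2} σ_R; qξ ≫ 1 marks the regime where the classical
flat-membrane description applies.

Numerics: the mode sum is accumulated from l_max down to l = 2 so the
terms (which grow as l decreases) enter in increasing magnitude; the test
suite verifies agreement with exact term-by-term `fsum` accumulation to
better than 1e−10 relative over random parameter draws with cutoffs up to
several hundred modes.

## Dynamic structure factor

Per radius the normalized relaxation factorizes as

    S_R(q,t)/S_R(q,0) = exp(−q²R² msd_rel(t)) · exp(−D(R) q² t),

the Gaussian damping of scattering from a surface displaced along the
wavevector (q²·MSD/2 with MSD = 2R² msd_rel).  The ensemble curve averages
the numerator over the radius distribution with the thin-shell scattering
power R⁴F(qR), F(x) = (sin x/x)², and normalizes by its own t = 0 value —
the quantity a polydisperse measurement actually forms:

    S(q,t)/S(q,0) = ⟨R⁴F(qR) e^{−q²R² msd_rel(t)} e^{−D(R)q²t}⟩ / ⟨R⁴F(qR)⟩.

Choices and their reasons:

* **Size distribution.** Schulz (Gamma) by default, matching SANS
  practice; lognormal available.  The polydispersity parameter is the
  relative width s/⟨R⟩.
* **Quadrature.** 21-node Gauss–Legendre over ±4 distribution widths
  (clipped to R > δ).  Halving/doubling the node count changes typical
  curves by far less than the 1e−8 monodisperse-limit test tolerance.
* **Weighting.** Number density × R⁴F(qR).  The R⁴ factor is the squared
  scattering amplitude of a thin shell (area² at fixed thickness).
* **Diffusion.** Stokes–Einstein per radius node by default, because SANS
  radii translate directly to hydrodynamic radii for spherical shells.  A
  switch evaluates one D at the mean radius (legacy comparison), a fixed
  imposed D supports DLS-derived values, and a crowded mode multiplies by
  the hard-sphere short-time self-diffusion factor
  1 − 1.8315φ(1 + 0.1195φ − 0.70φ²), validated for φ ≤ 0.4.  An advisory
  is logged when the effective vesicle volume fraction
  φ = φ_lipid R³/(R³−(R−δ)³) exceeds 0.05.
* **Normalization.** Division by the t = 0 average guarantees
  S(q,0) = 1 to machine precision for all parameters.

**Consistency with the flat-membrane limit.**  For R = 5 µm, κ̃ = 50 k_BT,
σ = 0, η_m = 0, diffusion off, the model curve at q = 0.05 Å⁻¹ fits a
stretched exponential with free exponent β = 0.665 and dimensionless rate
prefactor Γ/[(k_BT/κ̃)^{1/2}(k_BT/η)q³] = 0.0243, within 3% of the
canonical 0.025 of the flat-membrane theory (the residual reflects the
discrete mode sum and the finite fit window).  This limit pins the
prefactor conventions of the whole model: any misplaced factor of 2 or 4π
in amplitudes, rates, or the exponent would shift it far outside 10%.

A structural consequence worth stating: the undulation factor never decays
below exp(−q²R² msd_rel(∞)), and at σ̄ = 0 the saturated sum is
msd_rel(∞) = 1/(12π κ̃/k_BT) exactly (the l-sum telescopes to 1/3).  Very
stiff membranes therefore still differ from pure diffusion by
≈ q²R²/(12π κ̃/k_BT) — about 1.5e−6 at κ̃ = 10⁵ k_BT even for 15 nm
vesicles at q = 0.016 Å⁻¹, and ~6e−5 under typical conditions.

## Classical stretched-exponential model

`zg_rate`/`zg_curve`/`zg_kappa_from_rate` implement
Γ_q = p·γ·(k_BT/κ)^{1/2}(k_BT/η)q³ and exp(−(Γ_q t)^{2/3}) with the
prefactor convention p ∈ {0.025 (theory), 0.0069 (empirical), custom} and
γ = 1 by default (valid for κ ≫ k_BT).  The exponent is fixed at 2/3 here;
free-exponent fits live in `stretch_characterize`, which seeds a nonlinear
bounded fit from the log–log linearization.

## Leaflet coupling

κ̃ = κ + 2k_m d² with monolayer compression modulus k_m and neutral-surface
height d; with K_A = 2k_m and the polymer-brush closure K_A = 24κ/t_hc²
this is κ̃ = κ(1 + 24(d/t_hc)²), giving the anchor ratio 7 at d = t_hc/2
and 25 at d = t_hc.  The inversion for d is exact.  Heights outside
[t_hc/2, t_hc] warn but evaluate; the closure is flagged (log notice) for
lipid names suggesting polyunsaturation, cholesterol or peptides, where
the polymer-brush relation is known to fail.

## Fitting

Trust-region-reflective weighted least squares (weights 1/err²), numerical
Jacobians, rigidity bounds [0.5, 1e5] k_BT, multistart from
{10, 50, 200, 1000} k_BT.  The multistart guards against the documented
low-q pathology where a very small rigidity inflates the undulation
amplitude to absorb imperfections in the diffusion description; estimates
that run into a bound are flagged `at_bound` rather than silently
reported.  Uncertainties are 1σ from the covariance scaled by the reduced
χ²; for the nearly degenerate (κ̃, η_m) pair a warning is emitted and, if
the Hessian condition number exceeds 1e12, uncertainties are refused and
the correlation matrix is reported instead.  All time points are used — no
plateau masking, since the model contains the plateau.  σ = 0 and η_m = 0
are the (logged) defaults, appropriate for isosmotic fluid membranes.

The optimizer, weighting and multistart policy are this package's own
choices; calibration is demonstrated empirically: on synthetic data the
reported 1σ intervals cover the truth in the binomially expected fraction
of replicates, and mean recovery over seeded replicate sets is unbiased at
rigidities 20–500 k_BT and radii 30–100 nm.

## Synthetic data

The generator evaluates the forward model on instrument-like grids —
`standard`: six q between 0.02 and 0.13 Å⁻¹, 25 log-spaced times to
500 ns; `long_time`: six q between 0.016 and 0.14 Å⁻¹ with the maximum
time 1 µs at the lowest q, tapering as 1/q — and adds Gaussian noise with
σ(t) = noise_level·(1 + t/t_max), a simple linear proxy for echo-amplitude
loss (not a calibrated instrument model).  The `err` column carries the
generating σ; truth parameters and the seed are embedded in the metadata
header, so fixtures are self-describing.  Default study conditions for the
recovery suites: 2% noise, 25% Schulz polydispersity, radii 30–100 nm,
rigidities 20–500 k_BT.

What passing these tests shows: the estimator recovers the generating
parameters without bias and with calibrated uncertainties *when the model
is correctly specified and the noise is additive, Gaussian, and honestly
reported*.  What they cannot show: robustness to instrument resolution
effects, background subtraction errors, multilamellarity (de Gennes
narrowing around the interlamellar correlation peak), inter-vesicle
structure factors at high concentration, or mis-specified size
distributions — all of which affect real data and are out of scope here.

## Degenerate and edge inputs

Radius ≤ membrane thickness is an invalid geometry error; a monodisperse
population evaluated exactly at a deep form-factor zero yields a warning
attached to the returned curve (the normalization becomes 0/0-like and the
shape is computed from the number weights instead); negative tension
(hypo-osmotic flaccid vesicles) is rejected as out of scope; fewer than 4
points in a stretched-exponential fit window raise an insufficient-data
error; q blocks with fewer than 4 time points are rejected on dataset
construction.

## Known limitations

* The two-leaflet (compression–dilation) *dynamics* are not modelled —
  only the static rescaling κ → κ̃.  The q-dependent crossover between the
  two rigidities therefore cannot be fitted, only diagnosed via the per-q
  rigidity profile.
* Thickness and tilt fluctuations, pore dissipation, and structured-fluid
  environments are outside the mode spectrum implemented here.
* The hard-sphere crowding correction ignores charge and softness.
* The thin-shell form factor ignores the membrane thickness; it enters
  only through the mode cutoff and the volume-fraction formula.
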