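# Methods

This note records the models implemented, the conventions and default
parameters, what the synthetic-data generators do and do not emulate,
and the numerical choices that matter.

## Units and conventions

Momentum transfer `q = 4π sin(θ)/λ` is carried in Å⁻¹ throughout;
readers accept nm⁻¹ and convert on input (1 nm⁻¹ = 0.1 Å⁻¹). SAXS
real-space lengths (R_g, correlation lengths, sphere radii) are in nm,
NR layer thicknesses and roughnesses in Å, SLDs in Å⁻², QCM-D masses in
ng/cm². Reflectivity stacks are traversed fronting-first with the beam
through the silicon substrate.

## Scattering length densities and contrast

A material is a formula (H and D distinct), a mass density, and a count
of labile hydrogens. Its SLD is ρ = Σ b_j n_j with embedded Sears bound
coherent scattering lengths. Each labile hydrogen contributes
`b_H + x·e·(b_D − b_H)` where `x` is the solvent D₂O fraction and `e`
the exchange efficiency (default 0.9, the usual allowance for buried
-OH/-NH sites; exposed as a parameter). The mass density is taken as
that of the protiated formula — H/D substitution at a few labile sites
changes the molar volume negligibly. Solvent SLD interpolates linearly
between pure H₂O (−0.56×10⁻⁶ Å⁻², 1.000 g/cm³) and pure D₂O
(6.36×10⁻⁶ Å⁻², 1.105 g/cm³); dissolved salt at the ~150 mM level
shifts the SLD by well under 1% and is neglected.

A hydrated layer mixes by volume: ρ_layer = φ·ρ_dry + (1−φ)·ρ_solvent,
with the exact algebraic inverse available. Mucin's dry composition is
not known well enough to compute its SLD from a formula, so the dry SLD
is a parameter; the defaults (4.54×10⁻⁶ in H₂O-equilibrated form,
5.09×10⁻⁶ in D₂O) are the values implied by inverting hydrated-layer
SLDs of 2.5×10⁻⁶ / 5.6×10⁻⁶ Å⁻² at 60% occupancy, and the pair is
interpolated linearly in solvent deuteration. They serve as consistency
checks of the exchange model, not as independent measurements.

## SAXS models

The printed forms of the coil and chain equations in the source
literature are typographically garbled; the canonical forms are
implemented:

- Debye function `P(q) = 2(e^(−x) + x − 1)/x²`, `x = (qR_g)²`, with a
  series expansion below x = 10⁻⁴ against cancellation.
- Guinier law `I = I₀ exp(−q²R_g²/3)`. Window selection is a fixed-point
  iteration: fit ln I vs q² on the current window, recompute
  `q_max = (qR_g limit)/R_g`, repeat until R_g moves < 0.1%; ties go to
  the widest admissible window, starting from the full curve. On
  Debye-generated data with the default limit qR_g ≤ 1 the recovered
  R_g is biased low by ~2–4% (window truncation of a non-Gaussian
  curve); this is documented and tested rather than corrected. If even
  the smallest measured q violates qR_g < 1 the result is flagged as a
  lower bound and should be read "R_g ≥ value" — the convention used
  for hundreds-of-nm clusters (gyration, not sphere, convention).
- Mucin dumbbell model: `I = I₁/(1 + ξ²q²) + I₂/(Ξq)ⁿ +
  scale·⟨P_sphere⟩·S_PY`. The first two terms are the Ornstein–Zernike
  chain term (correlation length ξ) and a low-q power law over the
  large-scale length Ξ; the globule term uses a Schulz radius
  distribution (default relative width 0.2) in the local-monodisperse
  approximation, i.e. the polydispersity-averaged sphere form factor
  multiplied by the monodisperse Percus–Yevick hard-sphere structure
  factor at the mean radius (default 10 nm). No published parameter set
  exists for the chain amplitudes, so the defaults are chosen to give
  the characteristic two-regime mucin shape and are recoverable by fit
  on synthetic data only.
- Percus–Yevick S(q): the Ashcroft–Lekner analytic solution, with a
  five-term Taylor series below A = 2qR = 0.5 to avoid trigonometric
  cancellation; S(0) then equals the compressibility closed form
  (1−φ)⁴/(1+2φ)² to machine precision.
- Mixture diagnostic: the additive prediction I_mucin + A·I_polymer is
  compared pointwise with a measured mixture on the same q grid (no
  silent interpolation). A positive low-q excess with slope ≈ −3.7
  (surface fractal: compact clusters) rather than ≈ −2.7 (mass-fractal
  gel network) is the clustering signature.

Coil interparticle interactions are neglected (S ≈ 1), appropriate for
the dilute (~1%) solutions targeted.

## QCM-D

The dissipation factor is implemented as printed in the source
convention, `D = 1/(f·τ₀)`; the textbook `D = 1/(π f τ)` is available
via a flag, since the printed form most likely drops the π. The
Sauerbrey constant is computed from AT-cut quartz constants
(ρ_q = 2648 kg/m³, μ_q = 2.947×10¹⁰ Pa), giving 17.7 ng/(cm²·Hz) at
5 MHz. Traces may store raw or overtone-normalised Δf; a flag declares
which, and all step deltas are reported both ways internally.

Protocol segmentation takes the injection times as given (they are
operator actions, not inferences); each step's plateau is the median of
the trailing 20% of its window (robust to injection transients;
fraction configurable, widened to ≥5 samples on sparse windows), and
step deltas are differences of consecutive plateaus. A step is "rigid"
when max |ΔD| across overtones ≤ 0.5×10⁻⁶ (inclusive); otherwise the
Sauerbrey result is flagged unreliable. Viscoelastic (Voigt) modelling
is out of scope.

Note an instructive inconsistency the arithmetic exposes: a 55 ng/cm²
deposit at ρ = 1.05 g/cm³ is 5.2 Å via d = Δm/ρ, while reflectometry
on the same films gives ~22 Å at 60% occupancy. The Sauerbrey figure is
a dry-mass-equivalent thickness and the NR figure a hydrated-layer
thickness (and Sauerbrey misses loosely coupled water); the package
reports the honest 5.2 Å rather than forcing agreement.

## Neutron reflectometry

Reflectivity is computed by the Parratt recursion over layer
wavevectors `k_j = √((q/2)² − 4π(ρ_j − ρ_fronting))`, with each Fresnel
coefficient damped by the Nevot–Croce factor `exp(−2k_j k_{j+1} σ²)`;
σ = 0 reduces exactly to the sharp-interface matrix result. The
kinematic (Born) form `R = 16π²/q⁴ |Σ Δρ_j e^{iqz_j} e^{−q²σ_j²/2}|²`
(the |ρ̃(q)|²/q² convention after integration by parts) serves as an
independent cross-check; it is quantitatively reliable only well above
all critical edges, so the automated comparison uses a weak-contrast
slab between index-matched media, where agreement is sub-percent for
q > 3q_c. Resolution smearing is a pointwise Gaussian with
σ_q = (dq/q)·q; the default dq/q = 0.10/2.355 treats the instrument's
10% wavelength spread as a FWHM.

Co-refinement shares all structural parameters (thicknesses, volume
fractions, roughnesses, fixed SLDs) across contrasts; each contrast
gets a free intensity scale (0.3–3) and constant background (0–10⁻⁴)
because beamline normalisation is rarely absolute. The optimiser is a
bounded trust-region least-squares solver on the concatenated weighted
residuals, with 5 seeded multi-starts (free parameters jittered by
±15% of their bound range) keeping the best χ². Parameter uncertainties
come from the covariance at the optimum.

Named scenarios provide the study stacks as synthetic-data truths and
fit initialisers: Si / SiO₂ (12 Å, SLD 3.47×10⁻⁶, roughness 3 Å —
assumed values, as the original fit tables are unpublished) and then
mucin 22 Å at φ = 0.60 (`bare_mucin`); a 70 Å polymer layer at φ = 0.25
on a slightly destabilised mucin layer (`mucin_polymer`), which after
`rinsed=True` becomes mucin 20 Å at φ = 0.50; a deuterated-chain DPPC
bilayer on a 4 Å water gap (`dppc_membrane`); the GM1-doped bilayer
with ~32% solvent penetration carrying a 30 Å mucin cover
(`dppc_gm1_mucin`); and the same plus polymer. The polymer dry SLD pair
(1.8/2.6×10⁻⁶) and all bilayer sub-layer values are declared
assumptions. Pipeline reports list explicitly which parameters were
fitted and which were held at these defaults.

## Synthetic data

Generators are deterministic given (parameters, seed) and embed both in
their metadata; tests never re-enter truth values by hand.

- SAXS: components on a log grid covering 7×10⁻⁴–0.6 Å⁻¹
  (7×10⁻³–6 nm⁻¹), relative Gaussian noise (default 2%) or scaled
  Poisson counts; the "interacting" mixture adds a q⁻³·⁷ cluster tail
  sized to dominate only the lowest decade.
- NR: forward model → smear → noise on a log grid 0.008–0.25 Å⁻¹.
  The default noise model is relative Gaussian with σ/R growing from a
  1% floor at R = 1 logarithmically to a 20% ceiling as R falls —
  an emulation of counting statistics without modelling the
  instrument. A Poisson-counts mode exists.
- QCM-D: staircase with exponential approach to each plateau (time
  constant 30 s — equilibration is reported as "minutes", the exact
  kinetics unpublished), 900 s per step, per-overtone white noise
  (0.02 Hz on Δf/n) and optional linear drift. The default five steps
  encode the deposition protocol: baseline, mucin (55 ng/cm²,
  ΔD = 0.3×10⁻⁶), stable rinse, polymer (Δf/n = −6 Hz), partial
  desorption on final rinse.

What passing recovery tests show: the estimators are unbiased and
precise under the assumed noise/resolution models. What they do not
show: robustness to instrument systematics absent from the generators —
multiplicative normalisation drift, non-Gaussian resolution tails,
background structure, temperature drift in QCM-D, or sample-to-sample
biological variability of mucin preparations.

## Numerical choices and degenerate inputs

- Curve readers reject non-monotonic q and non-numeric rows with the
  offending line; 2-column files yield unweighted fits.
- Reflectivity is clipped to [0, 1] against rounding at total
  reflection; complex square roots take the +Im branch.
- Guinier fixed-point tolerance 10⁻³ on R_g, ≥3 points enforced;
  power-law fits require ≥4 strictly positive points.
- A constant SAXS curve makes R_g unidentifiable: the fit reports
  non-convergence or a standard error exceeding the estimate rather
  than a silent number.
- The problem sizes used by the test-suite and the acceptance script
  (200-point SAXS curves, 90-point reflectivity curves per contrast,
  10 noise realisations for recovery scoring, 1 s sampling of QCM-D
  traces) are chosen to make every statistical statement stable at the
  stated tolerances while keeping a full run near-interactive.

## Known limitations

Voigt viscoelastic QCM-D modelling, absolute SAXS intensity
calibration, freeform SLD profiles, off-specular scattering and
instrument-specific resolution kernels are deliberately out of scope.
The dumbbell chain amplitudes and all membrane sub-layer parameters are
package defaults, not published values; conclusions drawn from them on
real data should treat them as starting points for refinement.
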