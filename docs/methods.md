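# Methods

## Scope and model

`liposcatter` analyses two scattering geometries that probe the same
chemistry — lipid transfer between apolipoprotein-stabilised lipid
discs and planar model membranes:

1. **Specular neutron reflectometry** of a supported lipid bilayer on a
   silicon block, measured in several H₂O/D₂O buffer contrasts and
   co-refined against one structural model.
2. **Small-angle neutron scattering** of the free nanodisc particles in
   three buffer contrasts, fitted with an elliptical core–shell bicelle
   form factor.

### Slab reflectivity

A sample is an ordered stack of homogeneous layers between semi-infinite
silicon and solvent. Each layer carries thickness t (Å), real SLD ρ
(1e-6 Å⁻²), an interfacial Gaussian roughness σ (Å) to the previous
layer, and a solvent volume fraction φ; the optical SLD is
(1−φ)ρ + φρ_solvent (SLDs mix by volume). Reflectivity is computed by
the Abelès 2×2 characteristic-matrix recursion; roughness enters as
Nevot–Croce damping exp(−2·k_n·k_{n+1}·σ²) of each interfacial Fresnel
coefficient. The error-function slicing alternative was not
implemented; at the roughness values relevant here (≤10 Å) the two
treatments agree well inside the instrumental resolution, and
Nevot–Croce is the standard closed form. Zero-thickness layers are
dropped before matrix evaluation so no degenerate interface enters.

The supported-bilayer parameterisation is symmetric
(heads–tails–heads): both headgroup layers share thickness, coverage
and SLD, and one roughness applies to all membrane interfaces. An
optional pure-solvent gap below the membrane and an optional
protein/particle layer on top complete the five-layer variant; either
is omitted when its thickness is zero.

Instrument resolution is applied per point as a Gaussian of fwhm dq
(constant dq/q = 7 % for the emulated time-of-flight reflectometer),
evaluated by 17-node Gauss–Legendre quadrature with Gaussian weights
over ±3.5σ, renormalised so constants are preserved exactly. A
limitation worth knowing: at the total-reflection edge the smeared
curve has a kink, and any fixed-order rule is accurate there only to
~0.3 % (verified against dense numerical convolution); everywhere else
agreement is ≤0.1 %. Fit residuals are insensitive to this at the 3 %
noise level of the data the package targets.

### Multi-contrast co-refinement

All contrasts of one sample share the structural parameters; each
dataset has a scale and flat background nuisance. The joint
χ² = Σ((R_model·scale + bkg − R_obs)/dR)² is minimised by
`scipy.optimize.differential_evolution` (population 15×n_params by
default, latin-hypercube init, seeded, `updating="deferred"`) followed
by a Nelder–Mead polish; the differential-evolution + derivative-free
combination mirrors the genetic optimisers traditional in
reflectometry software while being exactly reproducible from the seed.
Parameter uncertainties come from Monte-Carlo resampling: each
resample perturbs every data point by Gaussian(0, dR) and re-polishes
from the best fit; σ is the standard deviation over resamples. Nested
models are compared with the F-test
F = ((χ²_r − χ²_f)/(dof_r − dof_f))/(χ²_f/dof_f) under the
normal-residual assumption; its type-I error calibration is exercised
in the test suite on simulated nulls.

The mean molecular area MMA = V/(t_leaflet·coverage) links head and
tail layers of a physical bilayer. It is available as a soft penalty
(`mma_volumes=(V_head, V_tail)` adds weight·(excess over 5 %)² to the
objective). The penalty is *opt-in* rather than always-on: after an
incubation the tail region is a lipid mixture (or lipid + protein)
whose effective molecular volume differs from the pure lipid's, so
blanket enforcement with pristine volumes would bias exactly the fits
the decomposition relies on. Pristine-bilayer fits should enable it.

### Composition decomposition

With tail-deuterated membranes and unlabelled particles, the dry
(solvent-corrected) tail SLD after incubation is modelled as a
two-component mixture. For rHDL incubations: d-lipid + h-lipid, giving
exchange % = 100(ρ_d − ρ_obs)/(ρ_d − ρ_h); protein contributions to
the core are neglected because only ~1 % of particles remain on top
and three contrasts cannot separate a third component. For lipid-free
protein incubations: d-lipid + protein, giving
φ_prot = (ρ_d − ρ_obs)/(ρ_d − ρ_prot). A fitted dry SLD outside the
two-component interval (beyond a 2 % tolerance) raises an error rather
than extrapolating — it signals model mis-specification. Exchange
values are volume fractions; `volume_to_mole_fraction` converts with
molecular volumes. Lipid removal is the signed coverage difference
100(c_before − c_after). Co-localisation uses equal-area slabs:
100·φ_core·t_core/(φ_core·t_core + φ_top·t_top).

Kinetics slices are single-contrast (H₂O-buffer) measurements, so per
slice only {tail SLD, tail solvation} are considered fitted; the series
reports three metrics per slice (solvent change, exchanged fraction,
and the combined replaced-lipid fraction
1 − φ_lip(t)x_d(t)/φ_lip(0)x_d(0)) rather than collapsing them into
one ambiguous scalar. Note a hard identifiability limit: within one
contrast the tail SLD and tail solvation enter the optical model only
through the same effective slab SLD, so a single-contrast fit cannot
separate them — one of the two must be frozen (or the combined metric
used); the full separation needs the three-contrast characterisation
before and after the kinetics run.

### Nanodisc SANS

The particle is three coaxial elliptical cylinders: chain core
(half-height L/2, L = 28 Å by default), headgroup faces extending to
L/2 + t_face, and a protein rim of constant width d_belt spanning the
full height. The belt ellipse uses semi-axes (a + d_belt, εa + d_belt)
— the standard constant-width approximation. "Radius" means the minor
semi-axis a; this is the only reading under which the printed
short–long diameters (2(a+d), 2(εa+d)) come out consistently.
Each cylinder's amplitude is V·Δρ·sinc(q·h·cosα)·2J₁(u)/u with
u = q·r(ψ)·sinα, r(ψ) = a·sqrt(cos²ψ + ε²sin²ψ); the orientation
average runs over α (weight sinα) and ψ on [0, π/2] by Gauss–Legendre
quadrature, order 40 by default for standalone evaluation (converged to
≤1e-7 vs order 80) and order 20 inside fits (≤1e-5, far below the 2 %
data noise); orders below 8 are refused. I(q) = scale/V_outer·⟨|F|²⟩ +
background, in cm⁻¹ for SLDs in 1e-6 Å⁻² and lengths in Å. Optional
Gaussian wavelength smearing (9 % fwhm) uses 9 quadrature nodes
(2e-4 converged). No size polydispersity and no structure factor:
the particles are assumed dilute and monodisperse, matching how such
data are conventionally modelled.

Protein and headgroup SLDs vary with solvent through labile-hydrogen
exchange, parameterised by (sld_in_h2o, sld_in_d2o) endpoints with
linear interpolation; the default protein pair (1.86, 3.11), with 90 %
exchange efficiency folded into the D₂O endpoint, self-consistently
contrast-matches at ~42 % D₂O, and silicon (2.07) at 38 % — the two
match points the measurement design relies on. Headgroup faces carry
30 % hydration by default. Buffer salts are neglected in the solvent
SLD (linear H₂O/D₂O mixing).

### Disc geometry chain

From the fitted shape: circumference
C = 2π·sqrt(((a+d)² + (εa+d)²)/2) (the quadratic-mean ellipse
perimeter approximation — exact for a circle, and within the inscribed/
circumscribed bounds for all ε tested); residues in contact
round(C/1.5 Å); maximum single-chain belt 299·1.5 = 448.5 Å; area per
lipid 2V_chain/L; lipids per leaflet round(πa·εa/APL); proteins per
disc ceil(2C/448.5) under the double-belt picture (one belt per
leaflet; a partial belt still needs a whole protein). Counts round
half-away-from-zero. The unrounded circumference feeds the residue
count — rounding first would lose a residue. The ceiling rule for
proteins per disc is a geometric reconstruction; complementary
evidence (phosphate analysis) is outside the package's scope.

## Synthetic data

The generators emulate reduced instrument output, not raw detectors:

- NR: 120 log-spaced q points over 0.01–0.3 Å⁻¹, dq/q = 7 % fwhm,
  three contrasts (h-TBS x=0, cmSi x=0.38, d-TBS x=1), Gaussian noise
  dR = max(3 %·R, 1e-8).
- SANS: 150 log-spaced points over 0.002–0.3 Å⁻¹, 9 % wavelength fwhm,
  contrasts (h-TBS, 42 % d-TBS, d-TBS), flat incoherent backgrounds
  0.05/0.03/0.005 cm⁻¹ (H-rich buffers scatter more incoherently),
  noise dI = max(2 %·I, 1e-4).
- Kinetics: h-TBS-only slices whose tail SLD follows a prescribed
  exchanged-fraction trajectory.

Noise levels are typical of reduced data from these instrument classes.
Each contrast gets an independent child RNG stream from the recipe
seed, so noise realisations never correlate across contrasts and the
output is byte-identical for a fixed seed. What the generators do *not*
emulate: footprint/gravity corrections, off-specular background,
multiple scattering, detector-resolution tails, or sample imperfections
(SLD gradients, inhomogeneous coverage). Passing recovery tests
therefore demonstrate the *statistical* identifiability of the
parameters under honest counting noise, not robustness to systematic
instrument effects.

## Numerical and scale choices

- Optimiser budgets in the test suite and acceptance runs are scaled to
  single-CPU execution: NR fits use popsize 8–10 and ≤100 generations
  (the objective landscape at three free parameters is unimodal near
  truth); SANS fits use quadrature order 16–20 with the 9-node smearing
  rule. Monte-Carlo uncertainties use 6–20 resamples, enough to
  estimate σ within the factor-two accuracy the recovery criteria need.
- The recovery grid test covers exchange ∈ {10, 25, 40} % crossed with
  removal ∈ {0, 5, 10} % at one seed per condition; the single-condition
  deep tests use 20 MC resamples.
- Fits refusing to converge return a flagged (`converged=False`) result
  rather than raising; degenerate inputs (zero dR, zero coverage,
  decreasing timestamps, out-of-interval dry SLDs) raise `ValueError`
  with the offending quantity named.

## Known limitations

- Specular, one-dimensional SLD profiles only; no magnetic scattering,
  no off-specular analysis, no raw-data reduction.
- The two-component decomposition cannot distinguish a protein bent
  across core and heads from separate proteins in each region, and for
  rHDL incubations it attributes the whole core SLD change to lipid
  exchange (any protein insertion balanced between heads and tails is
  absorbed into that number).
- The F-test assumes independent Gaussian residuals; strongly smeared
  neighbouring points are mildly correlated, so borderline p-values
  near the 0.05/0.1 reporting thresholds deserve caution.
- The belt circumference formula is an approximation to the true
  ellipse perimeter; at ε ≤ 2 it is accurate to well under the fitted
  radius uncertainty, but it degrades for very elongated discs.
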