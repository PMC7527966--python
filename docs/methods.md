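# Methods

## Pattern simulation

A crystal structure is six lattice parameters, a list of symmetry operators
as coordinate triplets, and the asymmetric-unit sites in fractional
coordinates. Sites are expanded by applying every operator and merging
images that coincide within 10⁻³ in every fractional coordinate
(minimum-image convention); 10⁻³ of a unit cell is below any physically
meaningful distinction and is standard crystallographic practice.

Reflections are enumerated over the full hkl sphere with
|h|,|k|,|l| ≤ ⌈max(a,b,c)/d_min⌉ where d_min = λ/(2 sin θ_max); this bound
is a superset of the window for every cell shape and avoids per-space-group
multiplicity tables. For each hkl inside the scan window the interplanar
spacing comes from the reciprocal metric tensor of the general triclinic
cell, and the squared structure factor is

    |F|² = |Σⱼ occⱼ · fⱼ(s) · exp(−Bⱼ s²) · exp(2πi h·xⱼ)|²,  s = sin θ/λ,

summed over symmetry-expanded sites with neutral-atom Cromer–Mann form
factors (packaged 4-Gaussian coefficients for H, C, N, O, Mg, Ca; ionic
corrections are far below matching noise). Symmetry-equivalent reflections —
identical d within 10⁻⁵ Å and identical |F|² within 10⁻⁶ relative — merge
into one entry whose multiplicity counts the family; |F|² below 10⁻⁸ of the
strongest reflection is treated as a systematic absence. Kinematic
intensities are I = m·|F|²·LP with the unpolarized Lorentz–polarization
factor LP = (1+cos²2θ)/(sin²θ cos θ).

The continuous pattern places a unit-area pseudo-Voigt (Lorentzian fraction
η, shared FWHM) at each reflection, scaled by its intensity, on a uniform
grid, then normalizes to max = 100. Defaults: λ = 1.5406 Å (Cu Kα₁; an
optional flag adds Kα₂ at 1.5444 Å with half weight), scan 20–60° at 0.02°,
FWHM 0.15°, η = 0.5 — typical values for a laboratory diffractometer
measuring carbonate powders. Simulation is fully deterministic. No
preferred orientation, absorption or microabsorption corrections are
applied: the matching stage compares peak positions and relative
intensities, which these effects perturb only secondarily.

## Phase matching

The experimental diffractogram is linearly resampled to the evaluation grid
(20–60° at 0.02°, 2001 points), optionally background-subtracted (a
polynomial of configurable degree fitted to rolling minima over a ~2°
window; off by default, since the synthetic fixtures carry no background),
clipped at zero and normalized to max 100.

Both the experimental pattern and each candidate's simulated pattern are
then represented by a continuous model of normalized intensity versus 2θ:

* **spline** (default): cubic smoothing spline on the [0,1]-scaled angle
  axis with penalty λ = 10⁻⁹ — small enough to keep 0.15°-wide peaks at
  full height (noise-free training MAE ≈ 0.1 units) while damping
  grid-scale noise; fully deterministic.
* **network**: a single-hidden-layer tanh regressor (64 units) trained
  full-batch by L-BFGS for up to 2000 iterations from a seed-determined
  initialization (default seed 42). 64 units is the narrowest single layer
  that resolves the ~30 pseudo-Voigt peaks of a carbonate scan; at half
  that width the model blurs the spectrum enough that the probability prior
  can override the spectral evidence for weakly probable phases. The
  network path exists for method-robustness checks; the spline is preferred
  for bit-reproducibility.

Candidates are scored by MAE/p: the mean absolute error between the two
models on the evaluation grid, divided by the candidate's formation
probability. The probability is a Boltzmann softmax over per-atom formation
energies (eV, Materials Project convention) at an effective temperature
T_eff = 10⁴ K, at which the ~0.3 eV/atom spread among plausible CaCO₃
polymorphs gives a strong but non-degenerate prior (most-stable : least-
stable ≈ 1.4 : 1 among the four fixture phases). T_eff is exposed so the
sensitivity of a ranking to the prior can be audited. Scores are sorted
ascending with ties broken by lower formation energy; candidates without an
atomic structure cannot be simulated and are excluded from both the ranking
and the probability normalization, with a logged warning. The score is
invariant under positive rescaling of the experimental intensities.

The packaged catalog lists 14 CaCO₃ polymorph entries (Materials Project
identifier, space group, formation energy, band gap, cell volume, site
count, density). Every stored density is reproducible from the volume, the
site count and the CaCO₃ molar mass (40.078 + 12.011 + 3×15.999 g/mol,
Avogadro 6.02214076×10²³) to within 0.002 g/cc.

## Voigt–Reuss–Hill elasticity

For hexagonal and trigonal crystals with constants C₁₁, C₁₂, C₁₃, C₃₃, C₄₄
and C₆₆ = (C₁₁−C₁₂)/2 (GPa):

    B_V = [2(C₁₁+C₁₂) + 4C₁₃ + C₃₃]/9
    G_V = [7C₁₁ − 5C₁₂ + 12C₄₄ + 2C₃₃ − 4C₁₃]/30
    B_R = C²/M,  C² = (C₁₁+C₁₂)C₃₃ − 2C₁₃²,  M = C₁₁+C₁₂+2C₃₃−4C₁₃
    G_R = 5C²C₄₄C₆₆ / [6B_V C₄₄C₆₆ + 2C²(C₄₄+C₆₆)]

Voigt assumes uniform strain (upper bound), Reuss uniform stress (lower
bound); Hill's estimate is their arithmetic mean. E and ν follow from each
(B, G) pair via E = 9BG/(3B+G), ν = (3B−2G)/(2(3B+G)); the report also
prints the per-column mean of the three schemes. Born stability (C₄₄ > 0,
C₁₁ > |C₁₂|, (C₁₁+C₁₂)C₃₃ > 2C₁₃²) is enforced before averaging and, for
this symmetry class, guarantees M > 0 and hence positive Reuss moduli.

An alternate `variant="as_printed"` reproduces two bulk-modulus forms that
circulate in the applied literature (B_V with +C₃₃+C₁₃ and B_R with
denominator C₁₁+C₁₂+C₃₃−C₁₃). The standard forms are the default: the G_V
coefficient set above is exactly the expansion of the generic hexagonal
Voigt average that the standard B_V/B_R belong to, so the variant forms are
best read as typographic contractions. Trigonal tensors carry C₁₄ (and
C₁₅), but the averaging deliberately uses the hexagonal-form expressions;
C₁₄/C₁₅ are stored and reported only. A strict full-trigonal Reuss average
(which involves C₁₄²) is out of scope.

Ductility classification follows the empirical Poisson's-ratio criterion:
ν < 0.26 brittle, ν ≥ 0.26 ductile, evaluated on the Hill row. Reported
tables are rounded to three decimals (round-half-even) with full precision
retained in machine-readable output.

## Assay arithmetic

Precipitate mass is W_total − W_paper (filter gravimetry; a negative
difference is rejected as a measurement-order error). Strength gain is
100·(treatment − control)/control percent, reported to one decimal.

## Synthetic fixtures

`micphase.fixtures` generates everything the tests consume:

* **Reference structures.** Calcite uses the real R-3c description
  (hexagonal setting, Ca 6b, C 6a, O 18e with x = 0.2568) with the cell
  scaled to the catalog volume (density 2.614 g/cc). The vaterite-like
  fixture carries genuine P6₅22 operators and the catalog cell volume
  (90 atoms, 2.547 g/cc) but synthetic asymmetric-unit coordinates: it
  reproduces the symmetry, stoichiometry and density of the hexagonal
  polymorph, not its true atomic arrangement. Two decoys (Pmmn, 10 atoms;
  a C222₁-type cell doubled to 20 atoms because that group has no order-2
  orbits) complete the candidate set at their catalog densities. All
  operator lists are produced by closing small generator sets under
  composition, so each fixture is guaranteed a consistent group.
* **Measurement noise.** Seeded Gaussian noise (s.d. = a fraction of the
  pattern maximum; default 2%) plus an optional polynomial background,
  clipped at zero. It emulates counting noise amplitude, not its Poisson
  statistics, nor Kα₂ doublets, texture, sample displacement or instrument
  aberrations — so recovery results bound performance under idealized,
  single-phase, well-calibrated conditions, not under every real-world
  artifact.
* **Random elastic tensors.** Rejection sampling from uniform ranges
  (C₁₁, C₃₃ ∈ [50, 400]; C₁₂, C₁₃, C₄₄ ∈ [10, 150]; trigonal
  C₁₄ ∈ [−30, 30] GPa) until Born stability holds; deterministic per seed.

## Verification problem sizes

The bundled checks run the recovery experiment at 20 seeded 2%-noise trials
for each of the four fixture phases (plus four noise-free self-matches,
which must be exact to MAE < 10⁻⁶), the bound-ordering sweep at 1000 random
tensors, and the diffraction-kernel oracles (brute-force complex summation;
explicit reciprocal-basis construction) at 100 random cases each — sizes at
which every property has been stable across seeds while the whole suite
stays fast.

## Known limitations

* Identification assumes a single-phase sample; there is no mixture or
  phase-fraction decomposition, and no Rietveld-style full-profile
  refinement.
* Candidates are matched only if an atomic structure is supplied; catalog
  entries without structures do not participate.
* The formation-energy prior treats catalog energies as eV/atom; the
  functional form (softmax at T_eff) is a declared modeling choice, not a
  thermodynamic derivation.
* Elastic averaging ignores C₁₄/C₁₅ for trigonal crystals (hexagonal-form
  equations) and computes no directional/anisotropic moduli or temperature
  dependence.
* The vaterite-like and decoy fixture coordinates are synthetic; tests
  demonstrate recovery among distinct, symmetry-correct candidates, not
  against experimentally refined vaterite coordinates.
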