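# micphase

Crystal-phase identification and polycrystalline elasticity for microbially
induced calcium carbonate (MICP) biominerals.

Bacteria such as calcifying *Lysinibacillus* strains raise the pH of their
medium and precipitate CaCO₃, a process exploited to strengthen and self-heal
cement. Which polymorph forms — trigonal calcite (R3c), metastable hexagonal
vaterite (here a P6₅22 model), or something rarer — controls the mechanical
value of the deposit. `micphase` answers two questions about such a
precipitate from routine laboratory data:

1. **Which crystal phase is it?** Powder-XRD patterns are simulated from
   candidate crystal structures (Bragg positions from the reciprocal metric,
   kinematic intensities `I = m·|F|²·LP`, pseudo-Voigt peak profiles, Cu Kα,
   20–60° 2θ). A continuous model of normalized intensity vs 2θ is fitted to
   both the experimental and each simulated spectrum — a smoothing spline by
   default, or a small seeded neural network — and each candidate *i* is
   scored by

   `score_i = MAE_i / p_i`, with `p_i = exp(−E_i/kT_eff) / Σ_j exp(−E_j/kT_eff)`,

   where `MAE_i` is the mean absolute error between the two spectral models
   and `p_i` a Boltzmann weight over per-atom formation energies from a
   packaged 14-entry catalog of CaCO₃ polymorphs. The lowest score
   identifies the phase: spectral disagreement is penalized, thermodynamic
   plausibility rewarded.

2. **How stiff is it?** Single-crystal elastic constants C₁₁, C₁₂, C₁₃,
   C₃₃, C₄₄ (with C₆₆ = (C₁₁−C₁₂)/2) are converted to polycrystalline
   moduli by the Voigt–Reuss–Hill average: B_V, G_V (uniform-strain upper
   bounds), B_R, G_R (uniform-stress lower bounds), Hill's midpoints, then
   `E = 9BG/(3B+G)` and `ν = (3B−2G)/(2(3B+G))`, with ν ≥ 0.26 classifying
   the aggregate as ductile.

The package also covers the surrounding assay arithmetic (precipitate
gravimetry, biocement compressive-strength gain) and ships a synthetic-data
module (`micphase.fixtures`) that generates reference structures, seeded
noisy diffractograms and random Born-stable elastic tensors, so the whole
pipeline is testable offline.

## Worked example

Identify the phase of a noisy simulated vaterite spectrum among four
candidates (`python examples/identify_phase.py`):

```
ranking for a 2%-noise vaterite spectrum (lower score = better match):
rank id         group      MAE    prob    score
   1 mp-560265  P6522    0.649  0.2824    2.298
   2 mp-3953    R3c      5.175  0.2851   18.153
   3 mp-3205    Pmmn     5.231  0.2340   22.350
   4 mp-548403  C2221    5.653  0.1985   28.482
```

The MAE is in normalized-intensity units (patterns scaled to max 100); the
correct phase is eight times closer to the data than the best decoy, so the
ranking is robust to the probability prior. Elastic moduli of that phase
from its Voigt/Reuss bounds (`python examples/elastic_moduli.py`):

```
scheme      B/GPa    E/GPa    G/GPa     nu
Voigt      70.051   70.041   26.265  0.333
Reuss      64.113   67.243   25.371  0.325
Hill       67.082   68.647   25.818  0.329
Average    67.082   68.644   25.818  0.329
ductility class from the Hill Poisson ratio: ductile
```

A bulk modulus of ~67 GPa and ν ≈ 0.33 put this biogenic carbonate in the
range of limestone cement and well above ordinary Portland cement — the
basis for using such precipitates as a strengthening admixture. See also
`examples/simulate_pattern.py` and `examples/assay_arithmetic.py`.

A thin CLI wraps the same functions:

```sh
micphase catalog
micphase simulate --cif calcite.cif --out calcite.xy
micphase identify --experimental exp.xy --structures cifs/ --out report.json
micphase elastic --constants c.yaml --symmetry trigonal --out vrh.json
micphase assay strength --treatment 37.02 --control 29.05
micphase fixtures --out fixtures/ --seed 42
```

## Documentation

`docs/methods.md` describes the models, their assumptions, all tunable
parameters with defaults, what the synthetic fixtures do and do not emulate,
and known limitations.
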