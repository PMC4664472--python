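# confsel

Comparative NMR mapping of conformational equilibria in allosteric proteins,
built around the tandem cAMP-binding domains (CBD-A and CBD-B) of the PKA
regulatory subunit RIα.  The package is for NMR spectroscopists and
structural biologists who have per-residue backbone amide chemical shifts
for several ligation states and/or ¹⁵N relaxation data, and want to turn
them into state populations, interface maps and residual-dynamics profiles.

## What it computes

**Two-state populations from chemical shifts.**  Under fast exchange between
an "active" and an "inactive" conformation, every observed amide shift is the
population-weighted average of the endpoint shifts,
δ_obs = p·δ_inactive + (1−p)·δ_active.  Two independent estimators of the
inactive molar fraction p are provided:

- *CHESPA* (chemical-shift projection analysis): per residue, the
  perturbation vector **A** = δ_perturbed − δ_ref1 is projected onto the
  inter-state vector **B** = δ_ref2 − δ_ref1 in compounded (δH, α·δN) space,
  giving the fractional shift X = (**A**·**B**)/|**B**|² and the linearity
  statistic cos θ; residues with |cos θ| > 0.95 behave two-state and their
  mean X estimates p.
- *Correlation slopes*: the through-origin slope of
  (δ_apo − δ_cAMP) versus (δ_C − δ_cAMP) over a reporter-residue set equals
  p directly (total-least-squares by default, bootstrap errors, permutation
  null checks for mutant-vs-WT comparisons).

**Reduced spectral density mapping.**  R1, R2 and the heteronuclear NOE are
mapped algebraically into J(0), J(ωN) and J(0.87ωH) with Monte-Carlo error
propagation.  No exchange term is subtracted, so ms–µs exchange inflates
J(0) by exactly R_ex/(d²/2 + 2c²/3) — the working diagnostic for residual
slow dynamics.  Region averages over the conserved CBD elements (N3A, β2–3,
BBR, PBC, hinge) are produced in a summary-table layout.

**Rigid-body reference.**  Woessner spectral densities for each NH bond
vector in an axially symmetric rotational diffusor,
J(ω) = (2/5)·Σ_k A_k τ_k/(1+(ωτ_k)²), with the tensor supplied externally,
read from a hydrodynamics program's output, or estimated from the
structure's equivalent inertia ellipsoid via Perrin's relations.

**SASA interface maps.**  Shrake–Rupley solvent-accessible surface areas and
deletion-difference maps: deleting a domain (or a subunit chain) and
recomputing the SASA of the remainder flags exactly the residues that were
in contact with it.  A reporter selector returns residues far from every
functional interface.

**Synthetic data.**  Every input above can be generated with known ground
truth (seeded), so the full pipeline is testable without downloads.

## Worked example

```sh
python examples/01_two_state_populations.py
```

prints

```
CBD-A: inactive fraction = 0.497 +/- 0.005  (r = 0.9985, n = 60 points, truth = 0.5)
CBD-B: inactive fraction = 0.704 +/- 0.005  (r = 0.9992, n = 60 points, truth = 0.7)
```

Two synthetic domains were built in fast exchange with inactive fractions
0.5 and 0.7 plus realistic shift noise (0.005/0.025 ppm for ¹H/¹⁵N); the
through-origin slope of the shift-difference correlation recovers both
fractions within the bootstrap error, and r ≈ 1 confirms the two-state
picture.  The other scripts in `examples/` walk through CHESPA
(`02`), spectral density mapping with an exchange-broadened hinge (`03`),
rigid-body predictions (`04`), SASA interface maps (`05`) and the complete
workflow with JSON reports (`06`).

A thin CLI mirrors the library: `confsel simulate | chespa | populations |
jmap | predict | sasa-diff | run-all` (see `confsel --help`).

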