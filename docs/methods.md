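# Methods

This note records the models implemented in `confsel`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would want to know.

## Two-state fast-exchange model

All population inference assumes interconversion between one "active" and
one "inactive" conformation that is fast on the chemical-shift time scale,
so the observed shift of every nucleus is the population-weighted average

δ_obs = p·δ_inactive + (1−p)·δ_active,  0 ≤ p ≤ 1.

The two reference states must be measured (e.g. the cAMP₂-bound form for the
active endpoint and the catalytic-subunit-bound form for the inactive one).
Two caveats follow directly from the model and are surfaced in the reports:

- If a reference complex is transient (weak binding), its peaks sit part-way
  toward apo and the fitted p is an **upper bound**.  No correction is
  attempted.
- Per-residue linearity (|cos θ| in CHESPA, r in the correlation fit) is the
  internal control that the two-state assumption holds for the residues
  used; residues off the line are excluded, not averaged in.

### CHESPA

Perturbation vectors are built in compounded shift space (ΔδH, α·ΔδN).
The ¹⁵N weight α = 0.2 is the common one-fifth convention; the literature
does not agree on a single value, so α is a parameter everywhere and 0.2 is
documented as a convention, not a measurement.  X is defined as the scalar
projection normalised by |B|, i.e. (A·B)/|B|²; the signed-magnitude variant
|A|·sign(cos θ)/|B| is algebraically identical on exact data and differs
only in how numerical noise enters, so only the projection form is
implemented.  A residue whose perturbation vector has zero length has an
undefined angle; such records are flagged (`defined = False`) rather than
propagated as NaN.  `min_magB` (default 0.02 ppm compounded) drops residues
that cannot distinguish the reference states; the default is roughly 3× the
compounded shift reproducibility.

### Correlation slopes

The two-state model forces the correlation through the origin, so the fit
is through-origin by construction.  Both axes carry comparable shift noise,
hence the default estimator is through-origin **total least squares**
(closed form from the 2×2 second-moment matrix); ordinary least squares
through the origin is available as an option.  ¹H and ¹⁵N points are pooled
unscaled — each point's y/x ratio is internal to one nucleus, so no ¹⁵N
weighting is needed or wanted.  Slope errors come from a seeded bootstrap
over points (1000 resamples by default).  A reporter set whose reference
shift differences are all below 3× the per-nucleus noise floor
(0.005/0.025 ppm) cannot constrain the slope and raises
"reporters insensitive" instead of returning a meaningless number.

The null check (mutant-vs-WT differences against the inter-state axis)
reports Pearson r and a permutation p-value (10⁴ seeded shuffles).  The
verdict is "correlated" only when **both** |r| ≥ 0.5 and p ≤ 0.05: an
effect-size and a significance condition.  A significance-only rule would
misclassify 5% of true nulls by construction.

## Reduced spectral density mapping

The five-frequency ¹⁵N relaxation equations (dipolar + CSA) are collapsed
with the standard high-frequency approximation
J(ωH−ωN) ≈ J(ωH) ≈ J(ωH+ωN) ≈ J(0.87ωH) into three linear relations
(documented in `relaxometry.py`).  Consequences:

- The mapping inverts its forward relations exactly (round-trip residuals at
  machine precision); the approximation error appears only against data
  generated from the *full* five-frequency equations, where J(0) and J(ωN)
  are recovered well inside 5% for globular-protein parameters while the
  small high-frequency density carries the bulk of the approximation error
  (~15% relative, on a value two orders of magnitude smaller than J(0)).
- No exchange term is subtracted from R2, so R_ex adds exactly
  R_ex/(d²/2 + 2c²/3) to J(0).  Elevated J(0) is therefore the ms–µs
  diagnostic, by design rather than by accident.

Physical constants: r_NH = 1.02 Å, Δσ(¹⁵N) = −160 ppm, γN/γH = −0.10136,
all configurable; the dipolar constant d and CSA constant c = ωN·Δσ/√3 are
always derived from them, never hard-coded.  The reported high-frequency
axis is 0.87ωH by default and can be switched to ωH+ωN; the mapping algebra
is identical either way, only the frequency label and any model comparison
change.  Because published tables may use slightly different constants and
conventions, comparisons against external values should allow ~10%.

Errors are propagated by Monte-Carlo resampling of (R1, R2, NOE) from
independent Gaussians (default 1000 draws, seeded, bit-reproducible).  A
NOE above 1.05 is physically impossible for an amide and flags the record;
the mapping is still computed so the offending input stays visible.

## Rigid-body reference (Woessner model)

For an NH vector at angle α to the unique axis of an axially symmetric
diffusion tensor, J(ω) is the three-Lorentzian Woessner form with weights
(3cos²α−1)²/4, 3sin²α·cos²α, (3/4)sin⁴α and rates 6D⊥, 5D⊥+D∥, 2D⊥+4D∥.
The weights sum to 1 for every α and the isotropic limit reduces to a
single Lorentzian with τc = 1/(6D).  One subtlety worth recording: at fixed
τ_iso and α = 90°, J(0) decreases with increasing D∥/D⊥ only up to a ratio
of ≈2.3; beyond that the slowing of D⊥ dominates and J(0) rises again.
Globular two-domain proteins live well below the turnaround.

The fully anisotropic (three-value) extension is not implemented; a
non-axial tensor raises an error saying so.  Bead-model hydrodynamics is
out of scope — the module instead accepts (a) an externally computed
tensor, (b) per-residue J predictions read from TSV, or (c) a shape-based
estimate: principal axes from the coordinate second-moment tensor, spheroid
semi-axes a_i = √(5λ_i) (uniform-solid model), anisotropy from Perrin's
rotational friction relations (α-integrals evaluated by quadrature), and
the absolute scale fixed by a user-supplied τ_iso.  The estimate captures
the anisotropy axis and trend, not hydration detail; it is a surrogate, and
quantitative comparisons should prefer an externally computed tensor.

When amide protons are absent from a structure, H is placed opposite the
bisector of the N–CA and N–C(i−1) directions and the resulting vector is
flagged approximate.

## SASA and interface mapping

Shrake–Rupley with a deterministic golden-spiral quadrature (960 points and
a 1.4 Å probe by default), Bondi-type van der Waals radii, hydrogens
ignored by default (united-atom convention).  At 960 points the worst-case
error against the two-sphere analytic oracle is ≲0.4%, and the quadrature
is deterministic, so repeated runs agree bitwise.  Because the point grid
is fixed in the laboratory frame, rigid-body motion of the molecule changes
individual atom areas by up to ~1%; totals are stable well below that.

Deletion differences are computed as SASA(remainder alone) −
SASA(remainder within the full structure), which is non-negative by
construction.  The contact threshold (5 Å² by default) and an
"above mean + SD" mode are both provided; neither is canonical, both are
parameters.  Reporter selection takes explicit interface residue sets and a
minimum heavy-atom distance (8 Å default) — there is deliberately no
hidden default reporter list.

## Synthetic generators

The generators define the study conditions used by the tests and the
acceptance script:

- **Two-state tables**: inactive fractions 0.5 (CBD-A) and 0.7 (CBD-B);
  endpoint separations drawn once per residue from 0.02–0.3 ppm (¹H) and
  0.1–1.5 ppm (¹⁵N) with random signs, matching typical well-resolved amide
  cross-peak separations; apo shift noise 0.005/0.025 ppm.  Reporters are
  placed in the non-overlapping parts of the two domains (119–243 and
  269–379) so domain membership is unambiguous.
- **Relaxation**: S² = 0.85, τe = 50 ps, field 700.13 MHz; τc = 18 ns for
  the compact condition (a ~30 kDa tandem construct near 306 K) and 15 ns
  for the interface-disrupted condition, emulating the faster effective
  tumbling of two de-correlated domains; R_ex = 3 s⁻¹ confined to the
  CBD-A hinge (226–251), which produces a ~0.8×10⁻⁹ s/rad J(0) elevation
  there.  Rates are generated from the full five-frequency equations, so
  mapping them back probes the reduced-mapping approximation honestly.
- **Toy structures**: an ideal helix (well-defined NH vectors, all at the
  same angle to the helix axis — a property of ideal helices, useful to
  remember when a spread is expected), a two-lobe grid with a designed
  contact layer, and a uniform sphere cloud.

What the generators do **not** emulate: peak overlap and misassignment,
field-dependent exchange regimes (fast exchange is an assumption, not an
output), anisotropic or residue-specific CSA, correlated noise between R1
and R2, partial endpoint character of weak complexes, and real protein
packing.  Passing the synthetic tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to every pathology of
real spectra; the per-residue linearity filters are the first line of
defence on real data.

All randomness flows through explicitly passed seeded generators; there is
no global random state anywhere in the package.

## Problem sizes and determinism

Default test and acceptance problem sizes — 30 reporters per domain, 200
replicates per recovery point, 10⁴ permutation shuffles, 960 quadrature
points, 4000-atom point clouds — were chosen so each estimator's sampling
error sits well below the tolerance being asserted while the full suite
runs in well under a minute.  Reports are pure functions of (inputs,
config, seed) and serialise with sorted keys, so re-runs are byte-identical.

## Known limitations

- Fully anisotropic rotational diffusion is not supported.
- Model-free parameter fitting, relaxation dispersion and lineshape
  analysis are out of scope; rates are inputs, not outputs.
- The ellipsoid tensor estimate is shape-only and should not replace
  bead-model hydrodynamics where quantitative rigid-body curves matter.
- Population estimates inherit the endpoint-purity assumption; for weakly
  bound reference complexes they are upper bounds.
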