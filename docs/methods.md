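# Methods

This note documents the models behind copigkit, the parameters that matter,
the numerical choices, and what the synthetic generators do and do not
emulate.

## Colorimetry

**Stimulus.** Solution colour is measured in transmission against a solvent
blank, so the colorimetric stimulus is the transmittance
τ(λ) = 10^(−A(λ)), not the absorbance itself; the blank defines A = 0.
Negative measured absorbances (baseline noise) are clipped to zero with a
warning.

**Integration.** Tristimulus values are rectangle sums on the 1 nm grid over
380–770 nm:

    X = k · Σ τ(λ) S(λ) x̄(λ) Δλ,   k = 100 / Σ S(λ) ȳ(λ) Δλ

(similarly Y, Z), so unit transmittance returns the illuminant white point
with Y = 100 exactly. The CIE 1964 10° colour-matching functions and the
D65 spectral power distribution are embedded as the published 5 nm tables
and interpolated linearly to 1 nm. The white point computed from these
tables over 380–770 nm is (94.810, 100, 107.283); the tiny Z offset from
the full-range value (107.304) comes from truncating the near-UV/IR tails
and is irrelevant to differences between solutions measured under the same
tables.

**CIELAB.** Standard CIE 1976 forward transform with the two-branch
nonlinearity (branch point (6/29)³). Hue angles are reported in degrees on
(−180, +180] — *not* [0, 360) — because slightly bluish reds are naturally
expressed as small negative angles (the convention of the solution tables
this package works with). The −180° edge case of `atan2` is folded to +180°.

**λmax.** Band maxima are located on the integer grid inside a window
(default 480–580 nm, isolating the flavylium band from UV bands), ties
breaking toward the lower wavelength.

**Colour objects from published tables.** `CIEColor.from_lab` derives
chroma and hue exactly from a\*, b\* (consistency asserted to 1e−9 in
tests). Direct construction also accepts independently supplied chroma/hue
— needed when working from published tables whose columns are rounded
independently — and then validates only loosely (0.5 units). With such
rounded inputs the decomposition identity ΔL² + ΔC² + ΔH² = ΔE² can be
violated by the inputs themselves; the hue term is clamped at zero, which
for near-zero differences can push the contribution sum above 100%. With
exactly derived colours the identity holds to machine precision.

## Differential colorimetry

ΔE\*ab is the Euclidean distance in (L\*, a\*, b\*). The attribute
decomposition takes ΔC\*ab = C\*sample − C\*ref and defines the hue
component as the residual, ΔH = sign(Δhab)·sqrt(max(0, ΔE² − ΔL² − ΔC²)).
(The residual form is forced by dimensional consistency; squaring makes the
sign irrelevant to contributions.) Relative contributions are
%ΔX = 100·ΔX²/ΔE², undefined at ΔE = 0 and flagged rather than returned.
Visual detectability uses the conventional threshold: strictly above 3.0
CIELAB units.

## ITC

**Dilution bookkeeping.** The cell is a fixed-volume perfusion cell: each
2 µL injection displaces liquid into an overflow. With cumulative injected
volume ΔV, total concentrations follow the constant-volume displacement
model

    Mt = M0 (1 − ΔV/2V0) / (1 + ΔV/2V0),
    Lt = Lsyr (ΔV/V0) / (1 + ΔV/2V0),

equivalent to placing all injected titrant in an effective volume
V0 + ΔV/2 and removing an equal overflow share of titrate. A genuinely
sequential expel-after-mix ledger differs from this closed form at
O((ΔV/V0)²) — about 6×10⁻⁴ relative over a 19 × 2 µL schedule in a 200 µL
cell — so the model choice is isolated in `concentrations_after` and can be
swapped (e.g. for an exponential-dilution variant) without touching the
rest of the chain.

**Forward model.** For 1:1 binding, the bound complex concentration is the
closed-form mass-action root; the stoichiometry factor n scales the
effective titrate concentration. The cell heat content after injection i is
H_i = V0·ΔH·[ML]_i, and the measured heat is

    q_i = H_i − H_{i−1} + (ΔV/V0)(H_i + H_{i−1})/2,

the last term correcting for complex carried out with the displaced volume.
The sequential two-site model (M + L ⇌ ML, ML + L ⇌ ML2) solves the free
ligand concentration by bracketed Brent iteration (bracket [0, Lt], rtol
1e−14) and uses H = V0·(ΔH₁([ML]+[ML₂]) + ΔH₂[ML₂]). With ΔH = 0 all heats
are identically zero, and summed heats telescope exactly to the final bound
amount plus displacement terms (asserted in tests).

**Fitting.** Least squares via lmfit/Levenberg–Marquardt with K
parameterised as log10 K on [0, 20] and n ∈ [0.1, 10]; unit weights by
default, or per-injection standard deviations when the thermogram carries
them. Initial values: ΔH from the first-injection heat per mole injected,
log K from the reciprocal cell concentration at the half-heat point, n = 1;
a deterministic multi-start over log K ∈ {2, 4, 6, 8} guards against local
minima (tolerances 1e−10). Standard errors come from the Jacobian, with a
delta-method back-transform for K. Degenerate inputs raise: all-zero heats
(compared exactly — an absolute "close to zero" test would swallow real
microcalorie signals) or fewer than 5 usable injections. Fits with K at a
bound, or with the Wiseman sigmoidicity parameter c = K·n·M0 outside
[0.1, 1e4], are flagged as low-information rather than reported as precise.
An optional first-injection discard is off by default.

**Thermodynamics.** ΔG = −RT ln K with R = 1.9872 cal·mol⁻¹·K⁻¹ (all
energies in cal/mol), −TΔS = ΔG − ΔH by construction. Driving forces are
classified by sign quadrant: ΔH > 0 ∧ −TΔS < 0 → hydrophobic;
ΔH < 0 ∧ −TΔS > 0 → hydrogen bonding; both negative → both. Exact zeros are
indeterminate, and the both-positive quadrant (no spontaneous-binding
signature) is refused rather than mislabelled.

**A note on tight binders at low molar ratio.** At the strong-binder assay
conditions (200 µM cell, 250 µM syringe), 19 × 2 µL only brings the molar
ratio to ~0.24: the pigment stays in excess, every aliquot binds
completely, and the thermogram is flat at q ≈ ΔH·ΔV·Lsyr. Such a titration
determines ΔH·n but carries almost no information about K (it is past the
fittable c-range); the fit flags this instead of inventing precision.

## MD post-processing

**Census.** Each frame's contact edges define a graph over the declared
molecule set; connected components (networkx) of two or more molecules are
aggregates, classified by (pigment count : copigment count). Monomers are
excluded — a lone molecule is not a complex — so edgeless frames yield an
empty census. Class frequency is the fraction of frames containing at least
one component of the class, and the filter keeps classes with frequency
strictly above the threshold (default 0.05, the >5% rule). The frequency
denominator is a documented parameter choice: the original metric is
population of RMSD clusters, which is not reconstructible from contact
edges alone. Raw counts are always reported alongside the filtered view.

**MM/PBSA ledger.** ΔH_binding is the exact sum of the four components
(van der Waals, electrostatic, polar solvation, nonpolar solvation);
component SEMs propagate as the root sum of squares, which is symmetric
and monotone in each input. Relative energies ΔΔH are taken against the
minimum total (most stable compound, exactly 0). Ranking is by |ΔH_binding|
descending; adjacent compounds whose totals differ by at most
sqrt(SEM_a² + SEM_b²) are flagged "≈" (statistically indistinguishable),
and the order is invariant under a uniform shift of all totals.

## Synthetic generators

The generators emulate the *statistical structure* the analyses consume,
not the instruments' physics:

* **Spectra** — a single Gaussian visible band (default: centre 520 nm,
  height 0.40 AU, σ 40 nm, matching a ~50 µM pigment solution in a 10 mm
  cell), an optional UV band, a flat baseline and i.i.d. Gaussian noise.
  The copigmented preset (523 nm, 0.46 AU) reproduces the qualitative
  strong-copigment signature through the colour pipeline — darker, bluer,
  ΔE > 3 versus the control — and the band-shift λmax 520 → 523 nm. It does
  *not* reproduce the true anthocyanin band shape or absolute CIELAB
  coordinates of real solutions (a lone Gaussian band at these heights
  reads bluer than the measured wine-like colours), nor any pH-dependent
  speciation; passing tests therefore validate the analysis arithmetic and
  directionality, not instrument-level realism.
* **Thermograms** — the forward ITC model plus i.i.d. Gaussian noise with
  standard deviation expressed as a fraction of the largest |heat| (1% is a
  realistic peak-height noise level for integrated heats). Truth is
  retained for recovery scoring; `recovery_experiment` reports
  median/IQR/bias/relative RMSE over seeded replicates. The default
  benchmark (50 replicates at the weak-binder schedule) recovers the median
  K within a few percent.
* **Contact frames** — 5 pigments and 11 copigments (the simulated system
  composition); each requested aggregate class appears in a frame as an
  independent Bernoulli event at its target frequency, built on disjoint
  molecules and wired as a path (composition, not topology, is what the
  census reads). Realized frequencies converge to targets with binomial
  error; jointly infeasible targets are rejected at recipe construction.

All randomness flows through explicit integer seeds (numpy `default_rng`;
replicate seeds derived via `SeedSequence`), never global state.

## Problem sizes

The test suite and the reproduction script use deliberately desk-scale
problems: 19-injection titrations, 50-replicate recovery benchmarks,
200–10 000 contact frames, 10-spectrum oracle batches. These sizes give
comfortable statistical margins for every assertion while keeping a full
run in seconds.

## Known limitations

* No baseline/peak integration of raw ITC power traces; the package starts
  from integrated per-injection heats.
* The one-site/sequential two-site models cover the study's stoichiometric
  range; no global multi-experiment fitting.
* No CIEDE2000/CMC colour differences (the 1976 ΔE\*ab is the method under
  study), no scatter/baseline correction, no speciation modelling of the
  anthocyanin equilibria.
* The census consumes declared contact edges; the contact definition
  (distance cutoff, atom subsets) and trajectory clustering are upstream
  and out of scope.
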