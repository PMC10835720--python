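# copigkit

Analysis toolkit for **anthocyanin copigmentation** studies: the noncovalent
stacking of a red wine pigment (the flavylium cation of
malvidin-3-*O*-glucoside, Mv3G) with colourless phenolic copigments such as
quercetin 3-*O*-glucoside, caffeic acid, (−)-epicatechin, (+)-catechin and
gallic acid. The package implements the full quantitative chain such a study
needs, as a reusable library:

1. **Spectrophotometric colorimetry** — visible absorbance spectra
   (380–770 nm, 1 nm) → transmitted stimulus τ(λ) = 10^(−A(λ)) → CIE
   tristimulus values under the CIE 1964 10° observer and illuminant D65 →
   CIELAB (L\*, a\*, b\*, C\*ab, hab), plus the visible band maximum λmax.
2. **Differential colorimetry** — colour differences
   ΔE\*ab = [(ΔL\*)² + (Δa\*)² + (Δb\*)²]^1/2 against a reference solution,
   decomposed into lightness/chroma/hue via ΔH² = ΔE² − ΔL² − ΔC², with
   relative contributions %ΔX = 100·ΔX²/ΔE² and the ~3-unit visual
   detectability rule.
3. **Isothermal titration calorimetry (ITC)** — a forward heat model for
   serial-injection titrations (constant-volume displacement cell, 1:1 or
   sequential 1:2 mass action), blank correction, nonlinear least-squares
   estimation of (K, ΔH, n), and the derived signature
   ΔG = −RT ln K, −TΔS = ΔG − ΔH, with sign-based classification of the
   driving forces (hydrophobic vs hydrogen bonding vs both).
4. **MD post-processing bookkeeping** — a complex census over per-frame
   intermolecular contact graphs (aggregates classified by
   pigment:copigment composition, filtered at >5% frame frequency) and an
   MM/PBSA ledger (component sums, SEM propagation, ΔΔH relative energies,
   affinity ranking with SEM tie flags).
5. **Synthetic-data generators** — seeded instrument stand-ins (Gaussian-band
   spectra, noisy thermograms with retained ground truth, contact frames
   with known aggregate frequencies) so the whole chain is testable end to
   end, including a Monte-Carlo parameter-recovery harness for the ITC fit.

## Worked example

```python
import copigkit as ck

# CIELAB means of the control and the 1:2 quercetin-glucoside solution
control = ck.CIEColor(78.5, 46.0, 1.7, 46.1, 2.1)
copigmented = ck.CIEColor(77.6, 44.8, -4.2, 45.0, -5.4)

d = ck.color_difference(control, copigmented)
print(round(d.dE, 2))                        # 6.09  -> clearly visible (> 3)
print([round(p, 1) for p in d.contributions])  # [2.2, 3.3, 94.5]

dG, minus_TdS = ck.derive_thermodynamics(K=2.01e3, dH=-256.0, T=298.0)
print(round(dG))                             # -4504 cal/mol
print(ck.classify_forces(-256.0, minus_TdS)) # ForceClass.BOTH
```

The colour change of the strongly copigmented solution is 6.09 CIELAB units
— well above the ~3-unit visual threshold — and ~94.5% of it is a hue
rotation toward blue rather than a lightness or chroma change. The ITC
numbers give the free energy of a weak flavanol binder and show its binding
driven by both hydrogen bonds and hydrophobic contacts.

The `examples/` directory holds one short narrative script per capability
(`color_difference.py`, `spectra_to_color.py`, `itc_fit.py`,
`complex_census.py`, `mmpbsa_ranking.py`); each prints the numbers it
computes and a line on what they mean. A thin CLI mirrors the main entry
points: `copigkit color`, `copigkit diff`, `copigkit itc fit|simulate`,
`copigkit census`, `copigkit mmpbsa`, `copigkit synth ...`.

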