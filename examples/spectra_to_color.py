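"""From absorbance spectra to CIELAB colour.

Generates a synthetic flavylium control spectrum (visible band at 520 nm)
and a strongly copigmented spectrum (band shifted to 523 nm, higher), runs
both through the tristimulus/CIELAB chain under the CIE 1964 10-degree
observer and illuminant D65, and reports the colour change.
"""

import copigkit as ck

control = ck.make_spectrum(ck.control_recipe())
copigmented = ck.make_spectrum(ck.copigmented_recipe())

for s in (control, copigmented):
    c = ck.spectrum_to_cielab(s)
    print(
        f"{s.label:12s} lambda_max = {ck.lambda_max(s):5.0f} nm   "
        f"L* = {c.L_star:6.2f}  a* = {c.a_star:6.2f}  b* = {c.b_star:6.2f}  "
        f"h_ab = {c.h_ab:6.2f} deg"
    )

d = ck.color_difference(
    ck.spectrum_to_cielab(control), ck.spectrum_to_cielab(copigmented)
)
print(
    f"\ndE = {d.dE:.2f} (detectable: {ck.visually_detectable(d)}), "
    f"dL = {d.dL:.2f}, db = {d.db:.2f}"
)
print(
    "A +3 nm bathochromic shift with a stronger band reads as a darker "
    "(dL < 0), bluer (db < 0) and clearly visible (dE > 3) colour change."
)
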