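"""Differential colorimetry of pigment/copigment solutions.

Builds CIELAB colours from the published triplicate means of the
malvidin-3-O-glucoside (Mv3G) control and ten binary Mv3G/copigment
solutions, then tabulates the colour difference of each solution against
the control, its lightness/chroma/hue decomposition, and whether the
change would be visible to the eye (ΔE*ab > 3).
"""

import copigkit as ck

table = ck.reference.cielab_reference()
colors = {
    label: ck.CIEColor(r.L_star, r.a_star, r.b_star, r.C_ab, r.h_ab, label=label)
    for label, r in table.iterrows()
}
control = colors.pop("Mv3G_control")

report = ck.batch_report(control, list(colors.values()))
cols = ["label", "dL", "dC", "dH", "dE", "pct_L", "pct_C", "pct_H", "detectable"]
print(report[cols].round(2).to_string(index=False))

print(
    "\nOnly the quercetin-glucoside solutions cross the ~3-unit visual "
    "threshold; their change is ~94% a hue rotation toward blue "
    "(negative dH), not a lightness or chroma change."
)
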