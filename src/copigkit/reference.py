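"""Published reference measurements for malvidin-3-O-glucoside copigmentation.

Printed study values for the Mv3G flavylium cation (pH 1.1, 25 °C) paired
with five wine phenolic copigments — quercetin 3-O-β-glucopyranoside (QG),
caffeic acid (CA), (−)-epicatechin (E), (+)-catechin (C) and gallic acid
(GA) — at 1:1 and 1:2 pigment:copigment molar ratios:

* CIELAB colour parameters of the control and binary solutions (triplicate
  means, rounded as printed) with the reported ΔE*ab and λmax;
* ITC thermodynamic parameters (ΔG, K, ΔH, −TΔS) per interaction;
* the ITC injection schedules (cell/syringe concentrations) per compound;
* MM/PBSA binding-enthalpy components with SEMs for the 1:1 complexes.

These serve as worked inputs for the analysis chain and as cross-checks of
its arithmetic; they are instrument/simulation outputs, not quantities this
package computes.
"""

from __future__ import annotations

import pandas as pd

from .itc import InjectionSchedule
from .mdpost import EnergyDecomposition

__all__ = [
    "cielab_reference",
    "itc_reference",
    "itc_schedules",
    "mmpbsa_reference",
]


def cielab_reference() -> pd.DataFrame:
    """CIELAB parameters (L*, a*, b*, C*ab, hab), reported ΔE*ab and λmax.

    Index: solution label; the control row has no ΔE*ab.  Values are the
    printed triplicate means.
    """
    rows = {
        #                L*     a*     b*    C*ab   h_ab   dE     lmax
        "Mv3G_control": (78.5, 46.0,  1.7,  46.1,   2.1,  None,  520),
        "Mv3G_QG":      (78.0, 45.3, -1.6,  45.4,  -2.1,  3.41,  521),
        "Mv3G_QG2":     (77.6, 44.8, -4.2,  45.0,  -5.4,  6.11,  523),
        "Mv3G_CA":      (79.0, 45.6,  1.3,  45.6,   1.6,  0.84,  520),
        "Mv3G_CA2":     (79.1, 45.8,  1.1,  45.8,   1.3,  1.33,  519),
        "Mv3G_E":       (79.2, 44.9,  1.2,  44.9,   1.6,  1.36,  519),
        "Mv3G_E2":      (79.1, 45.4,  1.4,  45.5,   1.8,  1.09,  520),
        "Mv3G_C":       (79.1, 45.9,  1.8,  46.0,   2.2,  1.32,  520),
        "Mv3G_C2":      (79.1, 46.0,  1.7,  46.0,   2.1,  0.67,  519),
        "Mv3G_GA":      (79.2, 46.3,  1.8,  46.4,   2.3,  1.14,  520),
        "Mv3G_GA2":     (79.5, 44.7,  1.3,  44.7,   1.7,  1.72,  520),
    }
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["L_star", "a_star", "b_star", "C_ab", "h_ab", "dE_printed", "lambda_max"],
    )


def itc_reference() -> pd.DataFrame:
    """Reported ITC thermodynamics per interaction, all energies in cal/mol."""
    rows = {
        #              dG        K        dH       -TdS
        "Mv3G_QG":  (-1.22e4, 9.72e8,  -4.01e3, -8.23e3),
        "Mv3G_QG2": (-2.44e4, 8.40e17, -1.36e2, -2.43e4),
        "Mv3G_CA":  (-5.59e3, 1.27e4,  -1.39e1, -5.58e3),
        "Mv3G_CA2": (-1.03e4, 3.85e7,   2.74e2, -1.06e4),
        "Mv3G_E":   (-4.50e3, 2.01e3,  -2.56e2, -4.24e3),
        "Mv3G_E2":  (-8.96e3, 3.78e6,  -1.50e2, -8.81e3),
        "Mv3G_C":   (-2.96e3, 1.50e2,  -2.65e3, -3.19e2),
        "Mv3G_C2":  (-5.88e3, 2.08e4,  -3.16e3, -2.72e3),
        "Mv3G_GA":  (-3.09e3, 1.86e2,  -1.19e3, -1.90e3),
        "Mv3G_GA2": (-6.42e3, 5.15e4,  -1.21e3, -5.21e3),
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["dG", "K", "dH", "minus_TdS"]
    )


def itc_schedules() -> dict[str, InjectionSchedule]:
    """Assay schedules: 19 × 2 µL injections into a 0.2 mL cell at 298 K.

    Cell (pigment) / syringe (copigment) concentrations per compound, chosen
    in the study to reach saturation with adequate signal.
    """
    conc = {  # (cell µM, syringe µM)
        "QG": (200.0, 250.0),
        "CA": (400.0, 3000.0),
        "E": (800.0, 10000.0),
        "C": (1000.0, 10000.0),
        "GA": (1000.0, 10000.0),
    }
    return {
        name: InjectionSchedule(syringe_conc=s * 1e-6, cell_conc=c * 1e-6)
        for name, (c, s) in conc.items()
    }


def mmpbsa_reference() -> list[EnergyDecomposition]:
    """MM/PBSA binding-enthalpy components (cal/mol, value ± SEM) per 1:1 complex."""
    rows = {
        # label:        vdw,              elec,           polar,          nonpolar
        "caffeic_acid": ((-11.09, 0.23), (-0.74, 0.13), (2.33, 0.11), (4.04, 0.16)),
        "gallic_acid":  ((-10.76, 0.15), (-0.91, 0.08), (2.34, 0.08), (3.83, 0.11)),
        "catechin":     ((-16.12, 0.23), (-1.51, 0.12), (3.36, 0.10), (5.66, 0.14)),
        "epicatechin":  ((-17.69, 0.19), (-1.29, 0.12), (3.20, 0.10), (5.86, 0.12)),
        "quercetin":    ((-20.58, 0.19), (-1.07, 0.09), (3.45, 0.07), (6.73, 0.09)),
    }
    out = []
    for label, (v, e, p, n) in rows.items():
        out.append(EnergyDecomposition(
            label=label,
            vdw=v[0] * 1e3, electrostatic=e[0] * 1e3,
            polar_solv=p[0] * 1e3, nonpolar_solv=n[0] * 1e3,
            vdw_sem=v[1] * 1e3, electrostatic_sem=e[1] * 1e3,
            polar_solv_sem=p[1] * 1e3, nonpolar_solv_sem=n[1] * 1e3,
        ))
    return out


#: ΔH_binding totals as printed alongside the component table (cal/mol).
MMPBSA_PRINTED_TOTALS = {
    "caffeic_acid": -5.47e3,
    "gallic_acid": -5.50e3,
    "catechin": -8.61e3,
    "epicatechin": -9.92e3,
    "quercetin": -11.46e3,
}
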