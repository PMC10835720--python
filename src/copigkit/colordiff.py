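"""Differential colorimetry in CIELAB.

Colour differences between a pigment reference solution and
pigment/copigment solutions are expressed as the Euclidean distance

    ΔE*ab = [(ΔL*)² + (Δa*)² + (Δb*)²]^(1/2)

and decomposed into the perceptual attributes lightness, chroma and hue:
ΔC*ab = C*ab,sample − C*ab,reference and the hue component as the residual
ΔH² = ΔE² − ΔL² − ΔC² (signed by the hue-angle difference).  Relative
contributions %ΔL, %ΔC, %ΔH = 100·Δ(·)²/ΔE² quantify which attribute
dominates a colour change; differences above ~3 CIELAB units are taken as
visually detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .spectra import CIEColor

__all__ = [
    "ColorDifference",
    "color_difference",
    "percent_contributions",
    "visually_detectable",
    "batch_report",
    "DETECTABILITY_THRESHOLD",
]

DETECTABILITY_THRESHOLD = 3.0  # CIELAB units; strictly above is detectable


@dataclass(frozen=True)
class ColorDifference:
    """CIELAB difference (sample − reference) and its attribute decomposition."""

    dL: float
    da: float
    db: float
    dC: float
    dH: float
    dE: float
    label: str = ""

    @property
    def contributions(self) -> tuple[float, float, float]:
        return percent_contributions(self)

    @property
    def detectable(self) -> bool:
        return visually_detectable(self)


def color_difference(reference: CIEColor, sample: CIEColor) -> ColorDifference:
    """Compute ΔE*ab and its lightness/chroma/hue decomposition.

    The hue component magnitude is the residual sqrt(max(0, ΔE² − ΔL² − ΔC²)),
    signed by the hue-angle difference, so ΔL² + ΔC² + ΔH² = ΔE² identically.
    """
    dL = sample.L_star - reference.L_star
    da = sample.a_star - reference.a_star
    db = sample.b_star - reference.b_star
    dE = math.sqrt(dL * dL + da * da + db * db)
    dC = sample.C_ab - reference.C_ab
    dH2 = dE * dE - dL * dL - dC * dC
    dH = math.sqrt(max(0.0, dH2))
    if sample.h_ab < reference.h_ab:
        dH = -dH
    return ColorDifference(dL, da, db, dC, dH, dE, label=sample.label)


def percent_contributions(d: ColorDifference) -> tuple[float, float, float]:
    """Relative contributions (%ΔL, %ΔC, %ΔH), each 100·Δ(·)²/ΔE².

    Squares are used, so the sign of ΔH does not matter and the three terms
    sum to 100.  Undefined for a null difference.
    """
    if d.dE == 0:
        raise ValueError("contributions undefined for a zero colour difference")
    e2 = d.dE * d.dE
    return (
        100.0 * d.dL * d.dL / e2,
        100.0 * d.dC * d.dC / e2,
        100.0 * d.dH * d.dH / e2,
    )


def visually_detectable(d: ColorDifference) -> bool:
    """True iff ΔE*ab strictly exceeds 3 CIELAB units."""
    return d.dE > DETECTABILITY_THRESHOLD


def batch_report(reference: CIEColor, samples: list[CIEColor]) -> pd.DataFrame:
    """Tabulate CIELAB parameters, differences and contributions per sample.

    One row per sample against the shared reference; an empty sample list
    yields an empty table with the full column set.
    """
    cols = [
        "label", "L_star", "a_star", "b_star", "C_ab", "h_ab",
        "dL", "da", "db", "dC", "dH", "dE",
        "pct_L", "pct_C", "pct_H", "detectable",
    ]
    rows = []
    for s in samples:
        d = color_difference(reference, s)
        if d.dE > 0:
            pct_L, pct_C, pct_H = percent_contributions(d)
        else:
            pct_L = pct_C = pct_H = float("nan")
        rows.append({
            "label": s.label,
            "L_star": s.L_star, "a_star": s.a_star, "b_star": s.b_star,
            "C_ab": s.C_ab, "h_ab": s.h_ab,
            "dL": d.dL, "da": d.da, "db": d.db,
            "dC": d.dC, "dH": d.dH, "dE": d.dE,
            "pct_L": pct_L, "pct_C": pct_C, "pct_H": pct_H,
            "detectable": visually_detectable(d),
        })
    return pd.DataFrame(rows, columns=cols)
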