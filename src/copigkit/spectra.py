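"""Visible absorbance spectra and their conversion to CIELAB colour.

A transmission spectrophotometer measures absorbance A(λ) of a pigment
solution against a solvent blank.  The colorimetric stimulus is the
transmitted light, τ(λ) = 10^(−A(λ)) (Beer–Lambert), weighted by the
illuminant power and the observer colour-matching functions to give
tristimulus values X, Y, Z, from which the CIELAB coordinates
(L*, a*, b*, C*ab, hab) follow.

Hue angles are reported in degrees on (−180, +180]: slightly bluish reds
carry small *negative* hue angles rather than values near 360.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .observers import ObserverIlluminant, cie1964_d65

__all__ = [
    "Spectrum",
    "CIEColor",
    "absorbance_to_transmittance",
    "tristimulus",
    "xyz_to_lab",
    "lambda_max",
    "spectrum_to_cielab",
    "read_spectra_csv",
]

# CIELAB forward nonlinearity branch point
_DELTA = 6.0 / 29.0


@dataclass
class Spectrum:
    """A wavelength-indexed absorbance record on a uniform 1 nm grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance must be 1-D and equal length")
        d = np.diff(self.wavelengths)
        if len(d) and not np.allclose(d, 1.0):
            raise ValueError("spectrum grid must be strictly increasing at 1 nm spacing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if np.any(self.absorbance < 0):
            warnings.warn(
                "negative absorbance clipped to 0 (baseline noise)", stacklevel=2
            )
            self.absorbance = np.clip(self.absorbance, 0.0, None)

    def slice(self, lo: float, hi: float) -> "Spectrum":
        m = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        return Spectrum(self.wavelengths[m], self.absorbance[m], self.label)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths.min() <= lo and self.wavelengths.max() >= hi

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "Spectrum":
        """Read a two-column ``wavelength_nm,absorbance`` CSV."""
        df = pd.read_csv(path)
        return cls(
            df["wavelength_nm"].to_numpy(),
            df["absorbance"].to_numpy(),
            label or Path(path).stem,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "absorbance": self.absorbance}
        ).to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    """Read spectra from CSV: two-column single spectrum, or wide multi-sample.

    Wide layout: a ``wavelength_nm`` column plus one absorbance column per
    sample, the column header serving as the sample label.
    """
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError("spectra CSV must contain a 'wavelength_nm' column")
    w = df["wavelength_nm"].to_numpy()
    cols = [c for c in df.columns if c != "wavelength_nm"]
    if cols == ["absorbance"]:
        return [Spectrum(w, df["absorbance"].to_numpy(), Path(path).stem)]
    return [Spectrum(w, df[c].to_numpy(), c) for c in cols]


@dataclass(frozen=True)
class CIEColor:
    """CIELAB coordinates with the polar form (chroma, hue angle in degrees).

    Use :meth:`from_lab` to derive chroma and hue exactly from a*, b*.
    Direct construction accepts independently supplied (e.g. published,
    rounded) chroma/hue values; consistency is then only checked loosely.
    """

    L_star: float
    a_star: float
    b_star: float
    C_ab: float = None
    h_ab: float = None
    label: str = ""

    def __post_init__(self):
        if self.C_ab is None:
            object.__setattr__(self, "C_ab", math.hypot(self.a_star, self.b_star))
        if self.h_ab is None:
            h = math.degrees(math.atan2(self.b_star, self.a_star))
            if h <= -180.0:  # atan2(-0.0, a<0) returns exactly -180
                h += 360.0
            object.__setattr__(self, "h_ab", h)
        if abs(self.C_ab - math.hypot(self.a_star, self.b_star)) > 0.5:
            raise ValueError("chroma inconsistent with a*, b*")
        if not -180.0 < self.h_ab <= 180.0:
            raise ValueError("hue angle must lie in (-180, +180] degrees")

    @classmethod
    def from_lab(cls, L: float, a: float, b: float, label: str = "") -> "CIEColor":
        h = math.degrees(math.atan2(b, a))
        if h <= -180.0:
            h += 360.0
        return cls(L, a, b, math.hypot(a, b), h, label)


def absorbance_to_transmittance(s: Spectrum) -> Spectrum:
    """Convert absorbance to transmittance pointwise, τ(λ) = 10^(−A(λ)).

    Returns a :class:`Spectrum` whose ``absorbance`` field holds τ; with
    A ≥ 0 the result lies in (0, 1].
    """
    tau = np.power(10.0, -s.absorbance)
    out = Spectrum.__new__(Spectrum)  # bypass clip warning path; tau >= 0 anyway
    out.wavelengths = s.wavelengths.copy()
    out.absorbance = tau
    out.label = s.label
    return out


def tristimulus(s: Spectrum, oi: ObserverIlluminant | None = None) -> tuple[float, float, float]:
    """Integrate a transmitted-light stimulus to CIE tristimulus values.

    X = k·Σ τ(λ)·S(λ)·x̄(λ)·Δλ over 380-770 nm (likewise Y, Z) with
    k = 100 / Σ S(λ)·ȳ(λ)·Δλ, so a blank (τ = 1 everywhere) returns the
    illuminant white point with Y = 100.

    ``s`` is the *absorbance* spectrum; the transmittance link is applied
    internally.
    """
    if oi is None:
        oi = cie1964_d65()
    lo, hi = oi.wavelengths.min(), oi.wavelengths.max()
    if not s.covers(lo, hi):
        raise ValueError(f"spectrum must cover {lo:.0f}-{hi:.0f} nm for colorimetry")
    vis = s.slice(lo, hi)
    tau = np.power(10.0, -vis.absorbance)
    k = 100.0 / float(np.sum(oi.spd * oi.cmf_y))
    X = k * float(np.sum(tau * oi.spd * oi.cmf_x))
    Y = k * float(np.sum(tau * oi.spd * oi.cmf_y))
    Z = k * float(np.sum(tau * oi.spd * oi.cmf_z))
    return X, Y, Z


def _f(t: np.ndarray | float) -> np.ndarray | float:
    t = np.asarray(t, dtype=float)
    lin = t / (3.0 * _DELTA**2) + 4.0 / 29.0
    return np.where(t > _DELTA**3, np.cbrt(t), lin)


def xyz_to_lab(
    X: float, Y: float, Z: float, oi: ObserverIlluminant | None = None, label: str = ""
) -> CIEColor:
    """CIE 1976 L*a*b* from tristimulus values under the given white point."""
    if min(X, Y, Z) < 0:
        raise ValueError("tristimulus values must be nonnegative")
    if oi is None:
        oi = cie1964_d65()
    Xn, Yn, Zn = oi.whitepoint
    fx, fy, fz = _f(X / Xn), _f(Y / Yn), _f(Z / Zn)
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return CIEColor.from_lab(float(L), float(a), float(b), label=label)


def lab_to_xyz(
    color: CIEColor, oi: ObserverIlluminant | None = None
) -> tuple[float, float, float]:
    """Algebraic inverse of :func:`xyz_to_lab` (both nonlinearity branches)."""
    if oi is None:
        oi = cie1964_d65()
    Xn, Yn, Zn = oi.whitepoint

    def finv(ft):
        return ft**3 if ft > _DELTA else 3.0 * _DELTA**2 * (ft - 4.0 / 29.0)

    fy = (color.L_star + 16.0) / 116.0
    fx = fy + color.a_star / 500.0
    fz = fy - color.b_star / 200.0
    return Xn * finv(fx), Yn * finv(fy), Zn * finv(fz)


def lambda_max(s: Spectrum, window: tuple[float, float] = (480.0, 580.0)) -> float:
    """Wavelength of maximum absorbance within ``window`` on the integer grid.

    The default 480-580 nm window isolates the flavylium visible band from
    UV bands.  Ties break toward the lowest wavelength.
    """
    sub = s.slice(*window)
    if len(sub.wavelengths) == 0:
        raise ValueError("lambda_max window contains no grid points")
    return float(sub.wavelengths[int(np.argmax(sub.absorbance))])


def spectrum_to_cielab(s: Spectrum, oi: ObserverIlluminant | None = None) -> CIEColor:
    """Full chain: absorbance spectrum → transmitted stimulus → CIELAB."""
    if oi is None:
        oi = cie1964_d65()
    X, Y, Z = tristimulus(s, oi)
    return xyz_to_lab(X, Y, Z, oi, label=s.label)
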