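"""Observer/illuminant weighting tables for tristimulus integration.

The package evaluates colour under the CIE 1964 supplementary standard
observer (10 degree visual field) and CIE standard illuminant D65, the
conditions used for transmission colorimetry of pigment solutions.  The
packaged 5 nm tables are interpolated linearly onto the 1 nm integration
grid (380-770 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._cie_tables import CIE1964_CMF_5NM, D65_SPD_5NM

VISIBLE_GRID_NM = np.arange(380, 771)  # 1 nm steps, inclusive


@dataclass(frozen=True)
class ObserverIlluminant:
    """Colour-matching functions and illuminant power on a common 1 nm grid.

    Attributes
    ----------
    wavelengths : ndarray of int
        Wavelength grid in nm, strictly increasing at 1 nm spacing.
    cmf_x, cmf_y, cmf_z : ndarray
        Colour-matching function values per wavelength.
    spd : ndarray
        Relative spectral power of the illuminant per wavelength.
    """

    wavelengths: np.ndarray
    cmf_x: np.ndarray
    cmf_y: np.ndarray
    cmf_z: np.ndarray
    spd: np.ndarray
    _whitepoint: tuple = field(init=False, default=None, repr=False, compare=False)

    def __post_init__(self):
        w = np.asarray(self.wavelengths)
        if w.ndim != 1 or len(w) < 2 or not np.all(np.diff(w) == 1):
            raise ValueError("observer/illuminant tables must be on a uniform 1 nm grid")
        for arr in (self.cmf_x, self.cmf_y, self.cmf_z, self.spd):
            if np.asarray(arr).shape != w.shape:
                raise ValueError("table columns must share the wavelength grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError("table values must be finite")
        k = 100.0 / float(np.sum(self.spd * self.cmf_y))
        wp = (
            k * float(np.sum(self.spd * self.cmf_x)),
            k * float(np.sum(self.spd * self.cmf_y)),
            k * float(np.sum(self.spd * self.cmf_z)),
        )
        object.__setattr__(self, "_whitepoint", wp)

    @property
    def whitepoint(self) -> tuple[float, float, float]:
        """Tristimulus values (Xn, Yn, Zn) of unit transmittance; Yn = 100."""
        return self._whitepoint


def cie1964_d65(grid: np.ndarray | None = None) -> ObserverIlluminant:
    """Build the CIE 1964 10-degree observer / D65 weighting set.

    Parameters
    ----------
    grid : ndarray, optional
        Integration grid in nm at 1 nm spacing; defaults to 380-770 nm,
        the visible range used for solution colorimetry.
    """
    if grid is None:
        grid = VISIBLE_GRID_NM
    grid = np.asarray(grid)
    cmf = CIE1964_CMF_5NM
    return ObserverIlluminant(
        wavelengths=grid,
        cmf_x=np.interp(grid, cmf[:, 0], cmf[:, 1]),
        cmf_y=np.interp(grid, cmf[:, 0], cmf[:, 2]),
        cmf_z=np.interp(grid, cmf[:, 0], cmf[:, 3]),
        spd=np.interp(grid, D65_SPD_5NM[:, 0], D65_SPD_5NM[:, 1]),
    )
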