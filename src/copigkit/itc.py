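"""Isothermal titration calorimetry: forward model, fitting, thermodynamics.

A titration injects small aliquots of copigment (syringe, concentration
``syringe_conc``) into a fixed-volume cell of pigment (``cell_conc``).  Each
injection i displaces cell liquid, diluting both species; the instrument
integrates the heat q_i released by the change in bound complex.  Fitting
the heat-versus-molar-ratio curve with a mass-action binding model yields
the association constant K, the binding enthalpy ΔH and the stoichiometry
factor n, from which ΔG = −RT ln K and −TΔS = ΔG − ΔH follow.

Signs of ΔH and −TΔS classify the dominant driving force: positive ΔH with
negative −TΔS indicates hydrophobic association, negative ΔH with positive
−TΔS hydrogen bonding, and both negative a mixture of the two.

All energies are in cal/mol (R = 1.9872 cal·mol⁻¹·K⁻¹), volumes in litres,
concentrations in mol/L.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "R_CAL",
    "InjectionSchedule",
    "Thermogram",
    "BindingResult",
    "ForceClass",
    "UninformativeTitrationError",
    "concentrations_after",
    "bound_fraction",
    "simulate_thermogram",
    "subtract_blank",
    "fit_binding",
    "derive_thermodynamics",
    "classify_forces",
]

R_CAL = 1.9872  # gas constant, cal mol^-1 K^-1


class UninformativeTitrationError(ValueError):
    """Raised when a thermogram carries no usable binding signal."""


@dataclass(frozen=True)
class InjectionSchedule:
    """Cell/syringe concentrations and the injection sequence of one assay."""

    syringe_conc: float  # mol/L titrant (copigment)
    cell_conc: float  # mol/L titrate (pigment)
    cell_volume: float = 0.2e-3  # L
    injection_volume: float = 2e-6  # L per injection
    n_injections: int = 19
    temperature: float = 298.0  # K

    def __post_init__(self):
        for name in ("syringe_conc", "cell_conc", "cell_volume",
                     "injection_volume", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")
        if self.n_injections * self.injection_volume > self.cell_volume:
            raise ValueError("cumulative injected volume exceeds the cell volume")

    @classmethod
    def from_json(cls, path: str | Path) -> "InjectionSchedule":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def concentrations_after(schedule: InjectionSchedule, i: int) -> tuple[float, float]:
    """Total cell concentrations (Mt, Lt) after ``i`` injections.

    Constant-volume displacement model for an overfilled perfusion cell:
    with cumulative injected volume ΔV = i·dV,

        Mt = M0·(1 − ΔV/2V0) / (1 + ΔV/2V0)
        Lt = Lsyr·(ΔV/V0) / (1 + ΔV/2V0)

    i.e. injected titrant is diluted into an effective volume V0 + ΔV/2 and
    an equal share of the original titrate is carried out with the overflow.
    """
    if not 0 <= i <= schedule.n_injections:
        raise ValueError("injection index out of range")
    v = i * schedule.injection_volume / schedule.cell_volume  # ΔV/V0
    Mt = schedule.cell_conc * (1.0 - v / 2.0) / (1.0 + v / 2.0)
    Lt = schedule.syringe_conc * v / (1.0 + v / 2.0)
    return Mt, Lt


def bound_fraction(K: float, Mt: float, Lt: float) -> float:
    """Complex concentration [ML] for 1:1 mass action at totals (Mt, Lt).

    Root of K·(Mt−[ML])·(Lt−[ML]) = [ML], taken on the physical branch
    0 ≤ [ML] ≤ min(Mt, Lt).
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if Mt < 0 or Lt < 0:
        raise ValueError("total concentrations must be nonnegative")
    b = K * (Mt + Lt) + 1.0
    disc = b * b - 4.0 * K * K * Mt * Lt
    ml = (b - math.sqrt(max(disc, 0.0))) / (2.0 * K)
    return min(max(ml, 0.0), min(Mt, Lt))


def _species_two_site(K1, K2, Mt, Lt):
    """[ML] and [ML2] for sequential binding M + L ⇌ ML, ML + L ⇌ ML2."""
    if Lt == 0 or Mt == 0:
        return 0.0, 0.0

    def excess_ligand(L):
        M = Mt / (1.0 + K1 * L + K1 * K2 * L * L)
        return L + K1 * M * L + 2.0 * K1 * K2 * M * L * L - Lt

    L = brentq(excess_ligand, 0.0, Lt, xtol=1e-18, rtol=1e-14)
    M = Mt / (1.0 + K1 * L + K1 * K2 * L * L)
    return K1 * M * L, K1 * K2 * M * L * L


@dataclass
class Thermogram:
    """Integrated per-injection heats (cal) with the cumulative molar ratio."""

    heats: np.ndarray  # cal, signed
    molar_ratio: np.ndarray  # cumulative [titrant]/[titrate] in the cell
    label: str = ""
    sd: np.ndarray | None = None  # optional per-injection standard deviations

    def __post_init__(self):
        self.heats = np.asarray(self.heats, dtype=float)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        if self.heats.shape != self.molar_ratio.shape:
            raise ValueError("heats and molar_ratio must have equal length")
        if not np.all(np.isfinite(self.heats)):
            raise ValueError("heats must be finite")

    def __len__(self):
        return len(self.heats)

    @classmethod
    def from_csv(cls, path: str | Path, schedule: InjectionSchedule | None = None,
                 label: str | None = None) -> "Thermogram":
        """Read an ``injection,heat_cal[,sd_cal]`` CSV; the molar ratio is
        reconstructed from the schedule when one is given."""
        df = pd.read_csv(path)
        heats = df["heat_cal"].to_numpy()
        if schedule is not None:
            mr = molar_ratios(schedule)[: len(heats)]
        elif "molar_ratio" in df.columns:
            mr = df["molar_ratio"].to_numpy()
        else:
            mr = np.arange(1, len(heats) + 1, dtype=float)
        sd = df["sd_cal"].to_numpy() if "sd_cal" in df.columns else None
        return cls(heats, mr, label or Path(path).stem, sd)

    def to_csv(self, path: str | Path) -> None:
        d = {"injection": np.arange(1, len(self) + 1),
             "heat_cal": self.heats, "molar_ratio": self.molar_ratio}
        if self.sd is not None:
            d["sd_cal"] = self.sd
        pd.DataFrame(d).to_csv(path, index=False)


def molar_ratios(schedule: InjectionSchedule) -> np.ndarray:
    """Cumulative titrant/titrate molar ratio in the cell after each injection."""
    out = np.empty(schedule.n_injections)
    for i in range(1, schedule.n_injections + 1):
        Mt, Lt = concentrations_after(schedule, i)
        out[i - 1] = Lt / Mt
    return out


def simulate_thermogram(
    schedule: InjectionSchedule,
    K: float,
    dH: float,
    n: float = 1.0,
    K2: float | None = None,
    dH2: float | None = None,
    label: str = "simulated",
) -> Thermogram:
    """Forward model: per-injection heats for 1:1 (or sequential 1:2) binding.

    The heat content of the cell after injection i is
    H_i = V0·ΔH·[ML]_i (plus the second-step term for the sequential model),
    with the stoichiometry factor n scaling the effective titrate
    concentration.  The instrument sees

        q_i = H_i − H_{i−1} + (ΔV/V0)·(H_i + H_{i−1})/2

    where the last term corrects for bound complex carried out with the
    displaced volume.
    """
    V0 = schedule.cell_volume
    dV = schedule.injection_volume
    heats = np.empty(schedule.n_injections)
    H_prev = 0.0
    for i in range(1, schedule.n_injections + 1):
        Mt, Lt = concentrations_after(schedule, i)
        if K2 is None:
            ml = bound_fraction(K, n * Mt, Lt)
            H = V0 * dH * ml
        else:
            ml, ml2 = _species_two_site(K, K2, n * Mt, Lt)
            H = V0 * (dH * (ml + ml2) + (dH2 or 0.0) * ml2)
        heats[i - 1] = H - H_prev + (dV / V0) * (H + H_prev) / 2.0
        H_prev = H
    return Thermogram(heats, molar_ratios(schedule), label=label)


def subtract_blank(sample: Thermogram, blank: Thermogram) -> Thermogram:
    """Remove dilution/mixing heats measured in a matched blank titration."""
    if len(sample) != len(blank):
        raise ValueError("sample and blank thermograms must have equal length")
    return Thermogram(
        sample.heats - blank.heats,
        sample.molar_ratio.copy(),
        label=f"{sample.label} - blank({blank.label})",
        sd=sample.sd,
    )


@dataclass
class BindingResult:
    """Fitted binding parameters and derived thermodynamic quantities."""

    K: float  # M^-1, first-step association constant
    dH: float  # cal/mol
    n: float  # stoichiometry / active-fraction factor
    dG: float  # cal/mol, -RT ln K
    minus_TdS: float  # cal/mol, dG - dH
    temperature: float  # K
    K2: float | None = None
    dH2: float | None = None
    fit_rss: float | None = None  # cal^2
    std_errors: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    model: str = "one_site"
    label: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def derive_thermodynamics(K: float, dH: float, T: float) -> tuple[float, float]:
    """(ΔG, −TΔS) in cal/mol from K (M⁻¹) and ΔH (cal/mol) at T (K)."""
    if K <= 0:
        raise ValueError("K must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    dG = -R_CAL * T * math.log(K)
    return dG, dG - dH


class ForceClass(Enum):
    """Dominant noncovalent driving force inferred from the signs of ΔH, −TΔS."""

    HYDROPHOBIC = "hydrophobic"
    HYDROGEN_BONDING = "hydrogen_bonding"
    BOTH = "both"


def classify_forces(dH: float, minus_TdS: float) -> ForceClass:
    """Sign-quadrant classification of the binding driving forces.

    ΔH > 0, −TΔS < 0 → hydrophobic; ΔH < 0, −TΔS > 0 → hydrogen bonding;
    both negative → both force types.  Exact zeros are indeterminate and the
    remaining quadrant (both positive: no spontaneous binding signature) is
    not assigned.
    """
    if dH == 0 or minus_TdS == 0:
        raise ValueError("force classification indeterminate at exactly zero")
    if dH > 0 and minus_TdS < 0:
        return ForceClass.HYDROPHOBIC
    if dH < 0 and minus_TdS > 0:
        return ForceClass.HYDROGEN_BONDING
    if dH < 0 and minus_TdS < 0:
        return ForceClass.BOTH
    raise ValueError("non-spontaneous-pattern: dH > 0 and -TdS > 0 not assigned")


def _initial_estimates(t: Thermogram, schedule: InjectionSchedule) -> tuple[float, float]:
    """Heuristic (logK, dH) start: first-injection heat per mole injected for
    ΔH; K from the molar ratio where cumulative heat reaches half its total."""
    moles_per_inj = schedule.injection_volume * schedule.syringe_conc
    dH0 = t.heats[0] / moles_per_inj
    cum = np.cumsum(t.heats)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(np.abs(cum), abs(half)))
    idx = min(idx, len(t) - 1)
    Mt, _ = concentrations_after(schedule, idx + 1)
    logK0 = math.log10(max(1.0 / Mt, 10.0))
    return logK0, dH0 if dH0 != 0 else -1000.0


def fit_binding(
    t: Thermogram,
    schedule: InjectionSchedule,
    model: str = "one_site",
    init: dict | None = None,
    fix_n: bool = False,
    discard_first: bool = False,
) -> BindingResult:
    """Weighted least-squares fit of the binding model to a thermogram.

    Parameters are K (fitted as log10 K on [0, 20]), ΔH, and n ∈ [0.1, 10]
    (plus K2, ΔH2 for the sequential two-site model).  Weights default to
    unity; per-injection standard deviations on the thermogram are used when
    present.  ``discard_first`` drops injection 1 (common practice for the
    diffusion-compromised first aliquot; off by default).

    Raises
    ------
    UninformativeTitrationError
        For all-zero heats or fewer than 5 usable injections.
    """
    heats = t.heats.copy()
    sd = t.sd.copy() if t.sd is not None else None
    mask = np.ones(len(heats), dtype=bool)
    if discard_first:
        mask[0] = False
    if mask.sum() < 5:
        raise UninformativeTitrationError("need at least 5 usable injections")
    if np.all(heats == 0.0):
        raise UninformativeTitrationError("titration uninformative: all heats zero")

    two_site = model == "sequential_two_site"
    if model not in ("one_site", "sequential_two_site"):
        raise ValueError(f"unknown model {model!r}")

    logK0, dH0 = _initial_estimates(t, schedule)
    init = init or {}
    params = lmfit.Parameters()
    params.add("logK", value=init.get("logK", logK0), min=0.0, max=20.0)
    params.add("dH", value=init.get("dH", dH0))
    params.add("n", value=init.get("n", 1.0), min=0.1, max=10.0, vary=not fix_n)
    if two_site:
        params.add("logK2", value=init.get("logK2", logK0 - 1.0), min=0.0, max=20.0)
        params.add("dH2", value=init.get("dH2", dH0))

    def residual(p):
        sim = simulate_thermogram(
            schedule,
            K=10.0 ** p["logK"].value,
            dH=p["dH"].value,
            n=p["n"].value,
            K2=10.0 ** p["logK2"].value if two_site else None,
            dH2=p["dH2"].value if two_site else None,
        )
        r = (sim.heats - heats)[mask]
        if sd is not None:
            r = r / np.where(sd[mask] > 0, sd[mask], 1.0)
        return r

    best = None
    starts = [params]
    if "logK" not in init:  # deterministic multi-start across affinity decades
        for lk in (2.0, 4.0, 6.0, 8.0):
            p = params.copy()
            p["logK"].value = lk
            starts.append(p)
    for p0 in starts:
        try:
            res = lmfit.minimize(residual, p0, method="leastsq",
                                 xtol=1e-10, ftol=1e-10, max_nfev=20000)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("binding fit failed to converge from all starts")

    p = best.params
    K = 10.0 ** p["logK"].value
    dH = p["dH"].value
    n = p["n"].value
    dG, mTdS = derive_thermodynamics(K, dH, schedule.temperature)

    flags = []
    if p["logK"].value <= 1e-6 or p["logK"].value >= 20.0 - 1e-6:
        flags.append("titration uninformative: K at bound")
    c_value = K * n * schedule.cell_conc
    if not (0.1 <= c_value <= 1e4):
        flags.append(f"low information: c = {c_value:.3g} outside fittable range")

    errs = {}
    for name in p:
        if p[name].stderr is not None:
            errs[name] = p[name].stderr
    if "logK" in errs:  # delta-method back-transform to K
        errs["K"] = K * math.log(10.0) * errs["logK"]

    return BindingResult(
        K=K, dH=dH, n=n, dG=dG, minus_TdS=mTdS,
        temperature=schedule.temperature,
        K2=10.0 ** p["logK2"].value if two_site else None,
        dH2=p["dH2"].value if two_site else None,
        fit_rss=float(best.chisqr), std_errors=errs, flags=flags,
        model=model, label=t.label,
    )
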