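"""Synthetic-data generators with the statistical structure the analyses assume.

Laboratory inputs for this pipeline (instrument spectra, calorimeter
thermograms, MD contact records) are emulated by three generators whose
ground truth is known, so every analysis stage can be exercised and scored
end to end:

* :func:`make_spectrum` — single-Gaussian visible pigment band (optional UV
  band) plus i.i.d. Gaussian noise on the 380-770 nm 1 nm grid.  The control
  recipe places the flavylium band at 520 nm; a copigmented recipe shifts it
  bathochromically to 523 nm with increased height, reproducing the darker,
  bluer colour signature of the strong-copigment case.
* :func:`make_thermogram` — forward ITC model heats with Gaussian noise
  scaled to the peak heat, retaining the generating truth for recovery
  scoring.
* :func:`make_frames` — per-frame contact graphs over 5 pigment + 11
  copigment molecules in which each aggregate class appears with a target
  Bernoulli frequency.

All generators take explicit integer seeds and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .itc import InjectionSchedule, Thermogram, simulate_thermogram, fit_binding
from .mdpost import ContactFrameSet, PIGMENT, COPIGMENT
from .spectra import Spectrum
from .observers import VISIBLE_GRID_NM

__all__ = [
    "SpectrumRecipe",
    "ThermogramRecipe",
    "FrameRecipe",
    "make_spectrum",
    "make_thermogram",
    "make_frames",
    "recovery_experiment",
    "control_recipe",
    "copigmented_recipe",
]


@dataclass(frozen=True)
class SpectrumRecipe:
    """Gaussian-band absorbance model of a pigment solution spectrum."""

    band_center: float = 520.0  # nm
    band_height: float = 0.40  # AU
    band_width: float = 40.0  # nm (Gaussian sigma)
    uv_band_center: float | None = None
    uv_band_height: float = 0.0
    uv_band_width: float = 20.0
    baseline: float = 0.0
    noise_sd: float = 0.0  # AU
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self):
        if self.band_width <= 0 or self.uv_band_width <= 0:
            raise ValueError("band widths must be positive")
        if self.band_height < 0 or self.uv_band_height < 0:
            raise ValueError("band heights must be nonnegative")


def control_recipe(**overrides) -> SpectrumRecipe:
    """Flavylium control solution: visible band at 520 nm, height 0.40 AU."""
    return replace(SpectrumRecipe(label="control"), **overrides)


def copigmented_recipe(**overrides) -> SpectrumRecipe:
    """Strongly copigmented solution: band shifted to 523 nm, height 0.46 AU
    (bathochromic + hyperchromic perturbation of the control)."""
    return replace(
        SpectrumRecipe(band_center=523.0, band_height=0.46, label="copigmented"),
        **overrides,
    )


def make_spectrum(recipe: SpectrumRecipe) -> Spectrum:
    """Generate an absorbance spectrum on the 380-770 nm grid from a recipe."""
    grid = VISIBLE_GRID_NM.astype(float)
    a = recipe.baseline + recipe.band_height * np.exp(
        -((grid - recipe.band_center) ** 2) / (2.0 * recipe.band_width**2)
    )
    if recipe.uv_band_center is not None:
        a = a + recipe.uv_band_height * np.exp(
            -((grid - recipe.uv_band_center) ** 2) / (2.0 * recipe.uv_band_width**2)
        )
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        a = a + rng.normal(0.0, recipe.noise_sd, size=grid.shape)
    with np.errstate(all="ignore"):
        a = np.clip(a, 0.0, None)
    return Spectrum(grid, a, label=recipe.label)


@dataclass(frozen=True)
class ThermogramRecipe:
    """Ground-truth binding parameters plus a schedule and a noise level."""

    true_K: float  # M^-1
    true_dH: float  # cal/mol
    schedule: InjectionSchedule
    true_n: float = 1.0
    true_K2: float | None = None
    true_dH2: float | None = None
    noise_sd: float = 0.0  # fraction of max |heat|
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self):
        if self.true_K <= 0:
            raise ValueError("true_K must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def make_thermogram(recipe: ThermogramRecipe) -> tuple[Thermogram, dict]:
    """Simulate a noisy thermogram; returns it with the generating truth."""
    clean = simulate_thermogram(
        recipe.schedule, K=recipe.true_K, dH=recipe.true_dH, n=recipe.true_n,
        K2=recipe.true_K2, dH2=recipe.true_dH2, label=recipe.label,
    )
    heats = clean.heats
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        sd = recipe.noise_sd * np.max(np.abs(heats))
        heats = heats + rng.normal(0.0, sd, size=heats.shape)
    truth = {"K": recipe.true_K, "dH": recipe.true_dH, "n": recipe.true_n,
             "K2": recipe.true_K2, "dH2": recipe.true_dH2}
    return Thermogram(heats, clean.molar_ratio, label=recipe.label), truth


@dataclass(frozen=True)
class FrameRecipe:
    """Contact-frame generator: target per-class aggregate frequencies.

    The molecule inventory mirrors the simulated systems (5 pigments, 11
    copigments).  ``class_freqs`` maps composition classes (n_pig, n_copig)
    to the Bernoulli probability that a frame contains one such aggregate.
    """

    n_frames: int
    class_freqs: dict = field(default_factory=dict)
    n_pigments: int = 5
    n_copigments: int = 11
    seed: int = 0

    def __post_init__(self):
        need_p = sum(k[0] for k in self.class_freqs)
        need_c = sum(k[1] for k in self.class_freqs)
        if need_p > self.n_pigments or need_c > self.n_copigments:
            raise ValueError("target classes are jointly infeasible for the molecule inventory")
        for k, f in self.class_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency for class {k} outside [0, 1]")
            if k[0] + k[1] < 2:
                raise ValueError("aggregate classes need at least two molecules")


def make_frames(recipe: FrameRecipe) -> ContactFrameSet:
    """Sample contact frames whose realized class frequencies match targets.

    Each frame independently contains one aggregate of each class with its
    target probability; aggregates are built on disjoint molecules and wired
    as a path, all remaining molecules staying isolated.  Realized
    frequencies therefore converge to targets with binomial sampling error.
    """
    rng = np.random.default_rng(recipe.seed)
    pig_ids = [f"P{i}" for i in range(recipe.n_pigments)]
    cop_ids = [f"C{i}" for i in range(recipe.n_copigments)]
    molecules = {m: PIGMENT for m in pig_ids}
    molecules.update({m: COPIGMENT for m in cop_ids})
    classes = sorted(recipe.class_freqs)
    frames = []
    for _ in range(recipe.n_frames):
        edges = []
        p_pool = list(pig_ids)
        c_pool = list(cop_ids)
        for cls in classes:
            if rng.random() >= recipe.class_freqs[cls]:
                continue
            members = [p_pool.pop() for _ in range(cls[0])]
            members += [c_pool.pop() for _ in range(cls[1])]
            # interleaving is irrelevant to composition; wire as a path
            edges += list(zip(members, members[1:]))
        frames.append(edges)
    return ContactFrameSet(molecules, frames)


def recovery_experiment(
    recipes: list[ThermogramRecipe],
    replicates: int,
    seed: int = 0,
    fix_n: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo parameter-recovery benchmark for the ITC fit.

    For each recipe, ``replicates`` noisy thermograms are generated (seeds
    derived from ``seed``) and fitted; the table reports median/IQR of the
    fitted K, ΔH, n plus bias and relative RMSE of K against the truth.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for recipe in recipes:
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(replicates)]
        Ks, dHs, ns = [], [], []
        for rep_seed in child_seeds:
            t, _ = make_thermogram(replace(recipe, seed=rep_seed))
            res = fit_binding(t, recipe.schedule, fix_n=fix_n)
            Ks.append(res.K)
            dHs.append(res.dH)
            ns.append(res.n)
        Ks, dHs, ns = np.array(Ks), np.array(dHs), np.array(ns)
        relK = Ks / recipe.true_K - 1.0
        rows.append({
            "label": recipe.label,
            "true_K": recipe.true_K, "true_dH": recipe.true_dH, "true_n": recipe.true_n,
            "K_median": float(np.median(Ks)),
            "K_iqr": float(np.subtract(*np.percentile(Ks, [75, 25]))),
            "dH_median": float(np.median(dHs)),
            "dH_iqr": float(np.subtract(*np.percentile(dHs, [75, 25]))),
            "n_median": float(np.median(ns)),
            "K_bias_rel": float(np.mean(relK)),
            "K_rmse_rel": float(np.sqrt(np.mean(relK**2))),
        })
    return pd.DataFrame(rows)
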