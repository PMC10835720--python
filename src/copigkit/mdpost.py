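"""Bookkeeping over MD-derived artifacts.

Two independent desk-scale analyses of molecular-dynamics output:

* a *complex census* — per-frame connected components of an intermolecular
  contact graph, classified by composition (n pigment : m copigment) and
  filtered at a minimum occurrence frequency (default: present in more than
  5% of frames);
* an MM/PBSA *energy ledger* — binding-enthalpy decomposition into van der
  Waals, electrostatic, polar-solvation and nonpolar-solvation components
  with SEM propagation, relative energies ΔΔH versus the most stable
  compound, and an affinity ranking with SEM-based tie flags.

Trajectory parsing, clustering and the Poisson–Boltzmann solve itself are
upstream of this module; it consumes declared contact edges and component
tables only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "ContactFrameSet",
    "ComplexCensus",
    "EnergyDecomposition",
    "census",
    "decompose_binding",
    "relative_binding",
    "rank_affinity",
    "AffinityRanking",
    "read_frames_csv",
    "read_energy_csv",
]

PIGMENT = "pigment"
COPIGMENT = "copigment"


@dataclass
class ContactFrameSet:
    """Per-frame intermolecular contact edges over a declared molecule set.

    ``molecules`` maps molecule id → species ("pigment" | "copigment");
    ``frames`` holds one undirected edge list per frame.
    """

    molecules: dict
    frames: list  # list of lists of (id, id) tuples

    def __post_init__(self):
        for sp in self.molecules.values():
            if sp not in (PIGMENT, COPIGMENT):
                raise ValueError(f"unknown species {sp!r}")
        for edges in self.frames:
            for a, b in edges:
                if a not in self.molecules or b not in self.molecules:
                    raise ValueError(f"edge ({a}, {b}) references an undeclared molecule")
                if a == b:
                    raise ValueError("self-edges are not allowed")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class ComplexCensus:
    """Aggregate composition classes found across frames.

    ``counts`` is the total number of components of each (pigment, copigment)
    class over all frames; ``frequencies`` the fraction of frames containing
    at least one such component.  ``filtered`` keeps only classes whose
    frequency strictly exceeds the threshold.  Monomers (components of one
    molecule) are not aggregates and are excluded.
    """

    counts: dict  # (n_pig, n_copig) -> total component count
    frequencies: dict  # (n_pig, n_copig) -> fraction of frames
    threshold: float
    n_frames: int

    @property
    def filtered(self) -> dict:
        return {k: v for k, v in self.frequencies.items() if v > self.threshold}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"n_pigment": k[0], "n_copigment": k[1], "count": self.counts[k],
             "frequency": self.frequencies[k], "retained": self.frequencies[k] > self.threshold}
            for k in sorted(self.counts)
        ]
        return pd.DataFrame(rows)


def census(frames: ContactFrameSet, threshold: float = 0.05) -> ComplexCensus:
    """Classify per-frame connected components by pigment:copigment composition.

    Every molecule appears in exactly one component per frame; components of
    two or more molecules are counted as aggregates of class
    (pigment count : copigment count).  A class is retained by ``filtered``
    when it occurs in strictly more than ``threshold`` of frames.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    counts: dict = {}
    frames_with: dict = {}
    for edges in frames.frames:
        g = nx.Graph()
        g.add_nodes_from(frames.molecules)
        g.add_edges_from(edges)
        seen = set()
        for comp in nx.connected_components(g):
            if len(comp) < 2:
                continue
            np_ = sum(1 for m in comp if frames.molecules[m] == PIGMENT)
            nc = len(comp) - np_
            key = (np_, nc)
            counts[key] = counts.get(key, 0) + 1
            seen.add(key)
        for key in seen:
            frames_with[key] = frames_with.get(key, 0) + 1
    n = max(frames.n_frames, 1)
    freqs = {k: frames_with[k] / n for k in counts}
    return ComplexCensus(counts, freqs, threshold, frames.n_frames)


@dataclass(frozen=True)
class EnergyDecomposition:
    """MM/PBSA binding-enthalpy components (cal/mol) with SEMs."""

    label: str
    vdw: float
    electrostatic: float
    polar_solv: float
    nonpolar_solv: float
    vdw_sem: float = 0.0
    electrostatic_sem: float = 0.0
    polar_solv_sem: float = 0.0
    nonpolar_solv_sem: float = 0.0

    @property
    def total(self) -> float:
        """ΔH_binding = vdW + electrostatic + polar solvation + nonpolar solvation."""
        return self.vdw + self.electrostatic + self.polar_solv + self.nonpolar_solv

    @property
    def total_sem(self) -> float:
        return math.sqrt(
            self.vdw_sem**2 + self.electrostatic_sem**2
            + self.polar_solv_sem**2 + self.nonpolar_solv_sem**2
        )


def decompose_binding(rows: dict, label: str = "") -> EnergyDecomposition:
    """Build an :class:`EnergyDecomposition` from component measurements.

    ``rows`` maps component name (vdw, electrostatic, polar_solv,
    nonpolar_solv) to either a value or a (value, sem) pair; all four
    components must be present.
    """
    required = ("vdw", "electrostatic", "polar_solv", "nonpolar_solv")
    missing = [k for k in required if k not in rows]
    if missing:
        raise ValueError(f"missing MM/PBSA components: {missing}")
    vals, sems = {}, {}
    for k in required:
        v = rows[k]
        if isinstance(v, (tuple, list)):
            vals[k], sems[k] = float(v[0]), float(v[1])
        else:
            vals[k], sems[k] = float(v), 0.0
    return EnergyDecomposition(
        label=label,
        vdw=vals["vdw"], electrostatic=vals["electrostatic"],
        polar_solv=vals["polar_solv"], nonpolar_solv=vals["nonpolar_solv"],
        vdw_sem=sems["vdw"], electrostatic_sem=sems["electrostatic"],
        polar_solv_sem=sems["polar_solv"], nonpolar_solv_sem=sems["nonpolar_solv"],
    )


def relative_binding(decomps: list[EnergyDecomposition]) -> dict:
    """ΔΔH_binding per compound relative to the most stable (lowest total).

    The most stable compound maps to exactly 0; all entries are ≥ 0 and the
    mapping is independent of input order.
    """
    if not decomps:
        raise ValueError("need at least one energy decomposition")
    ref = min(d.total for d in decomps)
    return {d.label: d.total - ref for d in decomps}


@dataclass
class AffinityRanking:
    """Compounds ordered by binding strength with SEM-based tie flags."""

    order: list  # labels, descending |total|
    tied_pairs: set = field(default_factory=set)  # frozensets of adjacent tied labels

    def tied(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.tied_pairs

    def __str__(self):
        parts = [self.order[0]]
        for prev, cur in zip(self.order, self.order[1:]):
            parts.append(" ≈ " if self.tied(prev, cur) else " > ")
            parts.append(cur)
        return "".join(parts)


def rank_affinity(decomps: list[EnergyDecomposition]) -> AffinityRanking:
    """Rank compounds by |ΔH_binding|, flagging ties within combined SEM.

    Adjacent compounds whose totals differ by no more than
    sqrt(SEM_a² + SEM_b²) are flagged as statistically indistinguishable
    ("≈").  The ordering is invariant under a uniform shift of all totals.
    """
    if len(decomps) < 2:
        raise ValueError("ranking needs at least two compounds")
    ordered = sorted(decomps, key=lambda d: abs(d.total), reverse=True)
    ties = set()
    for a, b in zip(ordered, ordered[1:]):
        if abs(a.total - b.total) <= math.hypot(a.total_sem, b.total_sem):
            ties.add(frozenset((a.label, b.label)))
    return AffinityRanking([d.label for d in ordered], ties)


def read_frames_csv(frames_path: str | Path, molecules_path: str | Path) -> ContactFrameSet:
    """Read a ``frame,mol_a,mol_b`` edge list plus an ``id,species`` manifest.

    Frames are numbered 1..max(frame); frames with no rows are edgeless.
    """
    mols = pd.read_csv(molecules_path)
    molecules = dict(zip(mols["id"].astype(str), mols["species"]))
    df = pd.read_csv(frames_path)
    n = int(df["frame"].max()) if len(df) else 0
    frames = [[] for _ in range(n)]
    for row in df.itertuples(index=False):
        frames[int(row.frame) - 1].append((str(row.mol_a), str(row.mol_b)))
    return ContactFrameSet(molecules, frames)


def read_energy_csv(path: str | Path) -> list[EnergyDecomposition]:
    """Read an MM/PBSA component table.

    Columns: ``compound, vdw, electrostatic, polar_solv, nonpolar_solv`` with
    optional ``*_sem`` columns; energies in cal/mol.
    """
    df = pd.read_csv(path)
    out = []
    for row in df.to_dict("records"):
        comps = {
            k: (row[k], row.get(f"{k}_sem", 0.0))
            for k in ("vdw", "electrostatic", "polar_solv", "nonpolar_solv")
        }
        out.append(decompose_binding(comps, label=str(row["compound"])))
    return out
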