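"""Chemical-space descriptors of the screened analogues.

Four descriptors characterise the chemical space: molecular weight
(average atomic weights, g/mol), oxygen and nitrogen atom counts over the
parent fragment, calculated logP (Wildman–Crippen atom contributions,
unitless) and topological polar surface area (Ertl N/O fragment
contributions, Å²).  All are 2-D, deterministic, and invariant under atom
reordering and SMILES dialect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from rdkit.Chem import Crippen, Descriptors

from .chem_io import Molecule, largest_fragment
from .errors import InputError


@dataclass(frozen=True)
class PropertyVector:
    mw: float
    n_oxygen: int
    n_nitrogen: int
    clogp: float
    tpsa: float


def molecular_weight(mol: Molecule) -> float:
    """Molecular weight from standard average atomic weights, hydrogens included."""
    return Descriptors.MolWt(mol.mol)


def heteroatom_counts(mol: Molecule) -> tuple[int, int]:
    """(oxygen, nitrogen) atom counts over the largest fragment."""
    parent = largest_fragment(mol)
    n_o = sum(1 for a in parent.mol.GetAtoms() if a.GetAtomicNum() == 8)
    n_n = sum(1 for a in parent.mol.GetAtoms() if a.GetAtomicNum() == 7)
    return n_o, n_n


def clogp(mol: Molecule) -> float:
    """Wildman–Crippen calculated logP (sum of atom contributions)."""
    return Crippen.MolLogP(mol.mol)


def tpsa(mol: Molecule) -> float:
    """Topological polar surface area from the Ertl N/O contribution table, Å²."""
    return Descriptors.TPSA(mol.mol)


def property_vector(mol: Molecule) -> PropertyVector:
    n_o, n_n = heteroatom_counts(mol)
    return PropertyVector(molecular_weight(mol), n_o, n_n, clogp(mol), tpsa(mol))


@dataclass
class PropertySummary:
    n: int
    mean_mw: float
    min_mw: float
    max_mw: float
    min_n_oxygen: int
    max_n_oxygen: int
    min_n_nitrogen: int
    max_n_nitrogen: int
    min_clogp: float
    max_clogp: float
    min_tpsa: float
    max_tpsa: float


def property_summary(vectors: list[PropertyVector]) -> PropertySummary:
    """Arithmetic mean MW and per-descriptor extrema over a compound set."""
    if not vectors:
        raise InputError("property summary of an empty set")
    return PropertySummary(
        n=len(vectors),
        mean_mw=sum(v.mw for v in vectors) / len(vectors),
        min_mw=min(v.mw for v in vectors),
        max_mw=max(v.mw for v in vectors),
        min_n_oxygen=min(v.n_oxygen for v in vectors),
        max_n_oxygen=max(v.n_oxygen for v in vectors),
        min_n_nitrogen=min(v.n_nitrogen for v in vectors),
        max_n_nitrogen=max(v.n_nitrogen for v in vectors),
        min_clogp=min(v.clogp for v in vectors),
        max_clogp=max(v.clogp for v in vectors),
        min_tpsa=min(v.tpsa for v in vectors),
        max_tpsa=max(v.tpsa for v in vectors),
    )


def write_properties_csv(path: str | Path, rows: list[tuple[int, str, PropertyVector]]) -> None:
    """Per-compound properties table: one row per (aaa_number, smiles, vector).

    Doubles as the scatter-data export (clogp vs tpsa) for charting.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["aaa_number", "canonical_smiles", "mw", "n_o", "n_n", "clogp", "tpsa"])
        for number, smiles, v in rows:
            w.writerow([number, smiles, f"{v.mw:.3f}", v.n_oxygen, v.n_nitrogen,
                        f"{v.clogp:.4f}", f"{v.tpsa:.2f}"])
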