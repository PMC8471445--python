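"""Reading, canonicalisation and registration of molecular structures.

All downstream stages (scaffold derivation, substructure screening,
descriptors) operate on 2-D connection tables: stereochemistry is discarded
on input, because scaffold containment must not depend on stereo
annotations, and only the largest fragment of a multi-component record is
kept, since occurrence data refer to the parent natural product rather than
a salt or solvate.  Tautomers are *not* normalised; two tautomeric drawings
of the same compound register as distinct entries.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

from .errors import InputError

logger = logging.getLogger(__name__)

# RDKit's per-record parse warnings are redundant with our own skip log.
RDLogger.DisableLog("rdApp.error")

DEFAULT_SMILES_COLUMN = "smiles"


@dataclass
class Molecule:
    """A sanitised 2-D structure with its canonical SMILES identity.

    ``canonical_smiles`` is invariant under atom reordering and input SMILES
    dialect, so it serves as the registry key.
    """

    mol: Chem.Mol
    canonical_smiles: str
    name: str = ""
    source_tag: str = ""

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Molecule({self.canonical_smiles!r}, name={self.name!r})"


def _sanitize(rdmol: Chem.Mol) -> Chem.Mol | None:
    """Sanitise, strip stereochemistry, and re-perceive aromaticity once."""
    if rdmol is None:
        return None
    try:
        Chem.SanitizeMol(rdmol)
    except Exception:
        return None
    Chem.RemoveStereochemistry(rdmol)
    return rdmol


def from_smiles(smiles: str, name: str = "", source_tag: str = "") -> Molecule:
    """Parse a single SMILES string into a :class:`Molecule`.

    Raises :class:`InputError` if the string cannot be parsed/sanitised.
    """
    rdmol = _sanitize(Chem.MolFromSmiles(smiles))
    if rdmol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    return Molecule(rdmol, Chem.MolToSmiles(rdmol), name=name, source_tag=source_tag)


def canonicalize(mol: Molecule | Chem.Mol | str) -> str:
    """Canonical SMILES of a molecule; idempotent and order-invariant.

    Accepts a :class:`Molecule`, a raw RDKit mol, or a SMILES string.
    """
    if isinstance(mol, Molecule):
        return Chem.MolToSmiles(mol.mol)
    if isinstance(mol, str):
        return from_smiles(mol).canonical_smiles
    rdmol = _sanitize(Chem.Mol(mol))
    if rdmol is None:
        raise InputError("unsanitizable structure")
    return Chem.MolToSmiles(rdmol)


def largest_fragment(mol: Molecule) -> Molecule:
    """Keep the fragment with the most heavy atoms.

    Ties are broken by higher molecular weight, then by canonical SMILES
    order, so the choice is deterministic for any input.
    """
    frags = Chem.GetMolFrags(mol.mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol
    from rdkit.Chem import Descriptors

    def key(f: Chem.Mol):
        return (f.GetNumHeavyAtoms(), Descriptors.MolWt(f), Chem.MolToSmiles(f))

    best = max(frags, key=key)
    return Molecule(best, Chem.MolToSmiles(best), name=mol.name, source_tag=mol.source_tag)


def read_structures(
    path: str | Path,
    fmt: str | None = None,
    smiles_column: str = DEFAULT_SMILES_COLUMN,
) -> tuple[list[Molecule], int]:
    """Read molecules from an SDF, SMILES file, or CSV of SMILES.

    ``fmt`` is one of ``{"sdf", "smiles_file", "csv"}``; when omitted it is
    inferred from the file suffix.  Unparsable records are logged with their
    record index and skipped.  Returns ``(molecules, n_skipped)``.

    Raises :class:`InputError` if the file is missing or yields zero
    parsable records.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if fmt is None:
        fmt = {".sdf": "sdf", ".csv": "csv"}.get(path.suffix.lower(), "smiles_file")
    mols: list[Molecule] = []
    n_skip = 0

    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False)
        for i, raw in enumerate(supplier):
            rdmol = _sanitize(raw)
            if rdmol is None:
                logger.warning("skipping unparsable SDF record %d in %s", i, path.name)
                n_skip += 1
                continue
            name = raw.GetProp("_Name") if raw.HasProp("_Name") else ""
            mols.append(
                Molecule(rdmol, Chem.MolToSmiles(rdmol), name=name, source_tag=f"{path.name}:{i}")
            )
    elif fmt == "smiles_file":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles, name = parts[0], (parts[1] if len(parts) > 1 else "")
                try:
                    m = from_smiles(smiles, name=name, source_tag=f"{path.name}:{i}")
                except InputError:
                    logger.warning("skipping unparsable SMILES line %d in %s", i, path.name)
                    n_skip += 1
                    continue
                mols.append(m)
    elif fmt == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or smiles_column not in reader.fieldnames:
                raise InputError(f"CSV {path} lacks structure column {smiles_column!r}")
            name_col = next((c for c in ("name", "compound", "id") if c in reader.fieldnames), None)
            for i, row in enumerate(reader):
                try:
                    m = from_smiles(
                        row[smiles_column] or "",
                        name=(row.get(name_col) or "") if name_col else "",
                        source_tag=f"{path.name}:{i}",
                    )
                except InputError:
                    logger.warning("skipping unparsable CSV row %d in %s", i, path.name)
                    n_skip += 1
                    continue
                mols.append(m)
    else:
        raise InputError(f"unknown format {fmt!r}")

    if not mols:
        raise InputError(f"no parsable records in {path}")
    return mols, n_skip


@dataclass
class CompoundRegistry:
    """Ordered, deduplicated collection of molecules keyed by canonical SMILES."""

    entries: list[Molecule] = field(default_factory=list)
    id_map: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, idx: int) -> Molecule:
        return self.entries[idx]

    def index_of(self, canonical_smiles: str) -> int | None:
        return self.id_map.get(canonical_smiles)

    def add(self, mol: Molecule) -> int:
        """Add one molecule, merging source tags on duplicates."""
        idx = self.id_map.get(mol.canonical_smiles)
        if idx is None:
            idx = len(self.entries)
            self.entries.append(mol)
            self.id_map[mol.canonical_smiles] = idx
        else:
            existing = self.entries[idx]
            tags = [t for t in (existing.source_tag, mol.source_tag) if t]
            existing.source_tag = ";".join(dict.fromkeys(";".join(tags).split(";"))) if tags else ""
            if not existing.name and mol.name:
                existing.name = mol.name
        return idx

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "canonical_smiles", "name", "source_tags"])
            for i, m in enumerate(self.entries):
                w.writerow([i, m.canonical_smiles, m.name, m.source_tag])

    @classmethod
    def read_csv(cls, path: str | Path) -> "CompoundRegistry":
        mols, _ = read_structures(path, fmt="csv", smiles_column="canonical_smiles")
        reg = cls()
        for m in mols:
            reg.add(m)
        return reg


def register(mols: list[Molecule]) -> CompoundRegistry:
    """Build a registry: duplicates merged, first-occurrence order preserved."""
    reg = CompoundRegistry()
    for m in mols:
        reg.add(m)
    return reg
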