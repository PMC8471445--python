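"""The virtual screen: scaffold containment, serial numbering, and
diagnosis of excluded analogues.

A library compound is an AAA hit when it contains at least one category
scaffold as a subgraph; its category is the first matching scaffold in
priority order (aristolochic acids before aristolactams before
4,5-dioxoaporphines), with all matches retained for audit.  Hits receive
serial numbers ("AAAs No.") that are contiguous from 1 and grouped into
category blocks; within a block the ordering follows first occurrence in
the input registry.

Reported analogues that fail the screen ("exclusions") are diagnosed by
three complementary views: named key groups of the nearest scaffold that
the molecule lacks (nitro, methylenedioxy, carboxylic acid, lactam
carbonyl, ring dione), the MCS the molecule still shares with that
scaffold, fingerprint similarity-map atom weights, and Gasteiger (PEOE)
partial charges.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import CompoundRegistry, Molecule
from .errors import AAAScreenError, InputError
from .scaffolds import CATEGORIES, MCSResult, MatchPolicy, ScaffoldDefinition, find_mcs

logger = logging.getLogger(__name__)

#: named key-group queries (structural alerts) used for exclusion diagnosis
FEATURE_SMARTS: dict[str, str] = {
    "nitro": "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
    "methylenedioxy": "C1Oc2ccccc2O1",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "lactam_carbonyl": "[OX1]=[C;R][#7;R]",
    "ring_dione": "[OX1]=[C;R][C;R]=[OX1]",
}


def _feature_queries(feature_smarts: dict[str, str] | None = None) -> dict[str, Chem.Mol]:
    return {k: Chem.MolFromSmarts(v) for k, v in (feature_smarts or FEATURE_SMARTS).items()}


# ---------------------------------------------------------------------------
# containment and classification


def matches_scaffold(mol: Molecule, scaffold: ScaffoldDefinition) -> tuple[bool, tuple[int, ...]]:
    """Subgraph containment test with a deterministic witness embedding.

    Returns ``(matched, atom_indices)`` where the witness is the
    lexicographically smallest atom-index tuple over all embeddings.
    """
    query = scaffold.query
    matches = mol.mol.GetSubstructMatches(query, uniquify=False, maxMatches=10000)
    if not matches:
        return False, ()
    return True, min(matches)


def classify(mol: Molecule, scaffolds: list[ScaffoldDefinition]) -> tuple[str | None, list[str]]:
    """Category of the first scaffold contained in ``mol`` (priority order),
    plus the full list of matching categories; ``(None, [])`` if none match."""
    all_matches = [s.category for s in scaffolds if mol.mol.HasSubstructMatch(s.query)]
    return (all_matches[0] if all_matches else None), all_matches


@dataclass
class ScreenHit:
    """One screened-in analogue with its serial number and witness match."""

    compound_id: int
    category: str
    all_matches: list[str]
    aaa_number: int
    match_atoms: tuple[int, ...] = ()


@dataclass
class ScreenResult:
    hits: list[ScreenHit]
    non_hit_ids: list[int]
    counts: dict[str, int] = field(default_factory=dict)

    def write_csv(self, path: str | Path, registry: CompoundRegistry) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["aaa_number", "canonical_smiles", "name", "category", "all_matches"])
            for h in self.hits:
                m = registry[h.compound_id]
                w.writerow([h.aaa_number, m.canonical_smiles, m.name, h.category,
                            ";".join(h.all_matches)])


def screen_library(registry: CompoundRegistry,
                   scaffolds: list[ScaffoldDefinition]) -> ScreenResult:
    """Screen every registry entry and number the hits in category blocks.

    Serial numbers are run-local identifiers: unique, contiguous from 1,
    grouped into blocks ordered by scaffold priority, first-occurrence
    order within each block.
    """
    if len(registry) == 0:
        raise InputError("cannot screen an empty registry")
    by_category: dict[str, list[tuple[int, list[str], tuple[int, ...]]]] = defaultdict(list)
    non_hits: list[int] = []
    for idx, mol in enumerate(registry):
        category, matched = classify(mol, scaffolds)
        if category is None:
            non_hits.append(idx)
            continue
        _, witness = matches_scaffold(mol, next(s for s in scaffolds if s.category == category))
        by_category[category].append((idx, matched, witness))

    hits: list[ScreenHit] = []
    serial = 1
    for s in scaffolds:
        for idx, matched, witness in by_category.get(s.category, []):
            hits.append(ScreenHit(idx, s.category, matched, serial, witness))
            serial += 1
    counts = {s.category: len(by_category.get(s.category, [])) for s in scaffolds}
    counts["total"] = len(hits)
    logger.info("screen: %d hits of %d compounds (%s)", len(hits), len(registry),
                ", ".join(f"{k}={v}" for k, v in counts.items() if k != "total"))
    return ScreenResult(hits, non_hits, counts)


# ---------------------------------------------------------------------------
# Gasteiger (PEOE) partial charges

# Gasteiger-Marsili electronegativity parameters (a, b, c) by element and,
# for C/N/O, hybridisation.  chi+ (the cation electronegativity used as the
# transfer denominator) is a+b+c, except hydrogen's conventional 20.02.
_PEOE_PARAMS: dict[tuple[str, str | None], tuple[float, float, float]] = {
    ("H", None): (7.17, 6.24, -0.56),
    ("C", "SP3"): (7.98, 9.18, 1.88),
    ("C", "SP2"): (8.79, 9.32, 1.51),
    ("C", "SP"): (10.39, 9.45, 0.73),
    ("N", "SP3"): (11.54, 10.82, 1.36),
    ("N", "SP2"): (12.87, 11.15, 0.85),
    ("N", "SP"): (15.68, 11.70, -0.27),
    ("O", "SP3"): (14.18, 12.92, 1.39),
    ("O", "SP2"): (17.07, 13.79, 0.47),
    ("F", None): (14.66, 13.85, 2.31),
    ("Cl", None): (11.00, 9.69, 1.35),
    ("Br", None): (10.08, 8.47, 1.16),
    ("I", None): (9.90, 7.96, 0.96),
    ("S", None): (10.14, 9.13, 1.38),
}
_H_CATION_CHI = 20.02


def _peoe_params(atom: Chem.Atom) -> tuple[float, float, float]:
    sym = atom.GetSymbol()
    if (sym, None) in _PEOE_PARAMS:
        return _PEOE_PARAMS[(sym, None)]
    hyb = str(atom.GetHybridization())
    if hyb not in ("SP", "SP2", "SP3"):
        hyb = "SP3"
    try:
        return _PEOE_PARAMS[(sym, hyb)]
    except KeyError:
        raise AAAScreenError(f"no PEOE electronegativity parameters for element {sym!r}")


@dataclass
class ChargeResult:
    """PEOE charges on the hydrogen-explicit graph of a molecule."""

    mol_h: Chem.Mol
    charges: list[float]

    def heavy(self) -> list[float]:
        """Charges folded onto heavy atoms (each heavy atom plus its hydrogens)."""
        out = []
        for atom in self.mol_h.GetAtoms():
            if atom.GetAtomicNum() == 1:
                continue
            q = self.charges[atom.GetIdx()]
            q += sum(self.charges[nb.GetIdx()] for nb in atom.GetNeighbors()
                     if nb.GetAtomicNum() == 1)
            out.append(q)
        return out

    @property
    def total(self) -> float:
        return sum(self.charges)


def gasteiger_charges(mol: Molecule, n_iter: int = 8) -> ChargeResult:
    """Partial equalisation of orbital electronegativity (PEOE).

    At step ``k`` each bond transfers charge proportional to the
    electronegativity difference of its atoms, damped by ``(1/2)**k``;
    ``chi_i = a + b*q_i + c*q_i**2`` and the transfer is normalised by the
    cation electronegativity of the less electronegative partner.  The
    formal charge of a group of equivalent terminal O/S atoms (carboxylate,
    nitro) is delocalised evenly over the group before iterating.  Total
    charge is conserved exactly.
    """
    mol_h = Chem.AddHs(mol.mol)
    params = [_peoe_params(a) for a in mol_h.GetAtoms()]
    chi_plus = [_H_CATION_CHI if mol_h.GetAtomWithIdx(i).GetAtomicNum() == 1 else sum(p)
                for i, p in enumerate(params)]
    q = [float(a.GetFormalCharge()) for a in mol_h.GetAtoms()]
    groups: dict[tuple[int, str], list[int]] = defaultdict(list)
    for a in mol_h.GetAtoms():
        if a.GetSymbol() in ("O", "S") and a.GetDegree() == 1:
            groups[(a.GetNeighbors()[0].GetIdx(), a.GetSymbol())].append(a.GetIdx())
    for idxs in groups.values():
        if len(idxs) > 1:
            tot = sum(q[i] for i in idxs)
            for i in idxs:
                q[i] = tot / len(idxs)

    for k in range(1, n_iter + 1):
        damp = 0.5 ** k
        chi = [a + b * x + c * x * x for (a, b, c), x in zip(params, q)]
        dq = [0.0] * len(q)
        for bond in mol_h.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            diff = chi[j] - chi[i]
            denom = chi_plus[i] if diff > 0 else chi_plus[j]
            t = diff / denom * damp
            dq[i] += t
            dq[j] -= t
        q = [a + b for a, b in zip(q, dq)]
    return ChargeResult(mol_h, q)


# ---------------------------------------------------------------------------
# similarity maps


@dataclass(frozen=True)
class FingerprintConfig:
    """Circular-fingerprint settings; ``n_bits=None`` keeps the sparse
    (unfolded) bit space."""

    radius: int = 2
    n_bits: int | None = 2048


@dataclass
class SimilarityMap:
    """Per-atom contributions to the fingerprint similarity of two molecules.

    ``weights[i]`` is the drop in Dice similarity when the circular-
    fingerprint environments centred on atom ``i`` of the probe molecule
    are removed; ``normalized`` rescales by the maximum absolute weight.
    """

    similarity: float
    weights: list[float]

    @property
    def normalized(self) -> list[float]:
        peak = max((abs(w) for w in self.weights), default=0.0)
        if peak == 0.0:
            return [0.0] * len(self.weights)
        return [w / peak for w in self.weights]


def _count_fp(mol: Chem.Mol, cfg: FingerprintConfig):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=cfg.radius,
                                                    fpSize=cfg.n_bits or 2048)
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    if cfg.n_bits is None:
        fp = gen.GetSparseCountFingerprint(mol, additionalOutput=out)
    else:
        fp = gen.GetCountFingerprint(mol, additionalOutput=out)
    return fp.GetNonzeroElements(), out.GetBitInfoMap()


def _atom_bit_lists(mol: Chem.Mol, info) -> list[list[int]]:
    """For each atom, the bits whose generating environment involves it
    (one entry per environment occurrence)."""
    bitmap: list[list[int]] = [[] for _ in range(mol.GetNumAtoms())]
    for bit, envs in info.items():
        for centre, radius in envs:
            if radius == 0:
                bitmap[centre].append(bit)
                continue
            env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, centre)
            atoms = set()
            for bidx in env:
                bond = mol.GetBondWithIdx(bidx)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            for a in atoms:
                bitmap[a].append(bit)
    return bitmap


def _dice(a: dict[int, int], b: dict[int, int]) -> float:
    tot = sum(a.values()) + sum(b.values())
    if tot == 0:
        return 0.0
    shared = sum(min(c, b[bit]) for bit, c in a.items() if bit in b)
    return 2.0 * shared / tot


def similarity_map(mol: Molecule, reference_mol: Molecule,
                   fp_config: FingerprintConfig | None = None) -> SimilarityMap:
    """Dice similarity map of ``mol`` against ``reference_mol`` using
    count-based hashed circular fingerprints (default radius 2, 2048 bits)."""
    cfg = fp_config or FingerprintConfig()
    probe_counts, probe_info = _count_fp(mol.mol, cfg)
    ref_counts, _ = _count_fp(reference_mol.mol, cfg)
    base = _dice(probe_counts, ref_counts)
    bitmap = _atom_bit_lists(mol.mol, probe_info)
    weights = []
    for atom_idx in range(mol.mol.GetNumAtoms()):
        reduced = dict(probe_counts)
        for bit in bitmap[atom_idx]:
            left = reduced.get(bit, 0) - 1
            if left > 0:
                reduced[bit] = left
            else:
                reduced.pop(bit, None)
        weights.append(base - _dice(reduced, ref_counts))
    return SimilarityMap(base, weights)


# ---------------------------------------------------------------------------
# exclusion diagnosis


@dataclass
class ExclusionReport:
    """Why a reported analogue fails the screen against its nearest scaffold."""

    compound_id: int
    nearest_category: str
    missing_features: list[str]
    mcs_with_scaffold: MCSResult | None
    atom_weight_map: list[float]
    partial_charges: list[float]


def diagnose_exclusion(
    mol: Molecule,
    nearest: ScaffoldDefinition,
    feature_smarts: dict[str, str] | None = None,
    compound_id: int = -1,
    policy: MatchPolicy | None = None,
) -> ExclusionReport:
    """Explain an exclusion: key groups of the nearest scaffold that the
    molecule lacks, the residual shared core, similarity-map weights and
    PEOE charges.

    Raises :class:`AAAScreenError` if the molecule actually matches the
    scaffold (then it is a hit, not an exclusion).
    """
    if mol.mol.HasSubstructMatch(nearest.query):
        raise AAAScreenError(
            f"{mol.name or mol.canonical_smiles} matches scaffold "
            f"{nearest.category!r}; it is not an exclusion"
        )
    queries = _feature_queries(feature_smarts)
    scaffold_features = nearest.features or [
        name for name, q in queries.items() if nearest.core.mol.HasSubstructMatch(q)
    ]
    missing = [name for name in scaffold_features
               if not mol.mol.HasSubstructMatch(queries[name])]
    core = nearest.core
    try:
        shared = find_mcs([mol, core], policy=policy, budget=10.0)
    except AAAScreenError:
        shared = None
    weights = similarity_map(mol, core).weights
    charges = gasteiger_charges(mol).heavy()
    return ExclusionReport(compound_id, nearest.category, missing, shared, weights, charges)


def nearest_scaffold(mol: Molecule, scaffolds: list[ScaffoldDefinition],
                     policy: MatchPolicy | None = None) -> ScaffoldDefinition:
    """Scaffold sharing the largest MCS with the molecule, scored by Dice
    overlap (2*shared bonds / (core bonds + molecule bonds)) so that small
    and large cores compete fairly; priority order breaks ties.

    Note the assignment can be genuinely ambiguous when the deleted group
    (e.g. a methylenedioxy) is shared by several chemotypes.
    """
    best, best_score = scaffolds[0], -1.0
    n_mol = mol.mol.GetNumBonds()
    for s in scaffolds:
        try:
            shared = find_mcs([mol, s.core], policy=policy, budget=10.0).num_bonds
        except AAAScreenError:
            shared = 0
        score = 2.0 * shared / (s.core.mol.GetNumBonds() + n_mol)
        if score > best_score:
            best, best_score = s, score
    return best


def write_exclusions_csv(reports: list[ExclusionReport], registry: CompoundRegistry,
                         path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["canonical_smiles", "name", "nearest_category", "missing_features"])
        for r in reports:
            m = registry[r.compound_id]
            w.writerow([m.canonical_smiles, m.name, r.nearest_category,
                        ";".join(r.missing_features)])
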