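"""Per-category maximum common substructures (MCS) of the reference set.

The screen recognises three chemotypes of aristolochic acid analogue (AAA):

* ``aristolochic_acid`` — nitro-phenanthrene carboxylic acids (MCS1),
* ``aristolactam`` — phenanthrene-fused cyclic amides (MCS2),
* ``dioxoaporphine`` — aporphine alkaloids with two adjacent ring carbonyls
  (MCS3).

Each category's scaffold is the maximum common substructure of the curated
reference compounds of that category, under an element-exact atom and
order-exact bond match policy.  Because MCS search is NP-hard, derived
scaffolds are persisted as SMARTS in a versioned YAML fixture; routine
screening loads the fixture and never re-derives.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem_io import Molecule, from_smiles
from .errors import ScaffoldError

#: category labels in screening priority order (MCS1, MCS2, MCS3)
CATEGORIES = ("aristolochic_acid", "aristolactam", "dioxoaporphine")


@dataclass(frozen=True)
class MatchPolicy:
    """Atom/bond comparison flags for MCS search and substructure matching.

    Defaults mirror a conventional exact-topology comparison: atoms match on
    element, bonds on order (aromatic only matches aromatic), and ring
    membership is not constrained.
    """

    atom_compare: str = "element"
    bond_compare: str = "order"
    ring_bond_only: bool = False

    def fmcs_params(self) -> dict:
        atom = {"element": rdFMCS.AtomCompare.CompareElements,
                "any": rdFMCS.AtomCompare.CompareAny}[self.atom_compare]
        bond = {"order": rdFMCS.BondCompare.CompareOrder,
                "any": rdFMCS.BondCompare.CompareAny}[self.bond_compare]
        return dict(atomCompare=atom, bondCompare=bond,
                    ringMatchesRingOnly=self.ring_bond_only)

    def digest(self) -> str:
        return hashlib.sha256(repr(sorted(asdict(self).items())).encode()).hexdigest()[:12]


@dataclass
class MCSResult:
    """Outcome of one MCS search: a connected common subgraph of all inputs."""

    smarts: str
    num_atoms: int
    num_bonds: int
    complete: bool  # False when the search budget expired (best-so-far)

    @property
    def query(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.smarts)


@dataclass
class ScaffoldDefinition:
    """A category's scaffold as a matchable substructure query.

    ``core_smiles`` is a concrete prototype molecule of the scaffold (used
    for key-group detection and exclusion diagnosis); ``smarts`` is the
    query actually matched during screening.
    """

    category: str
    smarts: str
    core_smiles: str = ""
    features: list[str] = field(default_factory=list)
    support: list[str] = field(default_factory=list)
    provenance: str = ""
    policy_hash: str = ""
    complete: bool = True

    @property
    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ScaffoldError(f"invalid scaffold SMARTS for {self.category}")
        return q

    @property
    def core(self) -> Molecule:
        return from_smiles(self.core_smiles, name=f"{self.category} core")


@dataclass
class ReferenceSet:
    """Curated reference compounds, each assigned to exactly one category."""

    members: list[tuple[Molecule, str]]

    def __len__(self) -> int:
        return len(self.members)

    def category(self, label: str) -> list[Molecule]:
        return [m for m, c in self.members if c == label]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceSet":
        import csv as _csv

        members = []
        with open(path, encoding="utf-8", newline="") as fh:
            for row in _csv.DictReader(fh):
                mol = from_smiles(row["smiles"], name=row.get("name", ""),
                                  source_tag=str(path))
                cat = row["category"]
                if cat not in CATEGORIES:
                    raise ScaffoldError(f"unknown category {cat!r} for {mol.name!r}")
                members.append((mol, cat))
        return cls(members)


def _as_rdmols(mols) -> list[Chem.Mol]:
    return [m.mol if isinstance(m, Molecule) else m for m in mols]


def find_mcs(mols, policy: MatchPolicy | None = None, budget: float = 60.0) -> MCSResult:
    """Maximum common (connected) substructure of two or more molecules.

    ``budget`` is the wall-clock search limit in seconds; when it expires
    the best candidate found so far is returned with ``complete=False``.
    Results are maximal by bond count and deterministic for fixed inputs,
    policy and budget.

    Raises :class:`ScaffoldError` for fewer than two molecules or when no
    common subgraph exists (naming the first non-matching pair).
    """
    policy = policy or MatchPolicy()
    rdmols = _as_rdmols(mols)
    if len(rdmols) < 2:
        raise ScaffoldError("MCS requires at least two molecules")
    res = rdFMCS.FindMCS(rdmols, timeout=max(1, int(budget)), **policy.fmcs_params())
    if res.numBonds == 0:
        for (i, a), (j, b) in itertools.combinations(enumerate(rdmols), 2):
            pair = rdFMCS.FindMCS([a, b], timeout=max(1, int(budget)), **policy.fmcs_params())
            if pair.numBonds == 0:
                raise ScaffoldError(
                    f"no common substructure between inputs {i} and {j} "
                    f"({Chem.MolToSmiles(a)} vs {Chem.MolToSmiles(b)})"
                )
        raise ScaffoldError("no common substructure across the input set")
    return MCSResult(res.smartsString, res.numAtoms, res.numBonds, complete=not res.canceled)


def validate_scaffold(scaffold: ScaffoldDefinition, refs: ReferenceSet) -> dict[str, bool]:
    """Per-member containment report for a scaffold over its category.

    Returns ``{member name or smiles: matched}``; the scaffold is valid iff
    every value is True.
    """
    query = scaffold.query
    report: dict[str, bool] = {}
    for mol in refs.category(scaffold.category):
        key = mol.name or mol.canonical_smiles
        report[key] = mol.mol.HasSubstructMatch(query)
    return report


def derive_category_scaffolds(
    refs: ReferenceSet,
    policy: MatchPolicy | None = None,
    budget: float = 60.0,
    feature_smarts: dict[str, str] | None = None,
) -> list[ScaffoldDefinition]:
    """Derive one validated scaffold per category from the reference set.

    Categories are processed (and returned) in screening priority order.
    Each derived scaffold must match 100% of its category's members;
    a failure is fatal and names the offending member.
    """
    policy = policy or MatchPolicy()
    scaffolds = []
    for cat in CATEGORIES:
        members = refs.category(cat)
        if len(members) < 2:
            raise ScaffoldError(f"category {cat!r} needs >= 2 reference members")
        res = find_mcs(members, policy, budget)
        core_smiles = _core_prototype(res, members)
        sd = ScaffoldDefinition(
            category=cat,
            smarts=res.smarts,
            core_smiles=core_smiles,
            features=_detect_features(core_smiles, feature_smarts),
            support=[m.name or m.canonical_smiles for m in members],
            provenance=f"MCS of {len(members)} reference members",
            policy_hash=policy.digest(),
            complete=res.complete,
        )
        report = validate_scaffold(sd, refs)
        bad = [k for k, ok in report.items() if not ok]
        if bad:
            raise ScaffoldError(f"scaffold for {cat!r} fails to match member(s): {bad}")
        scaffolds.append(sd)
    return scaffolds


def _core_prototype(res: MCSResult, members: list[Molecule]) -> str:
    """Concrete molecule realising the MCS: the matched atoms of the
    smallest supporting member, extracted as a fragment."""
    query = res.query
    smallest = min(members, key=lambda m: (m.num_heavy_atoms, m.canonical_smiles))
    match = smallest.mol.GetSubstructMatch(query)
    if not match:  # pragma: no cover - by construction the MCS matches
        return ""
    em = Chem.RWMol(smallest.mol)
    for idx in sorted(set(range(em.GetNumAtoms())) - set(match), reverse=True):
        em.RemoveAtom(idx)
    frag = em.GetMol()
    try:
        Chem.SanitizeMol(frag)
        return Chem.MolToSmiles(frag)
    except Exception:
        return ""


def _detect_features(core_smiles: str, feature_smarts: dict[str, str] | None) -> list[str]:
    if not core_smiles or not feature_smarts:
        return []
    mol = Chem.MolFromSmiles(core_smiles)
    return [name for name, sm in feature_smarts.items()
            if mol.HasSubstructMatch(Chem.MolFromSmarts(sm))]


# ---------------------------------------------------------------------------
# fixture persistence


def save_scaffolds(scaffolds: list[ScaffoldDefinition], path: str | Path) -> None:
    payload = [
        {
            "category": s.category,
            "smarts": s.smarts,
            "core_smiles": s.core_smiles,
            "features": list(s.features),
            "provenance": s.provenance,
            "policy_hash": s.policy_hash,
        }
        for s in scaffolds
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_scaffolds(path: str | Path | None = None) -> list[ScaffoldDefinition]:
    """Load scaffold definitions; defaults to the fixtures shipped with the
    package, ordered by screening priority."""
    if path is None:
        ref = resources.files("aaascreen").joinpath("data/scaffolds.yaml")
        payload = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
    scaffolds = [ScaffoldDefinition(**entry) for entry in payload]
    order = {c: i for i, c in enumerate(CATEGORIES)}
    scaffolds.sort(key=lambda s: order.get(s.category, 99))
    return scaffolds


def reference_set_path() -> Path:
    """Path of the shipped reference-set fixture (synthetic surrogate of the
    literature curation; see the fixture's header and the methods note)."""
    return Path(str(resources.files("aaascreen").joinpath("data/reference_set_synthetic.csv")))


def load_reference_set() -> ReferenceSet:
    return ReferenceSet.from_csv(reference_set_path())
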