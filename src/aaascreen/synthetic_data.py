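"""Seeded generators for every input of the screen, with known ground truth.

The generators emulate the three inputs of the study: a natural-product
library to screen (scaffold-decorated true positives, near-miss decoys
lacking exactly one key group, and unrelated natural-product decoys), a
taxonomy table with synonym chains, an occurrence table linking compounds
to species, and an externally-predicted toxicity table.  Every output is a
pure function of the :class:`SyntheticSpec` (identical seed and spec give
byte-identical files) and is accompanied by a ``truth`` record of the
planted quantities, so each pipeline stage can be tested end to end
without downloads.

``study_scale_spec`` returns the generation conditions matching the
headline shape of the published screen: 238 analogues split 79/125/34
across the three categories, 175 species in 13 families of Magnoliopsida,
44 of them traditional medicines, and 781 occurrence records whose
marginals plant the printed tallies (80 compounds in more than 2 species,
17 in more than 10, 22 species with more than 10 analogues, a unique
most-diverse species, and a 52-species union for the two flagged
aristolochic acids).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem_io import Molecule, from_smiles
from .errors import InputError
from .scaffolds import CATEGORIES, ScaffoldDefinition, load_scaffolds

# ---------------------------------------------------------------------------
# category cores and formula-verified exemplar structures

#: undecorated category scaffolds used to build positives
CORES: dict[str, str] = {
    # 3,4-methylenedioxy-10-nitrophenanthrene-1-carboxylic acid (= aristolochic acid II)
    "aristolochic_acid": "OC(=O)c1cc2OCOc2c2c3ccccc3cc([N+](=O)[O-])c12",
    # phenanthrene-fused five-membered lactam with the 3,4-dioxole (= aristolactam II type)
    "aristolactam": "O=C1Nc2cc3ccccc3c3c2c1cc1OCOc13",
    # N-methyl 1,2-methylenedioxy-4,5-dioxoaporphine (cepharadione-type)
    "dioxoaporphine": "O=C1C(=O)N(C)c2cc3ccccc3c4c5OCOc5cc1c24",
}

#: named structures used across tests and fixtures; formulas verified
#: against the literature values given in the comments
EXEMPLARS: dict[str, tuple[str, str | None]] = {
    # C17H11NO7, MW 341.3
    "aristolochic acid I": ("OC(=O)c1cc2OCOc2c2c3cccc(OC)c3cc([N+](=O)[O-])c12",
                            "aristolochic_acid"),
    # C16H9NO6, MW 311.2
    "aristolochic acid II": ("OC(=O)c1cc2OCOc2c2c3ccccc3cc([N+](=O)[O-])c12",
                             "aristolochic_acid"),
    # des-nitro analogue of aristolochic acid II; excluded from the screen
    "aristolic acid II": ("OC(=O)c1cc2OCOc2c2c3ccccc3ccc12", None),
    # C17H11NO4, MW 293.3
    "aristolactam I": ("O=C1Nc2cc3cccc(OC)c3c3c2c1cc1OCOc13", "aristolactam"),
    # parent lactam with the dioxole, C16H9NO3
    "aristolactam II": ("O=C1Nc2cc3ccccc3c3c2c1cc1OCOc13", "aristolactam"),
    # DII-type lactam: hydroxy/methoxy instead of the methylenedioxy; excluded
    "aristolactam DII-type": ("O=C1Nc2cc3ccccc3c3c2c1cc(OC)c3O", None),
    # cepharadione-type dioxoaporphine (N-methyl, 1,2-methylenedioxy)
    "cepharadione-type dioxoaporphine": ("O=C1C(=O)N(C)c2cc3ccccc3c4c5OCOc5cc1c24",
                                         "dioxoaporphine"),
    # asimilobine-type dioxoaporphine (1-OMe, 2-OH), C17H11NO4
    "dioxodehydroasimilobine-type": ("O=C1C(=O)Nc2cc3ccccc3c4c(OC)c(O)cc1c24",
                                     "dioxoaporphine"),
    # 1-desmethoxy variant: loses the 1-O, excluded
    "desmethoxy-dioxoaporphine": ("O=C1C(=O)Nc2cc3ccccc3c4cc(O)cc1c24", None),
}

#: substituents attached at hydrogen-bearing aromatic carbons of a core
SUBSTITUENTS: tuple[str, ...] = ("O", "OC", "C", "Cl", "CC=C(C)C",
                                 "OC1OC(CO)C(O)C(O)C1O")
_DIOXOLE_SUB = "OCH2O-fused"  # handled specially: bridges two adjacent positions

#: non-phenanthrenoid natural-product cores used as unrelated decoys
DECOY_CORES: tuple[str, ...] = (
    "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12",     # quercetin
    "O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12",        # kaempferol
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                     # caffeine
    "O=c1ccc2ccccc2o1",                               # coumarin
    "O=c1ccc2ccc(O)cc2o1",                            # umbelliferone
    "COc1cc(C=O)ccc1O",                               # vanillin
    "C=CCc1ccc2OCOc2c1",                              # safrole
    "O=C(C=CC=Cc1ccc2OCOc2c1)N1CCCCC1",               # piperine
    "COc1ccc2cc3[n+](cc2c1OC)CCc1cc2c(cc1-3)OCO2",    # berberine
    "CC(C)C1CCC(C)CC1O",                              # menthol
    "CC(=C)C1CCC(C)=CC1",                             # limonene
    "CC1(C)C2CCC1(C)C(=O)C2",                         # camphor
    "C=CCc1ccc(O)c(OC)c1",                            # eugenol
    "Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1",                   # resveratrol
    "O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c12",            # naringenin
    "COc1cc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)ccc1O",  # curcumin
    "Cc1cc2c(c(O)c1)C(=O)c1cc(O)cc(O)c1C2=O",         # emodin
    "CC(C)=CCCC(C)=CCO",                              # geraniol
    "CC(C)c1ccc(C)cc1O",                              # thymol
    "O=CC=Cc1ccccc1",                                 # cinnamaldehyde
    "COc1cc(C=CC(=O)O)ccc1O",                         # ferulic acid
    "CN1CCCC1c1cccnc1",                               # nicotine
    "O=C(O)Cc1c[nH]c2ccccc12",                        # indole-3-acetic acid
    "CC(=O)Oc1ccccc1C(=O)O",                          # aspirin-like salicylate
)

#: key-group deletions allowed per category; each deletion makes a molecule
#: that fails its own scaffold while keeping the remaining key groups intact
DELETABLE_FEATURES: dict[str, tuple[str, ...]] = {
    "aristolochic_acid": ("nitro", "carboxylic_acid", "methylenedioxy"),
    "aristolactam": ("lactam_carbonyl", "methylenedioxy"),
    "dioxoaporphine": ("ring_dione",),
}

_DELETION_QUERIES: dict[str, tuple[str, tuple[int, ...]]] = {
    # smarts, indices of matched atoms to remove
    "nitro": ("[NX3+](=O)[O-]", (0, 1, 2)),
    "carboxylic_acid": ("[CX3](=O)[OX2H1]", (0, 1, 2)),
    "methylenedioxy": ("[OX2;R][CH2;R][OX2;R]", (0, 1, 2)),
    "lactam_carbonyl": ("[OX1]=[C;R][#7;R]", (0,)),
    # remove the carbonyl oxygen NOT adjacent to the ring nitrogen, so the
    # lactam survives and only the adjacent-dione motif is lost
    "ring_dione": ("[OX1]=[C;R][C;R](=[OX1])[#7;R]", (0,)),
}


# ---------------------------------------------------------------------------
# spec


@dataclass(frozen=True)
class PlantedMarginals:
    """Explicit row (compound) and column (species) sums for the occurrence
    matrix, with an optional forced overlap between two designated rows."""

    row_counts: tuple[int, ...]
    col_counts: tuple[int, ...]
    overlap_rows: tuple[int, int] = (0, 1)
    overlap: int | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_positives_per_category: int | dict = 20
    n_near_miss: int = 20
    n_unrelated: int = 20
    n_species: int = 50
    synonym_fraction: float = 0.3
    tcm_fraction: float = 0.25
    n_tcm: int | None = None
    occurrence_density: float = 0.08
    planted_marginals: PlantedMarginals | None = None
    include_exemplars: bool = False

    def positives_for(self, category: str) -> int:
        if isinstance(self.n_positives_per_category, dict):
            return self.n_positives_per_category[category]
        return self.n_positives_per_category

    def __post_init__(self):
        counts = [self.n_near_miss, self.n_unrelated, self.n_species]
        counts += [self.positives_for(c) for c in CATEGORIES]
        if any(c < 0 for c in counts):
            raise InputError("synthetic counts must be >= 0")
        for f in (self.synonym_fraction, self.tcm_fraction, self.occurrence_density):
            if not 0.0 <= f <= 1.0:
                raise InputError("synthetic fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# structure decoration


def _open_positions(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetIsAromatic() and a.GetTotalNumHs() == 1]


def _adjacent_open_pairs(mol: Chem.Mol) -> list[tuple[int, int]]:
    pos = set(_open_positions(mol))
    pairs = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in pos and j in pos:
            pairs.append((min(i, j), max(i, j)))
    return sorted(pairs)


def _attach(em: Chem.RWMol, anchor: int, sub_smiles: str) -> None:
    frag = Chem.MolFromSmiles(sub_smiles)
    amap = {}
    for a in frag.GetAtoms():
        new = Chem.Atom(a.GetAtomicNum())
        new.SetFormalCharge(a.GetFormalCharge())
        amap[a.GetIdx()] = em.AddAtom(new)
    for b in frag.GetBonds():
        em.AddBond(amap[b.GetBeginAtomIdx()], amap[b.GetEndAtomIdx()], b.GetBondType())
    em.AddBond(anchor, amap[0], Chem.BondType.SINGLE)


def decorate(core_smiles: str, rng: random.Random, max_subs: int = 3,
             n_subs: int | None = None) -> Chem.Mol:
    """Attach random substituents at open (hydrogen-bearing aromatic)
    positions; ``n_subs`` fixes the count, otherwise 0-``max_subs`` are drawn.

    Raises :class:`InputError` when more substitution sites are requested
    than the scaffold offers.
    """
    mol = Chem.MolFromSmiles(core_smiles)
    if n_subs is None:
        n_subs = rng.randint(0, max_subs)
    open_pos = _open_positions(mol)
    if n_subs > len(open_pos):
        raise InputError(
            f"requested {n_subs} substitution sites, scaffold offers {len(open_pos)}")
    em = Chem.RWMol(mol)
    choices = list(SUBSTITUENTS) + [_DIOXOLE_SUB]
    used: set[int] = set()
    for _ in range(n_subs):
        sub = rng.choice(choices)
        if sub == _DIOXOLE_SUB:
            pairs = [p for p in _adjacent_open_pairs(em.GetMol())
                     if not (set(p) & used)]
            if not pairs:
                continue
            i, j = rng.choice(pairs)
            o1 = em.AddAtom(Chem.Atom(8))
            c = em.AddAtom(Chem.Atom(6))
            o2 = em.AddAtom(Chem.Atom(8))
            em.AddBond(i, o1, Chem.BondType.SINGLE)
            em.AddBond(o1, c, Chem.BondType.SINGLE)
            em.AddBond(c, o2, Chem.BondType.SINGLE)
            em.AddBond(o2, j, Chem.BondType.SINGLE)
            used |= {i, j}
        else:
            avail = [p for p in _open_positions(em.GetMol()) if p not in used]
            if not avail:
                break
            anchor = rng.choice(avail)
            _attach(em, anchor, sub)
            used.add(anchor)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return out


def delete_feature(mol: Chem.Mol, feature: str) -> Chem.Mol:
    """Remove one named key group, returning a sanitised molecule."""
    smarts, remove_idx = _DELETION_QUERIES[feature]
    match = mol.GetSubstructMatch(Chem.MolFromSmarts(smarts))
    if not match:
        raise InputError(f"molecule has no {feature} group to delete")
    em = Chem.RWMol(mol)
    for i in sorted((match[k] for k in remove_idx), reverse=True):
        em.RemoveAtom(i)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return out


# ---------------------------------------------------------------------------
# library generation


@dataclass
class SyntheticLibrary:
    """Generated structure library with per-record ground truth.

    ``molecules`` are ordered positives (category block order), then
    near-miss decoys, then unrelated decoys — the order a screen of the
    library will number hits in.
    """

    molecules: list[Molecule]
    positives: list[tuple[str, str]]              # (name, category) in block order
    near_miss: list[tuple[str, str, str]]         # (name, nearest category, deleted feature)
    unrelated: list[str]
    spec: SyntheticSpec

    @property
    def truth(self) -> dict:
        return {
            "n_positives": {c: sum(1 for _, cat in self.positives if cat == c)
                            for c in CATEGORIES},
            "positives": {n: c for n, c in self.positives},
            "near_miss": {n: {"nearest": c, "deleted": f} for n, c, f in self.near_miss},
            "unrelated": list(self.unrelated),
        }

    def write_smiles(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# seed={self.spec.seed}\n")
            for m in self.molecules:
                fh.write(f"{m.canonical_smiles} {m.name}\n")


def generate_library(spec: SyntheticSpec,
                     scaffolds: list[ScaffoldDefinition] | None = None) -> SyntheticLibrary:
    """Generate positives, near-miss decoys and unrelated decoys.

    Positives always contain their category scaffold (substituents attach
    only at hydrogen-bearing aromatic carbons); every near-miss is verified
    to match no scaffold; all structures are valid, canonical and unique.
    """
    scaffolds = scaffolds or load_scaffolds()
    queries = {s.category: s.query for s in scaffolds}
    rng = random.Random(spec.seed)
    seen: set[str] = set()
    molecules: list[Molecule] = []
    positives: list[tuple[str, str]] = []
    near_miss: list[tuple[str, str, str]] = []
    unrelated: list[str] = []

    def admit(mol: Chem.Mol, name: str) -> Molecule | None:
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            return None
        seen.add(smi)
        m = from_smiles(smi, name=name, source_tag="synthetic")
        molecules.append(m)
        return m

    for cat in CATEGORIES:
        want = spec.positives_for(cat)
        made = 0
        if spec.include_exemplars:
            for ex_name, (smi, ex_cat) in EXEMPLARS.items():
                if ex_cat == cat and made < want:
                    if admit(Chem.MolFromSmiles(smi), ex_name) is not None:
                        positives.append((ex_name, cat))
                        made += 1
        if made < want:  # the bare core anchors the category's MCS
            if admit(Chem.MolFromSmiles(CORES[cat]), f"pos-{cat}-{made + 1:03d}") is not None:
                positives.append((f"pos-{cat}-{made + 1:03d}", cat))
                made += 1
        attempts = 0
        while made < want:
            attempts += 1
            if attempts > 200 * want:
                raise InputError(f"cannot generate {want} unique positives for {cat}")
            mol = decorate(CORES[cat], rng)
            name = f"pos-{cat}-{made + 1:03d}"
            if admit(mol, name) is not None:
                assert mol.HasSubstructMatch(queries[cat])
                positives.append((name, cat))
                made += 1

    made = 0
    attempts = 0
    while made < spec.n_near_miss:
        attempts += 1
        if attempts > 300 * max(1, spec.n_near_miss):
            raise InputError("cannot generate enough unique near-miss decoys")
        cat = CATEGORIES[made % len(CATEGORIES)]
        feature = rng.choice(DELETABLE_FEATURES[cat])
        base = decorate(CORES[cat], rng, max_subs=2)
        if feature == "methylenedioxy":
            # only the scaffold's own dioxole may be present, so exactly one
            # deletion removes the key group
            if base.HasSubstructMatch(Chem.MolFromSmarts("C1Oc2ccccc2O1")) and \
               len(base.GetSubstructMatches(
                   Chem.MolFromSmarts("[OX2;R][CH2;R][OX2;R]"))) > 1:
                continue
        try:
            broken = delete_feature(base, feature)
        except InputError:
            continue
        if any(broken.HasSubstructMatch(q) for q in queries.values()):
            continue
        name = f"nearmiss-{cat}-{made + 1:03d}"
        if admit(broken, name) is not None:
            near_miss.append((name, cat, feature))
            made += 1

    decoys = list(DECOY_CORES)
    made = 0
    attempts = 0
    while made < spec.n_unrelated:
        attempts += 1
        if attempts > 300 * max(1, spec.n_unrelated):
            raise InputError("cannot generate enough unique unrelated decoys")
        smi = decoys[made % len(decoys)]
        mol = Chem.MolFromSmiles(smi)
        if made >= len(decoys):  # decorate for uniqueness beyond the shipped list
            try:
                mol = decorate(smi, rng, max_subs=2)
            except InputError:
                continue
        assert not any(mol.HasSubstructMatch(q) for q in queries.values())
        name = f"decoy-{made + 1:03d}"
        if admit(mol, name) is not None:
            unrelated.append(name)
            made += 1

    return SyntheticLibrary(molecules, positives, near_miss, unrelated, spec)


# ---------------------------------------------------------------------------
# taxonomy + occurrence generation

_GENUS_FAMILY: tuple[tuple[str, str], ...] = (
    ("Aristolochia", "Aristolochiaceae"), ("Aristolochia", "Aristolochiaceae"),
    ("Aristolochia", "Aristolochiaceae"), ("Aristolochia", "Aristolochiaceae"),
    ("Asarum", "Aristolochiaceae"), ("Asarum", "Aristolochiaceae"),
    ("Thottea", "Aristolochiaceae"),
    ("Piper", "Piperaceae"), ("Peperomia", "Piperaceae"),
    ("Houttuynia", "Saururaceae"), ("Saururus", "Saururaceae"),
    ("Fissistigma", "Annonaceae"), ("Uvaria", "Annonaceae"),
    ("Goniothalamus", "Annonaceae"), ("Polyalthia", "Annonaceae"),
    ("Clematis", "Ranunculaceae"), ("Thalictrum", "Ranunculaceae"),
    ("Stephania", "Menispermaceae"), ("Cissampelos", "Menispermaceae"),
    ("Litsea", "Lauraceae"), ("Lindera", "Lauraceae"),
    ("Doryphora", "Monimiaceae"),
    ("Corydalis", "Papaveraceae"),
    ("Antidesma", "Phyllanthaceae"),
    ("Combretum", "Combretaceae"),
    ("Magnolia", "Magnoliaceae"),
    ("Zanthoxylum", "Rutaceae"),
)

_SYLLABLES = ("ba", "ca", "da", "fa", "ga", "la", "ma", "na", "pa", "ra", "sa", "ta",
              "be", "ce", "de", "le", "me", "ne", "re", "se", "te", "vi", "lo", "ru")
_EPITHET_SUFFIX = ("ensis", "ana", "ata", "osa", "ifolia", "icola", "oides", "ii")
_AUTHOR_TAILS = ("L.", "(Thunb.) Miq.", "Y.C.Wu", "Hance", "Champ. ex Benth.")
_PINYIN = ("Fang", "Ji", "Mu", "Tong", "Xin", "Cao", "Teng", "Gen", "Hua", "Feng",
           "Xiang", "Bai", "Shan", "Zhong", "Dou", "Ling")

_EXEMPLAR_SPECIES = (
    ("Aristolochia kaempferi", "Han Zhong Fang Ji"),
    ("Aristolochia contorta", "Ma Dou Ling"),
    ("Aristolochia manshuriensis", "Guan Mu Tong"),
    ("Aristolochia mollissima", "Xun Gu Feng"),
    ("Aristolochia fangchi", "Guang Fang Ji"),
    ("Houttuynia cordata", "Yu Xing Cao"),
)


def _epithet(rng: random.Random) -> str:
    stem = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(1, 2)))
    return stem + rng.choice(_EPITHET_SUFFIX)


def _tcm_name(rng: random.Random) -> str:
    return " ".join(rng.choice(_PINYIN) for _ in range(rng.randint(2, 3)))


@dataclass
class SyntheticSources:
    taxonomy: pd.DataFrame
    occurrences: pd.DataFrame
    truth: dict

    def write(self, taxonomy_path: str | Path, occurrence_path: str | Path,
              seed: int) -> None:
        for path, df in ((taxonomy_path, self.taxonomy), (occurrence_path, self.occurrences)):
            with open(path, "w", encoding="utf-8", newline="") as fh:
                fh.write(f"# seed={seed}\n")
                df.to_csv(fh, index=False)


def realize_marginals(pm: PlantedMarginals) -> list[list[int]]:
    """Greedy bipartite realization of planted row/column sums.

    Rows are processed in descending degree (the two overlap rows first
    when an overlap is forced) and connected to the columns with the
    largest remaining capacity; infeasible marginals raise
    :class:`InputError`.  Returns, per row, the sorted list of column
    indices set to 1.
    """
    if sum(pm.row_counts) != sum(pm.col_counts):
        raise InputError("planted row and column sums disagree")
    cap = list(pm.col_counts)
    assignment: list[list[int] | None] = [None] * len(pm.row_counts)

    def take(k: int, allowed) -> list[int]:
        avail = [c for c in allowed if cap[c] > 0]
        if len(avail) < k:
            raise InputError("planted marginals are infeasible")
        avail.sort(key=lambda c: (-cap[c], c))
        chosen = avail[:k]
        for c in chosen:
            cap[c] -= 1
        return sorted(chosen)

    order = sorted(range(len(pm.row_counts)), key=lambda r: (-pm.row_counts[r], r))
    if pm.overlap is not None:
        r0, r1 = pm.overlap_rows
        assignment[r0] = take(pm.row_counts[r0], range(len(cap)))
        shared = take(pm.overlap, assignment[r0])
        rest = take(pm.row_counts[r1] - pm.overlap,
                    set(range(len(cap))) - set(assignment[r0]))
        assignment[r1] = sorted(shared + rest)
        order = [r for r in order if r not in (r0, r1)]
    for r in order:
        assignment[r] = take(pm.row_counts[r], range(len(cap)))
    if any(c != 0 for c in cap):  # pragma: no cover - take() exhausts exactly
        raise InputError("planted marginals are infeasible (stranded capacity)")
    return assignment  # type: ignore[return-value]


def generate_sources(spec: SyntheticSpec, library: SyntheticLibrary) -> SyntheticSources:
    """Generate a taxonomy table with synonym chains and an occurrence table.

    Occurrence cells are sampled at ``occurrence_density`` or forced to the
    planted marginals; raw species names mix accepted names, synonyms,
    author-cited and loosely formatted variants — all resolvable.
    """
    rng = random.Random(spec.seed + 1)
    n = spec.n_species
    species: list[tuple[str, str, str]] = []  # (name, genus, family)
    used_names: set[str] = set()
    exemplar_tcm: dict[str, str] = {}
    if spec.include_exemplars:
        for name, tcm in _EXEMPLAR_SPECIES[:n]:
            genus = name.split()[0]
            family = next(f for g, f in _GENUS_FAMILY if g == genus)
            species.append((name, genus, family))
            used_names.add(name)
            exemplar_tcm[name] = tcm
    i = len(species)
    while len(species) < n:
        genus, family = _GENUS_FAMILY[i % len(_GENUS_FAMILY)]
        name = f"{genus} {_epithet(rng)}"
        i += 1
        if name in used_names:
            continue
        used_names.add(name)
        species.append((name, genus, family))

    n_tcm = spec.n_tcm if spec.n_tcm is not None else round(spec.tcm_fraction * n)
    n_tcm = min(n_tcm, n)
    tcm_names = {}
    for idx in range(n_tcm):
        name = species[idx][0]
        tcm_names[name] = exemplar_tcm.get(name, _tcm_name(rng))

    rows = []
    synonyms_of: dict[str, list[str]] = {}
    for idx, (name, genus, family) in enumerate(species):
        rows.append({"name": name, "status": "accepted", "accepted_name": name,
                     "genus": genus, "family": family, "class": "Magnoliopsida",
                     "common_names": "", "tcm_name": tcm_names.get(name, "")})
        if rng.random() < spec.synonym_fraction:
            syn = f"{genus} {_epithet(rng)}"
            if syn in used_names:
                continue
            used_names.add(syn)
            rows.append({"name": syn, "status": "synonym", "accepted_name": name,
                         "genus": genus, "family": family, "class": "Magnoliopsida",
                         "common_names": "", "tcm_name": ""})
            synonyms_of.setdefault(name, []).append(syn)
            if idx % 5 == 0:  # occasionally chain synonym -> synonym -> accepted
                syn2 = f"{genus} {_epithet(rng)}"
                if syn2 not in used_names:
                    used_names.add(syn2)
                    rows.append({"name": syn2, "status": "synonym", "accepted_name": syn,
                                 "genus": genus, "family": family,
                                 "class": "Magnoliopsida", "common_names": "",
                                 "tcm_name": ""})
                    synonyms_of.setdefault(name, []).append(syn2)
    taxonomy = pd.DataFrame(rows)

    hit_names = [name for name, _cat in library.positives]
    if spec.planted_marginals is not None:
        pm = spec.planted_marginals
        if len(pm.row_counts) != len(hit_names) or len(pm.col_counts) != n:
            raise InputError("planted marginal lengths do not match library/species")
        assignment = realize_marginals(pm)
    else:
        assignment = []
        for r in range(len(hit_names)):
            cols = [c for c in range(n) if rng.random() < spec.occurrence_density]
            if not cols:
                cols = [r % n]
            assignment.append(cols)
        covered = {c for cols in assignment for c in cols}
        for c in set(range(n)) - covered:  # every species hosts >= 1 compound
            assignment[c % len(hit_names)].append(c)
        assignment = [sorted(set(cols)) for cols in assignment]

    occ_rows = []
    style = 0
    for r, cols in enumerate(assignment):
        for c in cols:
            accepted = species[c][0]
            style = (style + 1) % 4
            if style == 0:
                raw = accepted
            elif style == 1:
                raw = rng.choice(synonyms_of[accepted]) if accepted in synonyms_of else accepted
            elif style == 2:
                raw = f"{accepted} {rng.choice(_AUTHOR_TAILS)}"
            else:
                g, e = accepted.split(" ", 1)
                raw = f"  {g.upper()} {e} "
            occ_rows.append({"compound_key": hit_names[r],
                             "raw_species_name": raw,
                             "reference": f"Ref-{r:04d}-{c:04d}"})
    occurrences = pd.DataFrame(occ_rows)

    row_sums = [len(cols) for cols in assignment]
    col_sums = [0] * n
    for cols in assignment:
        for c in cols:
            col_sums[c] += 1
    present = [i for i, s in enumerate(col_sums) if s > 0]
    families = {species[i][2] for i in present}
    ranked = sorted(present, key=lambda i: (-col_sums[i], species[i][0]))
    truth = {
        "n_records": len(occ_rows),
        "n_species_present": len(present),
        "n_families": len(families),
        "n_tcm_present": sum(1 for i in present if species[i][0] in tcm_names),
        "species_per_compound": row_sums,
        "compounds_per_species": {species[i][0]: col_sums[i] for i in present},
        "top_species": species[ranked[0]][0] if ranked else None,
        "tally_gt": {t: sum(1 for s in row_sums if s > t) for t in (2, 10)},
        "species_tally_gt10": sum(1 for i in present if col_sums[i] > 10),
    }
    if spec.planted_marginals is not None and spec.planted_marginals.overlap is not None:
        r0, r1 = spec.planted_marginals.overlap_rows
        union = set(assignment[r0]) | set(assignment[r1])
        truth["flagged_union"] = len(union)
        truth["flagged_compounds"] = [hit_names[r0], hit_names[r1]]
    return SyntheticSources(taxonomy, occurrences, truth)


# ---------------------------------------------------------------------------
# toxicity generation

#: per-category (mean, sd) of each generated toxicity column; probability
#: columns are clipped to [0, 1], doses to >= 1 mg/kg
TOXICITY_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "ames_probability": {"aristolochic_acid": (0.9, 0.05), "aristolactam": (0.7, 0.05),
                         "dioxoaporphine": (0.6, 0.05)},
    "carcinogenicity_probability": {"aristolochic_acid": (0.85, 0.05),
                                    "aristolactam": (0.65, 0.05),
                                    "dioxoaporphine": (0.55, 0.05)},
    "ld50_rat_oral_mg_kg": {"aristolochic_acid": (100.0, 30.0),
                            "aristolactam": (400.0, 100.0),
                            "dioxoaporphine": (600.0, 150.0)},
}


@dataclass
class SyntheticToxicity:
    table: pd.DataFrame
    truth: dict

    def write(self, path: str | Path, seed: int) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# seed={seed}\n")
            self.table.to_csv(fh, index=False)


def generate_toxicity(spec: SyntheticSpec, library: SyntheticLibrary,
                      model: dict | None = None) -> SyntheticToxicity:
    """Per-compound toxicity table with planted per-category Gaussians,
    standing in for an external predictor's output (ingested, not computed)."""
    model = model or TOXICITY_MODEL
    rng = random.Random(spec.seed + 2)
    smiles_of = {m.name: m.canonical_smiles for m in library.molecules}
    rows = []
    for name, cat in library.positives:
        entry = {"canonical_smiles": smiles_of[name], "name": name, "category": cat}
        for col, percat in model.items():
            mean, sd = percat[cat]
            val = rng.gauss(mean, sd)
            if "probability" in col:
                val = min(1.0, max(0.0, val))
            else:
                val = max(1.0, val)
            entry[col] = round(val, 6)
        rows.append(entry)
    df = pd.DataFrame(rows)
    return SyntheticToxicity(df, {"model": model})


# ---------------------------------------------------------------------------
# study-scale conditions


def study_marginals() -> PlantedMarginals:
    """Occurrence marginals matching the published headline tallies.

    781 records over 238 compounds x 175 species; 17 compounds in more
    than 10 species and 80 in more than 2; 22 species with more than 10
    analogues, a unique top species, and the two flagged aristolochic
    acids present in 52 species altogether.
    """
    rows = ([40, 30, 20, 18, 16, 14, 13, 12, 12] + [11] * 8
            + [4] * 13 + [3] * 50 + [2] * 158)
    cols = ([35, 20, 18, 16, 15, 14, 13, 12, 12, 12] + [11] * 12
            + [4] * 23 + [3] * 130)
    assert sum(rows) == sum(cols) == 781 and len(rows) == 238 and len(cols) == 175
    return PlantedMarginals(tuple(rows), tuple(cols), overlap_rows=(0, 1), overlap=18)


def study_scale_spec(seed: int = 0) -> SyntheticSpec:
    """Generation conditions of the published screen's result tables."""
    return SyntheticSpec(
        seed=seed,
        n_positives_per_category={"aristolochic_acid": 79, "aristolactam": 125,
                                  "dioxoaporphine": 34},
        n_near_miss=17,
        n_unrelated=0,
        n_species=175,
        synonym_fraction=0.3,
        n_tcm=44,
        planted_marginals=study_marginals(),
        include_exemplars=True,
    )


def write_truth(path: str | Path, library: SyntheticLibrary,
                sources: SyntheticSources | None = None,
                toxicity: SyntheticToxicity | None = None) -> None:
    payload = {"spec": {k: v for k, v in asdict(library.spec).items()
                        if k != "planted_marginals"},
               "library": library.truth}
    if sources is not None:
        payload["sources"] = sources.truth
    if toxicity is not None:
        payload["toxicity"] = toxicity.truth
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
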