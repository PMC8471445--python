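"""Maintenance script: regenerate the shipped data fixtures.

Builds ``src/aaascreen/data/reference_set_synthetic.csv`` — a synthetic
surrogate of the literature-curated reference set (109 members: formula-
verified exemplars plus deterministically decorated core variants, split
45/45/19 across the three categories) — and freezes the scaffolds derived
from it into ``src/aaascreen/data/scaffolds.yaml``.

Run from the repository root:  python scripts/build_fixtures.py
"""

import csv
import random
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from rdkit import Chem  # noqa: E402

from aaascreen.scaffolds import ReferenceSet, derive_category_scaffolds, save_scaffolds  # noqa: E402
from aaascreen.screening import FEATURE_SMARTS  # noqa: E402
from aaascreen.synthetic_data import CORES, EXEMPLARS, decorate  # noqa: E402

SEED = 20240901
SPLIT = {"aristolochic_acid": 45, "aristolactam": 45, "dioxoaporphine": 19}
DATA = Path(__file__).resolve().parents[1] / "src" / "aaascreen" / "data"


def build_reference_rows():
    rng = random.Random(SEED)
    rows = []
    for cat, want in SPLIT.items():
        seen = set()
        made = 0
        for name, (smi, ex_cat) in EXEMPLARS.items():
            if ex_cat == cat:
                canon = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
                if canon not in seen:
                    seen.add(canon)
                    rows.append({"smiles": canon, "name": name, "category": cat})
                    made += 1
        core = Chem.MolToSmiles(Chem.MolFromSmiles(CORES[cat]))
        if core not in seen:
            seen.add(core)
            rows.append({"smiles": core, "name": f"ref-{cat}-core", "category": cat})
            made += 1
        while made < want:
            mol = decorate(CORES[cat], rng)
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            made += 1
            rows.append({"smiles": canon, "name": f"ref-{cat}-{made:03d}", "category": cat})
    return rows


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    rows = build_reference_rows()
    ref_path = DATA / "reference_set_synthetic.csv"
    with open(ref_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["smiles", "name", "category"])
        w.writeheader()
        w.writerows(rows)
    print(f"wrote {len(rows)} reference members to {ref_path}")

    refs = ReferenceSet.from_csv(ref_path)
    scaffolds = derive_category_scaffolds(refs, feature_smarts=FEATURE_SMARTS)
    for s in scaffolds:
        # the concrete core prototype is pinned to the category's generator
        # core so key-group diagnosis covers the methylenedioxy pattern even
        # where the MCS only retains the two exocyclic oxygens
        s.core_smiles = Chem.MolToSmiles(Chem.MolFromSmiles(CORES[s.category]))
        s.features = [name for name, sm in FEATURE_SMARTS.items()
                      if Chem.MolFromSmiles(s.core_smiles).HasSubstructMatch(
                          Chem.MolFromSmarts(sm))]
        s.provenance = (f"MCS of the {len(s.support)}-member synthetic surrogate "
                        f"reference set (seed {SEED})")
    save_scaffolds(scaffolds, DATA / "scaffolds.yaml")
    for s in scaffolds:
        print(f"{s.category}: {s.smarts}")
        print(f"  features: {s.features}")


if __name__ == "__main__":
    main()
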