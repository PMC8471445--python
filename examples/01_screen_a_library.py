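"""Screen a small natural-product library for aristolochic acid analogues.

Builds a tiny library mixing two genuine analogues, one reported-but-
excluded compound and two unrelated natural products, screens it against
the shipped category scaffolds, and prints the classification.
"""

from aaascreen import classify, from_smiles, load_scaffolds, register, screen_library
from aaascreen.synthetic_data import EXEMPLARS

library = [
    from_smiles(EXEMPLARS["aristolochic acid I"][0], name="aristolochic acid I"),
    from_smiles(EXEMPLARS["aristolactam I"][0], name="aristolactam I"),
    from_smiles(EXEMPLARS["aristolic acid II"][0], name="aristolic acid II"),
    from_smiles("Cn1cnc2c1c(=O)n(C)c(=O)n2C", name="caffeine"),
    from_smiles("O=c1ccc2ccccc2o1", name="coumarin"),
]

scaffolds = load_scaffolds()
registry = register(library)
result = screen_library(registry, scaffolds)

print(f"{len(registry)} compounds screened, {result.counts['total']} analogues found\n")
for hit in result.hits:
    mol = registry[hit.compound_id]
    print(f"AAAs No. {hit.aaa_number}: {mol.name}  ->  {hit.category}")
for cid in result.non_hit_ids:
    category, _ = classify(registry[cid], scaffolds)
    print(f"not an analogue: {registry[cid].name}")

# The two genuine analogues are classified into their chemotypes and
# numbered in category-block order; aristolic acid II (which lacks the
# nitro group) and the unrelated compounds fall through the screen.
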