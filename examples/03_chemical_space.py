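"""Chemical-space descriptors of a screened analogue set.

Generates a seeded synthetic library, screens it, and summarises the
molecular weight, O/N composition, CLogP and TPSA of the hits — the same
four descriptors used to chart the analogues' chemical space.
"""

from aaascreen import (load_scaffolds, property_summary, property_vector,
                       register, screen_library)
from aaascreen.synthetic_data import SyntheticSpec, generate_library

scaffolds = load_scaffolds()
lib = generate_library(SyntheticSpec(seed=42), scaffolds)
registry = register(lib.molecules)
hits = screen_library(registry, scaffolds).hits

vectors = [property_vector(registry[h.compound_id]) for h in hits]
s = property_summary(vectors)

print(f"{s.n} analogues")
print(f"mean MW:  {s.mean_mw:.2f} g/mol  (range {s.min_mw:.2f}-{s.max_mw:.2f})")
print(f"oxygens:  {s.min_n_oxygen}-{s.max_n_oxygen} per molecule")
print(f"nitrogens: {s.min_n_nitrogen}-{s.max_n_nitrogen} per molecule")
print(f"CLogP:    {s.min_clogp:.2f} to {s.max_clogp:.2f}")
print(f"TPSA:     {s.min_tpsa:.2f} to {s.max_tpsa:.2f} A^2")

# Every analogue carries at least one nitrogen (the nitro or lactam
# nitrogen of its scaffold) and several oxygens; CLogP and TPSA spread
# with the decorations (glycosides push TPSA up and CLogP down).
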