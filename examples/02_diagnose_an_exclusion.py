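"""Explain why a reported analogue fails the screen.

Aristolic acid II is a des-nitro congener of aristolochic acid II: it was
reported as an analogue but contains no nitro group, so it cannot match
the nitro-phenanthrene carboxylic acid scaffold.  The diagnosis names the
missing key group, measures the residual shared core, and localises the
similarity loss on specific atoms.
"""

from aaascreen import diagnose_exclusion, from_smiles, load_scaffolds
from aaascreen.synthetic_data import EXEMPLARS

scaffolds = {s.category: s for s in load_scaffolds()}
mol = from_smiles(EXEMPLARS["aristolic acid II"][0], name="aristolic acid II")

report = diagnose_exclusion(mol, scaffolds["aristolochic_acid"])
print(f"compound: {mol.name}")
print(f"nearest chemotype: {report.nearest_category}")
print(f"missing key groups: {report.missing_features}")
print(f"shared core with the scaffold: {report.mcs_with_scaffold.num_bonds} bonds")

charges = report.partial_charges
print(f"PEOE charge sum: {sum(charges):+.6f} (equals the formal charge)")
top = sorted(range(len(report.atom_weight_map)),
             key=lambda i: abs(report.atom_weight_map[i]), reverse=True)[:3]
print(f"atoms driving the similarity difference: {top}")

# Expected output: missing key groups ['nitro'] — the compound keeps the
# methylenedioxy and carboxylic acid, so the nitro group alone explains
# the exclusion, matching the known structure-toxicity rationale (the
# nitro group is the precursor of the genotoxic N-hydroxylamine).
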