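# Methods

This note records the models, numerical choices and limitations behind
`aaascreen`, in the order the pipeline runs.

## Structure handling

All chemistry is 2-D. On input every structure is sanitised once
(valence check + aromaticity perception), stereochemistry is discarded,
and only the largest fragment is kept (occurrence data refer to the parent
natural product, not its salts or solvates; ties on heavy-atom count break
by molecular weight, then canonical SMILES order). The canonical SMILES is
the registry identity: two encodings of the same graph always collapse to
one entry, and source tags are unioned on merge. Tautomers are **not**
normalised — the screen treats tautomeric drawings as distinct compounds,
a documented source of divergence for libraries drawn with inconsistent
conventions.

## Scaffolds

Each analogue chemotype is represented by the maximum common substructure
(MCS) of its reference compounds under the default match policy:
element-exact atoms, order-exact bonds (aromatic matches aromatic only),
no ring-membership constraint. The policy is configurable because MCS
"defaults" differ across toolkit versions; the policy hash is stored next
to each scaffold. The search is connected-MCS only (the chemotype cores
are connected), maximises bond count, and accepts a wall-clock budget
(default 60 s per category — derivation over the shipped reference set
finishes in well under a second, so the budget never binds in practice).
When the budget does expire the best-so-far result is returned and flagged
`complete: false`. Determinism holds for fixed inputs, policy and budget;
the tie-break among equally large candidates is the search engine's.

Because MCS search is NP-hard, derived scaffolds are frozen to
`data/scaffolds.yaml` and screening always loads the fixture;
re-derivation (`aaascreen derive-scaffolds`, `scripts/build_fixtures.py`)
is an explicit maintenance step, and a test asserts the fixture matches
what re-derivation produces.

The reference curation behind the published chemotypes is not public, so
the shipped `reference_set_synthetic.csv` is a synthetic surrogate with
the same shape: 109 members split 45/45/19 across the categories (the
published curation's per-category split is unstated; the 45/45/19 choice
mirrors the relative abundance of the chemotypes among the screened hits).
It contains formula-verified exemplars — aristolochic acids I/II
(C17H11NO7 / C16H9NO6), aristolactams I/II (C17H11NO4 / C16H9NO3),
cepharadione-type and asimilobine-type dioxoaporphines, plus the three
classic exclusions (aristolic acid II, a DII-type lactam, a desmethoxy
dioxoaporphine) — and deterministically decorated core variants.

Two consequences of the mixed dioxoaporphine membership are intentional.
First, because the category contains both methylenedioxy (cepharadione-
type) and methoxy/hydroxy (asimilobine-type) members, its derived MCS
keeps only the two exocyclic oxygens at the 1,2-positions rather than the
full dioxole ring — so either oxygenation pattern matches, while the
1-desmethoxy exclusion does not. Second, each scaffold's concrete core
prototype is pinned to the generator core (with the full dioxole), so the
key-group vocabulary of exclusion diagnosis includes `methylenedioxy` for
every chemotype that can carry it.

## Screening and numbering

A compound is classified by the **first** scaffold it contains in the
fixed priority order aristolochic acids → aristolactams →
dioxoaporphines; all matching categories are retained so the priority
decision stays auditable. Serial numbers ("AAAs No.") are run-local
identifiers: unique, contiguous from 1, grouped in category blocks in
priority order, first-occurrence order within a block. They reproduce the
published numbering's block structure, not its per-compound assignments
(the original within-category ordering is unstated). The match witness
reported for each hit is the lexicographically smallest atom-index
embedding, for determinism.

## Exclusion diagnosis

The named key groups are SMARTS queries shipped in
`screening.FEATURE_SMARTS`: nitro (either charge convention),
methylenedioxy (aryl-fused dioxole), carboxylic acid, in-ring lactam
carbonyl, and adjacent in-ring dione. An exclusion's `missing_features`
are the nearest scaffold's features absent from the molecule. The nearest
scaffold is chosen by Dice-normalised MCS overlap
(2·shared bonds / (core bonds + molecule bonds)), with priority order
breaking ties; the assignment is genuinely ambiguous when the lost group
(typically a methylenedioxy) is shared across chemotypes, so pipelines
that know the intended chemotype should pass it explicitly.

**Gasteiger (PEOE) charges** are computed in-package: at step *k* each
bond transfers charge proportional to the electronegativity difference
χ = a + b·q + c·q², damped by (1/2)^k (default 8 iterations; 12 for
sub-milli-electron convergence), normalised by the cation
electronegativity of the less electronegative partner (hydrogen's
conventional 20.02). Formal charge on groups of equivalent terminal O/S
atoms (nitro, carboxylate) is delocalised evenly before iterating. Charge
is conserved exactly by construction; parameters cover H, C, N, O, S and
halogens, and an unparameterised element is a hard error naming it. Tests
cross-check against an independent PEOE implementation to < 1e-3.

**Similarity maps** follow the published atom-weight formulation: the
weight of atom *i* is the drop in Dice similarity of count-based circular
fingerprints (default radius 2 folded to 2048 bits; `n_bits=None` keeps
the sparse space) when every fingerprint environment involving atom *i*
is removed. Weights are reported raw and max-|w|-normalised. In the
sparse space the implementation agrees with an independent published
implementation to machine precision.

## Descriptors

MW is the sum of standard average atomic weights; CLogP is Wildman–
Crippen (open and deterministic — the published analysis does not name
its logP tool, so exact reproduction of a printed CLogP range is treated
as soft); TPSA is the original Ertl N/O fragment table (no S/P
contributions). O/N counts are over the largest fragment. Tests verify
MW and TPSA against independent re-implementations at 1e-6.

## Taxonomy

The resolver works against a static CSV snapshot (name, status, accepted
name, lineage, common/TCM names) rather than a live database, for
reproducibility. Synonym chains of any depth are flattened at load;
dangling or cyclic chains are fatal. Matching is exact first, then
normalized: whitespace collapse, case-fold, author-citation stripping by
the first-two-Latin-tokens heuristic, with the hybrid sign preserved and
`var.`/`subsp.`/`f.` epithets kept. Known limitation: authorship strings
that embed additional Latin-looking tokens before the epithet, and ranks
below forma, are not parsed. Unresolved names are quarantined and
counted, never dropped.

## Relational analytics

The incidence matrix is binary over screened compounds × accepted
species, with per-cell reference provenance; duplicate (compound,
species, reference) triples collapse idempotently (references normalised
only by whitespace trimming). Every headline number is a marginal: "more
than *t*" is a strict inequality throughout, rankings break ties
alphabetically, hazard flags are row unions, and the TCM ranking filters
columns to species with a medicine name. Occurrence records referencing
non-hit compounds are errors, not skips.

## Synthetic data

The generators emulate the study's three inputs with known ground truth.
Positives attach substituents (OH, OCH3, CH3, Cl, prenyl, O-glucosyl,
fused methylenedioxy) only at hydrogen-bearing aromatic carbons, so the
scaffold always survives; near-miss decoys delete exactly one key group
chosen so the remaining groups stay intact (for dioxoaporphines only the
dione is deleted — removing the carbonyl away from the nitrogen keeps the
lactam); unrelated decoys come from a fixed list of non-phenanthrenoid
natural-product cores, verified never to match a scaffold. All outputs
are pure functions of (seed, spec); the seed is recorded in every file
header.

Default conditions are 20 positives per category, 20 near-miss, 20
unrelated decoys, 50 species, synonym fraction 0.3, occurrence density
0.08 — enough to exercise every code path at interactive speed.
`study_scale_spec()` fixes the study-scale conditions instead: 79/125/34
positives, 17 near-miss exclusions, 175 species in 13 Magnoliopsida
families, 44 TCM species, and 781 occurrence records realised from
explicit planted marginals (Gale–Ryser-style greedy realization, largest
residual capacity first) that encode the published tallies: 17 compounds
in more than 10 species, 80 in more than 2, 22 species with more than 10
analogues, a unique most-diverse species, and a 52-species union for the
two flagged aristolochic acids, whose rows are forced to overlap in
exactly 18 columns. Toxicity tables are per-category Gaussians
(probability columns clipped to [0, 1], doses to ≥ 1 mg/kg) standing in
for an external predictor's output — the pipeline only ever ingests
toxicity values, it never computes them.

What passing on synthetic data does **not** show: the surrogate library's
descriptor statistics (e.g. its mean molecular weight) are properties of
the generated decorations, not of the real compounds; real-world name
matching is messier than the generator's resolvable variants; and
tautomer- or salt-inconsistent libraries can split or merge registry
entries. Conclusions about real libraries need the real curation.

## Numerical and degenerate-input conventions

Thresholds default to t ∈ {2, 10}. Empty registries, empty property
sets, fewer than two MCS inputs, and infeasible planted marginals are
errors, not empty results; an empty common subgraph names the first
non-matching pair. Ranking ties are alphabetical everywhere. Counts in
CSV exports are written at full precision except descriptors (3–4
decimals, documented per column).
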