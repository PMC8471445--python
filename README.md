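# aaascreen

Scaffold-based virtual screening of naturally occurring **aristolochic acid
analogues (AAAs)** and relational analysis of their biological sources.

Aristolochic acids are nitro-phenanthrene carboxylic acids, best known from
*Aristolochia* herbs, that cause nephropathy and upper-urinary-tract
carcinoma; their metabolites (aristolactams) and biosynthetic relatives
(4,5-dioxoaporphines) share the phenanthrenoid core and much of the hazard.
Because these compounds keep being isolated from new plants — including
species still sold as traditional medicines — toxicologists and natural-
product chemists need a reproducible way to ask two questions of any
compound library: *which structures are aristolochic acid analogues*, and
*which species contain them*.

`aaascreen` answers both with a transparent, fully 2-D pipeline:

1. **Scaffold derivation** — one maximum common substructure (MCS) per
   chemotype is derived from a curated reference set under an
   element-exact / bond-order-exact match policy:
   - MCS1: nitro-phenanthrene carboxylic acid (aristolochic acids),
   - MCS2: phenanthrene-fused lactam (aristolactams),
   - MCS3: aporphine core with two adjacent ring carbonyls
     (4,5-dioxoaporphines).
2. **Screening** — a library compound is an analogue iff it contains a
   scaffold as a subgraph (substructure search); hits are serially numbered
   ("AAAs No.") in category blocks.
3. **Exclusion diagnosis** — reported analogues that fail the screen are
   explained via missing key groups (nitro, methylenedioxy, carboxylic
   acid, lactam carbonyl, ring dione), the residual MCS with the nearest
   scaffold, Gasteiger (PEOE) partial charges and fingerprint
   similarity-map atom weights.
4. **Chemical space** — MW, O/N counts, Wildman–Crippen CLogP and Ertl
   TPSA per hit, with summaries and chart-data exports.
5. **Biological sources** — raw species names are resolved against a
   taxonomy snapshot (synonym chains flattened, author citations
   stripped), and the compound × species incidence matrix yields the
   headline tallies: species per compound, compounds per species, strict
   "more than *t*" thresholds, traditional-medicine (TCM) ranking, and the
   set of species flagged for containing specific hazard compounds.

A first-class synthetic-data module generates structure libraries
(scaffold-decorated positives, near-miss decoys lacking exactly one key
group, unrelated natural products), taxonomy tables with synonym chains,
occurrence tables with planted marginals, and external-predictor-style
toxicity tables — all seeded, with ground truth alongside — so every stage
is testable without downloads.

## Worked example

`examples/` holds one short narrative script per capability. Screening a
five-compound library (`examples/01_screen_a_library.py`) prints:

```
5 compounds screened, 2 analogues found

AAAs No. 1: aristolochic acid I  ->  aristolochic_acid
AAAs No. 2: aristolactam I  ->  aristolactam
not an analogue: aristolic acid II
not an analogue: caffeine
not an analogue: coumarin
```

Aristolochic acid I and aristolactam I contain their chemotype scaffolds
and receive serial numbers; aristolic acid II — a reported congener that
lacks the nitro group — correctly falls through the screen, and
`examples/02_diagnose_an_exclusion.py` explains why:

```
compound: aristolic acid II
nearest chemotype: aristolochic_acid
missing key groups: ['nitro']
shared core with the scaffold: 23 bonds
PEOE charge sum: +0.000000 (equals the formal charge)
```

The missing nitro group is exactly the structural alert that, after
metabolic reduction, drives the genotoxicity of true aristolochic acids.
`examples/05_full_pipeline.py` runs the whole pipeline at study scale
(238 analogues, 175 species, 781 occurrence records) and prints every
headline count of the run report.

There is also a thin CLI: `aaascreen synth`, `screen`, `properties`,
`sources`, `report`, `derive-scaffolds` (see `aaascreen --help`).

## Data fixtures

The scaffold SMARTS in `src/aaascreen/data/scaffolds.yaml` are the source
of truth for screening; they were derived from
`src/aaascreen/data/reference_set_synthetic.csv`, a 109-member **synthetic
surrogate** of the literature-curated reference set (formula-verified
exemplar structures plus deterministically decorated core variants; see
`docs/methods.md`). `scripts/build_fixtures.py` regenerates both.

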