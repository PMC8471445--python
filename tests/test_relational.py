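import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaascreen.chem_io import from_smiles, register
from aaascreen.errors import RelationalError
from aaascreen.relational import (OccurrenceRecord, build_matrix,
                                  compounds_per_species, hazard_flags,
                                  ingest_toxicity_table, species_per_compound,
                                  tcm_ranking, threshold_tally)
from aaascreen.screening import ScreenHit, screen_library
from aaascreen.synthetic_data import (PlantedMarginals, SyntheticSpec,
                                      generate_library, generate_sources,
                                      generate_toxicity, realize_marginals)
from aaascreen.taxonomy import load_taxonomy

COLUMNS = ["name", "status", "accepted_name", "genus", "family", "class",
           "common_names", "tcm_name"]


@pytest.fixture()
def toy_taxonomy(tmp_path):
    rows = [
        ["Species alpha", "accepted", "Species alpha", "Species", "Famone",
         "Magnoliopsida", "", "Tcm One"],
        ["Species beta", "accepted", "Species beta", "Species", "Famone",
         "Magnoliopsida", "", ""],
        ["Species gamma", "accepted", "Species gamma", "Species", "Famtwo",
         "Magnoliopsida", "", "Tcm Three"],
        ["Species oldname", "synonym", "Species alpha", "Species", "Famone",
         "Magnoliopsida", "", ""],
    ]
    path = tmp_path / "tax.csv"
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
    return load_taxonomy(path)


def _hits(n):
    return [ScreenHit(i, "aristolochic_acid", ["aristolochic_acid"], i + 1)
            for i in range(n)]


def test_matrix_from_triples(toy_taxonomy):
    records = [OccurrenceRecord(0, "Species alpha", "r1"),
               OccurrenceRecord(0, "Species beta", "r2"),
               OccurrenceRecord(1, "Species alpha", "r3")]
    m = build_matrix(records, _hits(2), toy_taxonomy)
    assert m.data.shape == (2, 2) and m.n_cells == 3
    assert m.n_records == 3 and not m.unresolved


def test_duplicate_records_are_idempotent(toy_taxonomy):
    records = [OccurrenceRecord(0, "Species alpha", "r1")] * 3 + [
        OccurrenceRecord(0, "  Species   alpha ", "r1")]
    m = build_matrix(records, _hits(1), toy_taxonomy)
    assert m.n_cells == 1 and m.n_records == 1
    assert m.provenance[(0, "Species alpha")] == {"r1"}


def test_synonyms_collapse_and_unresolved_are_quarantined(toy_taxonomy):
    records = [OccurrenceRecord(0, "Species oldname", "r1"),
               OccurrenceRecord(0, "Species alpha", "r2"),
               OccurrenceRecord(0, "Unknownia missing", "r3")]
    m = build_matrix(records, _hits(1), toy_taxonomy)
    assert list(m.data.columns) == ["Species alpha"]
    assert m.provenance[(0, "Species alpha")] == {"r1", "r2"}
    assert [r.species for r in m.unresolved] == ["Unknownia missing"]


def test_record_for_non_hit_compound_is_an_error(toy_taxonomy):
    with pytest.raises(RelationalError):
        build_matrix([OccurrenceRecord(5, "Species alpha", "r")], _hits(2), toy_taxonomy)


def test_marginals_and_strict_threshold_tallies(toy_taxonomy):
    records = [OccurrenceRecord(0, "Species alpha", "r1"),
               OccurrenceRecord(0, "Species beta", "r2"),
               OccurrenceRecord(0, "Species gamma", "r3"),
               OccurrenceRecord(1, "Species alpha", "r4")]
    m = build_matrix(records, _hits(2), toy_taxonomy)
    counts = species_per_compound(m)
    assert sorted(counts.tolist()) == [1, 3]
    assert threshold_tally(counts, 2) == 1     # strictly greater than
    assert threshold_tally(counts, 3) == 0
    assert threshold_tally(counts * 0, 0) == 0
    # monotone non-increasing in t
    tallies = [threshold_tally(counts, t) for t in range(0, 5)]
    assert tallies == sorted(tallies, reverse=True)


def test_tallies_invariant_under_record_permutation(toy_taxonomy):
    records = [OccurrenceRecord(i % 2, sp, f"r{i}")
               for i, sp in enumerate(["Species alpha", "Species beta",
                                       "Species gamma", "Species alpha"])]
    base = species_per_compound(build_matrix(records, _hits(2), toy_taxonomy))
    rng = random.Random(0)
    for _ in range(3):
        rng.shuffle(records)
        again = species_per_compound(build_matrix(records, _hits(2), toy_taxonomy))
        assert again.equals(base)


def test_compounds_per_species_ranking_ties_alphabetical(toy_taxonomy):
    records = [OccurrenceRecord(0, "Species alpha", "r"),
               OccurrenceRecord(1, "Species alpha", "r"),
               OccurrenceRecord(0, "Species gamma", "r"),
               OccurrenceRecord(0, "Species beta", "r")]
    ranked = compounds_per_species(build_matrix(records, _hits(2), toy_taxonomy))
    assert list(ranked.index) == ["Species alpha", "Species beta", "Species gamma"]
    assert ranked.tolist() == [2, 1, 1]


def test_hazard_flags_union(toy_taxonomy):
    records = [OccurrenceRecord(0, "Species alpha", "r"),
               OccurrenceRecord(0, "Species beta", "r"),
               OccurrenceRecord(1, "Species gamma", "r")]
    m = build_matrix(records, _hits(2), toy_taxonomy)
    assert hazard_flags(m, [0]) == {"Species alpha", "Species beta"}
    assert hazard_flags(m, [0, 1]) == {"Species alpha", "Species beta", "Species gamma"}
    with pytest.raises(RelationalError):
        hazard_flags(m, [99])


def test_tcm_ranking_filters_and_orders(toy_taxonomy):
    records = [OccurrenceRecord(0, "Species gamma", "r"),
               OccurrenceRecord(1, "Species gamma", "r"),
               OccurrenceRecord(0, "Species alpha", "r"),
               OccurrenceRecord(0, "Species beta", "r")]
    m = build_matrix(records, _hits(2), toy_taxonomy)
    ranking = tcm_ranking(m, toy_taxonomy)
    assert ranking == [("Species gamma", "Tcm Three", 2),
                       ("Species alpha", "Tcm One", 1)]


@settings(max_examples=50, derandomize=True, deadline=None)
@given(counts=st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=40),
       t=st.integers(min_value=0, max_value=30))
def test_threshold_tally_properties(counts, t):
    """Strictness, monotonicity in t, and permutation invariance hold for
    arbitrary count vectors."""
    s = pd.Series(counts)
    tally = threshold_tally(s, t)
    assert tally == sum(1 for c in counts if c > t)
    assert threshold_tally(s, t + 1) <= tally
    assert threshold_tally(s.sample(frac=1, random_state=0), t) == tally


def test_planted_marginals_realized_exactly():
    pm = PlantedMarginals(row_counts=(4, 3, 2, 2, 1), col_counts=(3, 3, 2, 2, 1, 1),
                          overlap_rows=(0, 1), overlap=2)
    assignment = realize_marginals(pm)
    assert [len(cols) for cols in assignment] == list(pm.row_counts)
    col_sums = [sum(1 for cols in assignment for c in cols if c == j)
                for j in range(6)]
    assert col_sums == list(pm.col_counts)
    assert len(set(assignment[0]) & set(assignment[1])) == 2


def test_infeasible_marginals_raise():
    from aaascreen.errors import InputError
    with pytest.raises(InputError):
        realize_marginals(PlantedMarginals((5,), (1, 1)))          # sums disagree
    with pytest.raises(InputError):
        realize_marginals(PlantedMarginals((3,), (2, 1)))          # row exceeds columns


def test_planted_occurrence_truth_recovered(tmp_path, scaffolds):
    spec = SyntheticSpec(seed=21, n_positives_per_category=5, n_near_miss=0,
                         n_unrelated=0, n_species=12,
                         planted_marginals=PlantedMarginals(
                             row_counts=(9,) + (2,) * 14,
                             col_counts=(8, 5, 4, 3, 3, 3, 3, 2, 2, 2, 1, 1),
                             overlap_rows=(0, 1), overlap=1))
    lib = generate_library(spec, scaffolds)
    src = generate_sources(spec, lib)
    src.write(tmp_path / "tax.csv", tmp_path / "occ.csv", spec.seed)
    table = load_taxonomy(tmp_path / "tax.csv")
    registry = register(lib.molecules)
    hits = screen_library(registry, scaffolds).hits
    from aaascreen.relational import read_occurrences
    m = build_matrix(read_occurrences(tmp_path / "occ.csv", registry), hits, table)
    assert species_per_compound(m).tolist() == list(spec.planted_marginals.row_counts)
    ranked = compounds_per_species(m)
    assert ranked.iloc[0] == 8 and ranked.index[0] == src.truth["top_species"]
    assert m.n_records == src.truth["n_records"] == 37
    assert hazard_flags(m, [hits[0].compound_id, hits[1].compound_id]) == \
        set(m.data.columns[m.data.iloc[[0, 1]].any(axis=0)])


# ---------------------------------------------------------------------------
# toxicity ingestion


def test_toxicity_join_orphans_and_nulls(tmp_path, toy_taxonomy):
    mols = [from_smiles("CCO", name="a"), from_smiles("CCCO", name="b"),
            from_smiles("CCCCO", name="c")]
    registry = register(mols)
    hits = [ScreenHit(i, "aristolactam", ["aristolactam"], i + 1) for i in range(3)]
    rows = [{"canonical_smiles": mols[0].canonical_smiles, "ames_probability": "0.9"},
            {"canonical_smiles": mols[1].canonical_smiles, "ames_probability": "oops"},
            {"canonical_smiles": "CC(=O)O", "ames_probability": "0.5"}]
    path = tmp_path / "tox.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    out = ingest_toxicity_table(path, hits, registry)
    assert out.joined.shape[0] == 3                 # left join onto hits
    assert out.orphans == ["CC(=O)O"]
    vals = out.joined["ames_probability"].tolist()
    assert vals[0] == 0.9 and pd.isna(vals[1]) and pd.isna(vals[2])


def test_generated_toxicity_medians_recover_planted_parameters(tmp_path, scaffolds):
    spec = SyntheticSpec(seed=31, n_positives_per_category=50, n_near_miss=0,
                         n_unrelated=0)
    lib = generate_library(spec, scaffolds)
    zero_sd = {"ames_probability": {"aristolochic_acid": (0.9, 0.0),
                                    "aristolactam": (0.7, 0.0),
                                    "dioxoaporphine": (0.6, 0.0)}}
    tox = generate_toxicity(spec, lib, model=zero_sd)
    tox.write(tmp_path / "tox.csv", spec.seed)
    registry = register(lib.molecules)
    hits = screen_library(registry, scaffolds).hits
    out = ingest_toxicity_table(tmp_path / "tox.csv", hits, registry)
    medians = out.per_category[("ames_probability", "median")]
    assert medians["aristolochic_acid"] == pytest.approx(0.9)
    assert medians["aristolactam"] == pytest.approx(0.7)
    assert medians["dioxoaporphine"] == pytest.approx(0.6)
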