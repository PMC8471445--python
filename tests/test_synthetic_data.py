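import filecmp
import random

import pytest
from rdkit import Chem

from aaascreen.chem_io import register
from aaascreen.errors import InputError
from aaascreen.screening import classify, screen_library
from aaascreen.synthetic_data import (CORES, DECOY_CORES, EXEMPLARS,
                                      SyntheticSpec, decorate, delete_feature,
                                      generate_library, generate_sources,
                                      generate_toxicity, study_marginals,
                                      study_scale_spec, realize_marginals)


def test_spec_validation():
    with pytest.raises(InputError):
        SyntheticSpec(n_near_miss=-1)
    with pytest.raises(InputError):
        SyntheticSpec(occurrence_density=1.5)


def test_decorate_requesting_too_many_sites_is_an_error():
    with pytest.raises(InputError):
        decorate("c1ccccc1", random.Random(0), n_subs=7)


def test_decorated_positives_keep_their_scaffold(scaffolds):
    queries = {s.category: s.query for s in scaffolds}
    rng = random.Random(17)
    for cat, core in CORES.items():
        for _ in range(5):
            mol = decorate(core, rng, n_subs=2)
            assert mol.HasSubstructMatch(queries[cat])


def test_feature_deletion_removes_exactly_that_group():
    aa = Chem.MolFromSmiles(CORES["aristolochic_acid"])
    broken = delete_feature(aa, "nitro")
    assert not broken.HasSubstructMatch(Chem.MolFromSmarts("[NX3+](=O)[O-]"))
    assert broken.HasSubstructMatch(Chem.MolFromSmarts("[CX3](=O)[OX2H1]"))
    with pytest.raises(InputError):
        delete_feature(broken, "nitro")


def test_small_generated_set_classifies_into_planted_categories(scaffolds):
    lib = generate_library(SyntheticSpec(seed=1, n_positives_per_category=5,
                                         n_near_miss=0, n_unrelated=0), scaffolds)
    assert len(lib.molecules) == 15
    for mol, (name, planted) in zip(lib.molecules, lib.positives):
        category, _ = classify(mol, scaffolds)
        assert category == planted and mol.name == name


def test_near_miss_decoys_are_unclassified_with_known_deletion(scaffolds):
    lib = generate_library(SyntheticSpec(seed=2, n_positives_per_category=2,
                                         n_near_miss=10, n_unrelated=0), scaffolds)
    names = {m.name: m for m in lib.molecules}
    assert len(lib.truth["near_miss"]) == 10
    for name, info in lib.truth["near_miss"].items():
        category, _ = classify(names[name], scaffolds)
        assert category is None
        assert info["deleted"]


def test_unrelated_decoy_cores_never_match_a_scaffold(scaffolds):
    queries = [s.query for s in scaffolds]
    for smi in DECOY_CORES:
        mol = Chem.MolFromSmiles(smi)
        assert mol is not None, smi
        assert not any(mol.HasSubstructMatch(q) for q in queries), smi


def test_generation_is_deterministic(tmp_path, scaffolds):
    spec = SyntheticSpec(seed=5, n_positives_per_category=4, n_near_miss=4,
                         n_unrelated=4, n_species=10)
    for tag in ("a", "b"):
        lib = generate_library(spec, scaffolds)
        lib.write_smiles(tmp_path / f"{tag}.smi")
        src = generate_sources(spec, lib)
        src.write(tmp_path / f"{tag}_tax.csv", tmp_path / f"{tag}_occ.csv", spec.seed)
        generate_toxicity(spec, lib).write(tmp_path / f"{tag}_tox.csv", spec.seed)
    for stem in (".smi", "_tax.csv", "_occ.csv", "_tox.csv"):
        assert filecmp.cmp(tmp_path / f"a{stem}", tmp_path / f"b{stem}", shallow=False)


def test_density_one_fills_the_matrix(scaffolds):
    spec = SyntheticSpec(seed=3, n_positives_per_category=2, n_near_miss=0,
                         n_unrelated=0, n_species=5, occurrence_density=1.0)
    lib = generate_library(spec, scaffolds)
    src = generate_sources(spec, lib)
    assert src.truth["species_per_compound"] == [5] * 6


def test_toxicity_probabilities_respect_clipping(scaffolds):
    spec = SyntheticSpec(seed=4, n_positives_per_category=30, n_near_miss=0,
                         n_unrelated=0)
    lib = generate_library(spec, scaffolds)
    hot = {"ames_probability": {c: (0.99, 0.3) for c in
                                ("aristolochic_acid", "aristolactam", "dioxoaporphine")}}
    tox = generate_toxicity(spec, lib, model=hot)
    vals = tox.table["ames_probability"]
    assert vals.between(0.0, 1.0).all() and (vals == 1.0).any()


def test_toxicity_sample_means_near_planted_values(scaffolds):
    spec = SyntheticSpec(seed=6, n_positives_per_category=50, n_near_miss=0,
                         n_unrelated=0)
    lib = generate_library(spec, scaffolds)
    tox = generate_toxicity(spec, lib)
    got = tox.table.groupby("category")["ames_probability"].mean()
    for cat, planted in (("aristolochic_acid", 0.9), ("aristolactam", 0.7),
                         ("dioxoaporphine", 0.6)):
        se = 0.05 / (50 ** 0.5)
        assert abs(got[cat] - planted) < 3 * se + 0.01  # clipping skews slightly


def test_study_scale_conditions_shape():
    pm = study_marginals()
    assert sum(pm.row_counts) == sum(pm.col_counts) == 781
    assert len(pm.row_counts) == 238 and len(pm.col_counts) == 175
    assignment = realize_marginals(pm)
    assert len(set(assignment[0]) | set(assignment[1])) == 52
    spec = study_scale_spec(seed=0)
    assert spec.positives_for("aristolochic_acid") == 79
    assert spec.positives_for("aristolactam") == 125
    assert spec.positives_for("dioxoaporphine") == 34
    assert spec.n_tcm == 44 and spec.n_species == 175


def test_exemplars_are_injected_at_study_scale(scaffolds):
    spec = study_scale_spec(seed=9)
    lib = generate_library(spec, scaffolds)
    names = {m.name for m in lib.molecules}
    assert {"aristolochic acid I", "aristolochic acid II", "aristolactam I"} <= names
    registry = register(lib.molecules)
    result = screen_library(registry, scaffolds)
    assert result.counts == {"aristolochic_acid": 79, "aristolactam": 125,
                             "dioxoaporphine": 34, "total": 238}


def test_exemplar_structures_parse_and_annotate():
    for name, (smi, cat) in EXEMPLARS.items():
        assert Chem.MolFromSmiles(smi) is not None, name
        assert cat in (None, "aristolochic_acid", "aristolactam", "dioxoaporphine")
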