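"""Compound × species occurrence matrix and its headline analytics.

Every reported (compound, species, reference) triple becomes one
occurrence record; the binary incidence matrix has a 1 wherever at least
one record supports the pair, with per-cell reference provenance.  All the
headline numbers of the analysis are marginals of this matrix: species per
compound, compounds per species, strict "more than t" tallies, the ranking
of traditional-medicine species, and the set of species flagged for
containing specific hazard compounds.

Species names are resolved through the taxonomy table before entering the
matrix; unresolved names are quarantined to a side list, never silently
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_io import CompoundRegistry
from .errors import RelationalError
from .screening import ScreenHit
from .taxonomy import TaxonomyTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccurrenceRecord:
    compound_id: int  # registry index
    species: str      # raw species name as printed in the source
    reference: str

    def normalized(self) -> "OccurrenceRecord":
        return OccurrenceRecord(self.compound_id, " ".join(self.species.split()),
                                self.reference.strip())


def read_occurrences(path: str | Path, registry: CompoundRegistry) -> list[OccurrenceRecord]:
    """Read an occurrence CSV (compound_key, raw_species_name, reference).

    ``compound_key`` is matched against canonical SMILES first, then
    compound name.  Unknown keys are fatal: an occurrence must refer to a
    registered structure.
    """
    df = pd.read_csv(path, dtype=str, comment="#").fillna("")
    by_name = {m.name: i for i, m in enumerate(registry) if m.name}
    records = []
    for _, row in df.iterrows():
        key = row["compound_key"]
        cid = registry.index_of(key)
        if cid is None:
            cid = by_name.get(key)
        if cid is None:
            raise RelationalError(f"occurrence references unknown compound {key!r}")
        records.append(OccurrenceRecord(cid, row["raw_species_name"], row["reference"]))
    return records


@dataclass
class IncidenceMatrix:
    """Binary presence matrix over screened compounds × accepted species."""

    data: pd.DataFrame                       # index: compound_id, columns: accepted species
    categories: dict[int, str]               # compound_id -> category
    aaa_numbers: dict[int, int]              # compound_id -> serial number
    provenance: dict[tuple[int, str], set[str]] = field(default_factory=dict)
    unresolved: list[OccurrenceRecord] = field(default_factory=list)
    n_records: int = 0

    @property
    def n_cells(self) -> int:
        return int(self.data.values.sum())

    def write_triplets_csv(self, path: str | Path, registry: CompoundRegistry) -> None:
        rows = []
        for cid in self.data.index:
            for sp in self.data.columns:
                if self.data.at[cid, sp]:
                    rows.append({
                        "aaa_number": self.aaa_numbers[cid],
                        "canonical_smiles": registry[cid].canonical_smiles,
                        "category": self.categories[cid],
                        "species": sp,
                        "references": ";".join(sorted(self.provenance.get((cid, sp), set()))),
                    })
        pd.DataFrame(rows).to_csv(path, index=False)


def build_matrix(records: list[OccurrenceRecord], hits: list[ScreenHit],
                 taxonomy: TaxonomyTable) -> IncidenceMatrix:
    """Assemble the incidence matrix from occurrence records.

    Duplicate triples collapse idempotently (provenance is a set union).
    A record referencing a compound that is not a screen hit is an error.
    """
    hit_ids = {h.compound_id for h in hits}
    categories = {h.compound_id: h.category for h in hits}
    numbers = {h.compound_id: h.aaa_number for h in hits}
    cells: dict[tuple[int, str], set[str]] = {}
    unresolved: list[OccurrenceRecord] = []
    seen_triples: set[tuple[int, str, str]] = set()
    n_records = 0
    for rec in records:
        rec = rec.normalized()
        if rec.compound_id not in hit_ids:
            raise RelationalError(
                f"occurrence record references non-hit compound id {rec.compound_id}"
            )
        triple = (rec.compound_id, rec.species, rec.reference)
        if triple in seen_triples:
            continue
        seen_triples.add(triple)
        n_records += 1
        res = taxonomy.resolve(rec.species)
        if not res.matched:
            unresolved.append(rec)
            continue
        cells.setdefault((rec.compound_id, res.accepted.name), set()).add(rec.reference)

    species = sorted({sp for _, sp in cells})
    compound_ids = sorted(hit_ids, key=lambda cid: numbers[cid])
    data = pd.DataFrame(np.zeros((len(compound_ids), len(species)), dtype=np.int8),
                        index=compound_ids, columns=species)
    for (cid, sp), refs in cells.items():
        data.at[cid, sp] = 1
    if unresolved:
        logger.warning("%d occurrence records with unresolved species quarantined",
                       len(unresolved))
    return IncidenceMatrix(data, categories, numbers, cells, unresolved, n_records)


def species_per_compound(m: IncidenceMatrix) -> pd.Series:
    """Row marginals: in how many accepted species each compound occurs."""
    return m.data.sum(axis=1)


def threshold_tally(counts: pd.Series, t: int) -> int:
    """Number of entries strictly greater than ``t``."""
    return int((counts > t).sum())


def compounds_per_species(m: IncidenceMatrix) -> pd.Series:
    """Column marginals ranked descending, ties broken alphabetically."""
    counts = m.data.sum(axis=0)
    return counts.iloc[np.lexsort((counts.index, -counts.values))]


def hazard_flags(m: IncidenceMatrix, flag_compounds: list[int]) -> set[str]:
    """Species containing any of the flagged compounds (union over rows)."""
    unknown = [cid for cid in flag_compounds if cid not in m.data.index]
    if unknown:
        raise RelationalError(f"flagged compound ids not in matrix: {unknown}")
    mask = m.data.loc[flag_compounds].any(axis=0)
    return set(m.data.columns[mask])


def tcm_ranking(m: IncidenceMatrix, taxonomy: TaxonomyTable) -> list[tuple[str, str, int]]:
    """Traditional-medicine species ranked by number of analogues they contain.

    Returns ``(species, tcm_name, count)`` tuples sorted by descending
    count, ties alphabetical by species.  Species present in the taxonomy
    with a TCM name but absent from the matrix are not listed.
    """
    ranked = compounds_per_species(m)
    out = []
    for sp, count in ranked.items():
        rec = taxonomy.accepted.get(sp)
        if rec is not None and rec.tcm_name:
            out.append((sp, rec.tcm_name, int(count)))
    return out


@dataclass
class ToxicitySummary:
    joined: pd.DataFrame
    per_category: pd.DataFrame  # index (category, column); min/median/max
    orphans: list[str]


def ingest_toxicity_table(path: str | Path, hits: list[ScreenHit],
                          registry: CompoundRegistry,
                          numeric_columns: list[str] | None = None) -> ToxicitySummary:
    """Join an externally produced per-compound toxicity table onto the hits.

    The table is keyed by ``canonical_smiles`` or ``aaa_number``.  Values
    are ingested, never computed.  Non-numeric cells are logged and set to
    null; rows for unknown compounds are logged as orphans and excluded.
    """
    df = pd.read_csv(path, dtype=str, comment="#").fillna("")
    if "canonical_smiles" in df.columns:
        keyed = {row["canonical_smiles"]: row for _, row in df.iterrows()}
        key_of = lambda h: registry[h.compound_id].canonical_smiles
    elif "aaa_number" in df.columns:
        keyed = {row["aaa_number"]: row for _, row in df.iterrows()}
        key_of = lambda h: str(h.aaa_number)
    else:
        raise RelationalError("toxicity table needs a canonical_smiles or aaa_number column")
    if numeric_columns is None:
        numeric_columns = [c for c in df.columns
                           if c not in ("canonical_smiles", "aaa_number", "name", "category")]
    hit_keys = {key_of(h) for h in hits}
    orphans = [k for k in keyed if k not in hit_keys]
    for k in orphans:
        logger.warning("toxicity row for unknown compound %r excluded", k)

    rows = []
    for h in hits:
        row = keyed.get(key_of(h))
        entry = {"aaa_number": h.aaa_number, "category": h.category,
                 "canonical_smiles": registry[h.compound_id].canonical_smiles}
        for col in numeric_columns:
            val = None
            if row is not None and row.get(col, "") != "":
                try:
                    val = float(row[col])
                except ValueError:
                    logger.warning("non-numeric toxicity cell %s for AAAs No. %d",
                                   col, h.aaa_number)
            entry[col] = val
        rows.append(entry)
    joined = pd.DataFrame(rows)
    stats = joined.groupby("category")[numeric_columns].agg(["min", "median", "max"])
    return ToxicitySummary(joined, stats, orphans)
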