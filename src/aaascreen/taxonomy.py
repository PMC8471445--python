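"""Resolution of raw species names to accepted names with lineage.

Occurrence records quote species names as printed in the primary
literature; over time many of those names have become synonyms.  The
resolver works against a static taxonomy table (one row per scientific
name, accepted or synonym, in the style of a Catalogue of Life export)
shipped or generated alongside the occurrence data, so results are
reproducible against a fixed snapshot rather than a moving database.

Name matching is exact first, then "normalized": whitespace collapsed,
genus and epithet case-folded, and author citations stripped using a
first-two-Latin-tokens heuristic (the hybrid sign ``×`` is preserved, and
``var.``/``subsp.``/``f.`` rank markers keep their epithet).  Anything else
is reported unresolved — never silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import TaxonomyError

REQUIRED_COLUMNS = ["name", "status", "accepted_name", "genus", "family",
                    "class", "common_names", "tcm_name"]

_RANK_MARKERS = {"var.", "subsp.", "ssp.", "f."}


@dataclass(frozen=True)
class TaxonRecord:
    name: str
    status: str  # "accepted" | "synonym"
    accepted_name: str
    genus: str
    family: str
    class_name: str
    common_names: tuple[str, ...] = ()
    tcm_name: str = ""


@dataclass(frozen=True)
class ResolutionResult:
    raw_name: str
    matched: bool
    accepted: TaxonRecord | None
    method: str  # "exact" | "normalized" | "unresolved"


def normalize_name(raw: str) -> str:
    """Canonical lower-case binomial key for fuzzy-free matching."""
    tokens = raw.strip().split()
    if not tokens:
        return ""
    lead = []
    if tokens[0] in ("×", "x") and len(tokens) > 1:
        lead, tokens = ["×"], tokens[1:]
    keep = tokens[:2]
    if len(tokens) >= 4 and tokens[2] in _RANK_MARKERS:
        keep = tokens[:4]
    return " ".join(lead + [t.lower() for t in keep])


class TaxonomyTable:
    """Validated, chain-flattened taxonomy with exact and normalized indices."""

    def __init__(self, records: list[TaxonRecord]):
        self.records = records
        self.accepted: dict[str, TaxonRecord] = {
            r.name: r for r in records if r.status == "accepted"
        }
        self._exact: dict[str, TaxonRecord] = {}
        self._normalized: dict[str, TaxonRecord] = {}
        for r in records:
            target = self.accepted[r.accepted_name]
            self._exact.setdefault(r.name, target)
            self._normalized.setdefault(normalize_name(r.name), target)

    def __len__(self) -> int:
        return len(self.records)

    def resolve(self, raw: str) -> ResolutionResult:
        return resolve_name(raw, self)

    def tcm_species(self) -> list[TaxonRecord]:
        return [r for r in self.accepted.values() if r.tcm_name]


def _flatten(name: str, status: dict[str, str], target: dict[str, str]) -> str:
    """Follow a synonym chain to its accepted endpoint; fatal on cycles."""
    seen = []
    cur = name
    while True:
        if cur in seen:
            raise TaxonomyError(f"cyclic synonym chain: {' -> '.join(seen + [cur])}")
        seen.append(cur)
        if status.get(cur) == "accepted":
            return cur
        if cur not in target:
            raise TaxonomyError(f"dangling synonym target: {' -> '.join(seen)}")
        cur = target[cur]


def load_taxonomy(path: str | Path) -> TaxonomyTable:
    """Load and validate a taxonomy CSV.

    Synonym chains of any depth are flattened so that every record's
    ``accepted_name`` points directly at an accepted row; dangling or
    cyclic chains are fatal, listing the offenders.
    """
    df = pd.read_csv(path, dtype=str, comment="#").fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TaxonomyError(f"taxonomy table lacks columns: {missing}")
    status = dict(zip(df["name"], df["status"]))
    target = dict(zip(df["name"], df["accepted_name"]))
    errors: list[str] = []
    resolved: dict[str, str] = {}
    for name in df["name"]:
        try:
            resolved[name] = _flatten(name, status, target)
        except TaxonomyError as e:
            errors.append(str(e))
    if errors:
        raise TaxonomyError("invalid taxonomy table: " + "; ".join(errors))

    accepted_rows = df[df["status"] == "accepted"].set_index("name")
    records = []
    for _, row in df.iterrows():
        acc_name = resolved[row["name"]]
        acc = accepted_rows.loc[acc_name]
        if row["status"] == "accepted" and row["accepted_name"] not in ("", row["name"]):
            raise TaxonomyError(f"accepted record {row['name']!r} points elsewhere")
        records.append(TaxonRecord(
            name=row["name"],
            status=row["status"],
            accepted_name=acc_name,
            genus=acc["genus"],
            family=acc["family"],
            class_name=acc["class"],
            common_names=tuple(s for s in str(row["common_names"]).split(";") if s),
            tcm_name=acc["tcm_name"],
        ))
    return TaxonomyTable(records)


def resolve_name(raw: str, table: TaxonomyTable) -> ResolutionResult:
    """Resolve one raw species name: exact match, then normalized, else
    unresolved.  Synonyms map to their accepted record.  Idempotent on
    accepted names."""
    hit = table._exact.get(raw.strip())
    if hit is not None:
        return ResolutionResult(raw, True, hit, "exact")
    hit = table._normalized.get(normalize_name(raw))
    if hit is not None:
        return ResolutionResult(raw, True, hit, "normalized")
    return ResolutionResult(raw, False, None, "unresolved")


def rollup(species: list[TaxonRecord]) -> dict[str, list[tuple[str, int]]]:
    """Counts of accepted species grouped by genus, family and class,
    sorted descending (ties alphabetical)."""
    for r in species:
        if r.status != "accepted":
            raise TaxonomyError(f"rollup expects accepted records, got {r.name!r}")
    out = {}
    for level, key in (("genus", lambda r: r.genus),
                       ("family", lambda r: r.family),
                       ("class", lambda r: r.class_name)):
        counts = Counter(key(r) for r in species)
        out[level] = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return out
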