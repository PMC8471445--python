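"""End-to-end orchestration: read -> screen -> properties -> resolve ->
matrix -> tallies -> exports.

``run_pipeline`` sequences the whole analysis from a validated
:class:`RunConfig` and writes a run report containing every headline count
(total hits, per-category counts, species/family/TCM counts, threshold
tallies, flagged-species count, record count) plus a log of skipped and
unresolved items.  ``export_chart_data`` writes one tidy CSV per figure
analogue (property scatter, family rollup, incidence heat data, toxicity
scatters) instead of interactive charts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import relational, taxonomy as taxonomy_mod
from .chem_io import largest_fragment, read_structures, register
from .errors import AAAScreenError, InputError
from .properties import property_summary, property_vector, write_properties_csv
from .scaffolds import load_scaffolds
from .screening import (diagnose_exclusion, nearest_scaffold, screen_library,
                        write_exclusions_csv)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    library: str
    occurrences: str | None = None
    taxonomy: str | None = None
    toxicity: str | None = None
    scaffolds: str | None = None          # None -> shipped fixtures
    outdir: str = "aaascreen_out"
    smiles_column: str = "smiles"
    thresholds: list[int] = field(default_factory=lambda: [2, 10])
    flag_compounds: list[str] = field(default_factory=list)
    diagnose_exclusions: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def validate(self) -> None:
        if not Path(self.library).exists():
            raise InputError(f"library path does not exist: {self.library}")
        for label in ("occurrences", "taxonomy", "toxicity", "scaffolds"):
            p = getattr(self, label)
            if p is not None and not Path(p).exists():
                raise InputError(f"{label} path does not exist: {p}")
        if (self.occurrences is None) != (self.taxonomy is None):
            raise InputError("occurrences and taxonomy must be supplied together")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen; returns the report dict (also written to
    ``outdir/report.json``).  Stage errors propagate with the stage name."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)

    report: dict = {"stages": [], "counts": {}, "skipped": {}}

    def stage(name):
        report["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("read")
        mols, n_skip = read_structures(config.library, smiles_column=config.smiles_column)
        registry = register([largest_fragment(m) for m in mols])
        report["skipped"]["unparsable_records"] = n_skip
        report["counts"]["library_size"] = len(registry)

        stage("screen")
        scaffolds = load_scaffolds(config.scaffolds)
        screen = screen_library(registry, scaffolds)
        screen.write_csv(outdir / "hits.csv", registry)
        report["counts"]["total_hits"] = screen.counts["total"]
        for s in scaffolds:
            report["counts"][f"hits_{s.category}"] = screen.counts[s.category]
        blocks = {}
        pos = 1
        for s in scaffolds:
            n = screen.counts[s.category]
            blocks[s.category] = [pos, pos + n - 1] if n else None
            pos += n
        report["aaa_number_blocks"] = blocks

        if config.diagnose_exclusions and screen.non_hit_ids:
            stage("diagnose")
            reports = []
            for cid in screen.non_hit_ids:
                mol = registry[cid]
                nearest = nearest_scaffold(mol, scaffolds)
                try:
                    reports.append(diagnose_exclusion(mol, nearest, compound_id=cid))
                except AAAScreenError:  # pragma: no cover - nearest never matches
                    continue
            write_exclusions_csv(reports, registry, outdir / "exclusions.csv")
            report["counts"]["exclusions"] = len(reports)

        stage("properties")
        vec_rows = [(h.aaa_number, registry[h.compound_id].canonical_smiles,
                     property_vector(registry[h.compound_id])) for h in screen.hits]
        write_properties_csv(outdir / "properties.csv", vec_rows)
        summary = property_summary([v for _, _, v in vec_rows])
        report["properties"] = dataclasses.asdict(summary)

        matrix = None
        tax = None
        if config.occurrences:
            stage("resolve")
            tax = taxonomy_mod.load_taxonomy(config.taxonomy)
            records = relational.read_occurrences(config.occurrences, registry)

            stage("matrix")
            matrix = relational.build_matrix(records, screen.hits, tax)
            matrix.write_triplets_csv(outdir / "incidence.csv", registry)
            report["counts"]["relational_records"] = matrix.n_records
            report["counts"]["unresolved_species_records"] = len(matrix.unresolved)
            report["counts"]["species"] = int(matrix.data.shape[1])
            present = [tax.accepted[sp] for sp in matrix.data.columns]
            roll = taxonomy_mod.rollup(present)
            report["counts"]["families"] = len(roll["family"])
            report["rollup_family"] = roll["family"]

            stage("tallies")
            spc = relational.species_per_compound(matrix)
            report["tallies_species_per_compound"] = {
                str(t): relational.threshold_tally(spc, t) for t in config.thresholds}
            cps = relational.compounds_per_species(matrix)
            report["counts"]["species_with_gt10_analogues"] = relational.threshold_tally(cps, 10)
            report["top_species"] = [cps.index[0], int(cps.iloc[0])] if len(cps) else None
            ranking = relational.tcm_ranking(matrix, tax)
            report["counts"]["tcm_species"] = len(ranking)
            report["tcm_top5"] = ranking[:5]
            pd.DataFrame(ranking, columns=["species", "tcm_name", "n_analogues"]).to_csv(
                outdir / "tcm_ranking.csv", index=False)
            if config.flag_compounds:
                by_name = {registry[h.compound_id].name: h.compound_id for h in screen.hits}
                by_smiles = {registry[h.compound_id].canonical_smiles: h.compound_id
                             for h in screen.hits}
                flag_ids = []
                for key in config.flag_compounds:
                    cid = by_name.get(key, by_smiles.get(key))
                    if cid is None:
                        raise relational.RelationalError(f"flagged compound not a hit: {key!r}")
                    flag_ids.append(cid)
                flagged = relational.hazard_flags(matrix, flag_ids)
                report["counts"]["flagged_species"] = len(flagged)

        toxicity = None
        if config.toxicity:
            stage("toxicity")
            toxicity = relational.ingest_toxicity_table(config.toxicity, screen.hits, registry)
            report["counts"]["toxicity_rows"] = int(toxicity.joined.shape[0])
            report["skipped"]["toxicity_orphans"] = len(toxicity.orphans)
        else:
            report["skipped"]["toxicity"] = "no toxicity table supplied"

        stage("export")
        export_chart_data(outdir, vec_rows, matrix, toxicity)
    except AAAScreenError as e:
        e.args = (f"[stage {report['stages'][-1]}] {e}",)
        raise

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    return report


def export_chart_data(outdir: str | Path, vec_rows, matrix=None, toxicity=None) -> None:
    """Write tidy per-figure CSVs: property scatter, family rollup is part of
    the report, incidence heat triplets, and toxicity scatter tables."""
    outdir = Path(outdir)
    pd.DataFrame(
        [{"aaa_number": n, "clogp": v.clogp, "tpsa": v.tpsa, "mw": v.mw}
         for n, _smi, v in vec_rows]
    ).to_csv(outdir / "chart_property_scatter.csv", index=False)
    if matrix is not None:
        rows = []
        for cid in matrix.data.index:
            for j, sp in enumerate(matrix.data.columns):
                if matrix.data.at[cid, sp]:
                    rows.append({"aaa_number": matrix.aaa_numbers[cid],
                                 "species": sp, "value": 1})
        pd.DataFrame(rows).to_csv(outdir / "chart_incidence_heat.csv", index=False)
    if toxicity is not None:
        toxicity.joined.to_csv(outdir / "chart_toxicity_scatter.csv", index=False)
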