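"""Orchestration: build -> search -> quantify -> compare -> taxonomy.

Each stage is an ordinary function taking a :class:`RunConfig`; the CLI
subcommands are thin wrappers.  Stages persist their outputs under the
config's output directory so they compose: running them one at a time
yields byte-identical tables to a single ``run_all``.  A run manifest
records the config hash, seed, package version and every output path.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import COMPARISON_COLUMNS, compare_groups
from .config import APASE_FAMILIES, RunConfig
from .io import PhoscanError, read_alignment, read_cds_set, read_fasta, read_table, write_table
from .profiles import ProfileHMM, build_profile
from .quantify import quantify_sites
from .search import HitTable, ScoringProfile, hit_table_rows, search_site
from .taxonomy import (
    aggregate_ranks,
    assign_hits,
    assignment_rows,
    mean_identity,
    write_krona_text,
)

logger = logging.getLogger("phoscan")

HIT_COLUMNS = ["site_id", "family", "cds_id", "bit_score", "viterbi_bits", "accepted"]


class StageError(PhoscanError):
    """A pipeline stage failed; the message names the stage and subject."""


@dataclass
class RunResult:
    output_dir: Path
    profile_paths: dict[str, Path] = field(default_factory=dict)
    hit_table_paths: dict[str, Path] = field(default_factory=dict)
    abundance_path: Path | None = None
    comparison_path: Path | None = None
    assignment_path: Path | None = None
    krona_path: Path | None = None
    manifest_path: Path | None = None


def _out(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# stages

def build_profiles_stage(config: RunConfig) -> dict[str, ProfileHMM]:
    """Build one profile HMM per family from its reference alignment."""
    config.validate()
    out = _out(config) / "profiles"
    profiles: dict[str, ProfileHMM] = {}
    for fam in sorted(config.families):
        fc = config.families[fam]
        try:
            alignment = read_alignment(fc.reference_path)
            prof = build_profile(
                alignment,
                occupancy_threshold=config.occupancy_threshold,
                pseudocount=config.pseudocount,
                family_name=fam,
                reference_statistic=config.reference_statistic,
            )
        except PhoscanError as exc:
            raise StageError(f"build-profiles failed for family {fam}: {exc}") from exc
        prof.to_json(out / f"{fam}.json")
        profiles[fam] = prof
        logger.info("built profile %s: L=%d ref_length=%d",
                    fam, prof.L, prof.reference_length)
    return profiles


def load_profiles(config: RunConfig) -> dict[str, ProfileHMM]:
    out = _out(config) / "profiles"
    profiles = {}
    for fam in sorted(config.families):
        path = out / f"{fam}.json"
        if not path.exists():
            raise StageError(f"missing profile for family {fam}; run build-profiles")
        profiles[fam] = ProfileHMM.from_json(path)
    return profiles


def search_stage(
    config: RunConfig, profiles: dict[str, ProfileHMM]
) -> list[HitTable]:
    """Screen every site's pooled CDS set against every family profile."""
    out = _out(config) / "hits"
    sps = [ScoringProfile(profiles[fam]) for fam in sorted(profiles)]
    tables: list[HitTable] = []
    for site_id in sorted(config.sites):
        site = config.sites[site_id]
        t0 = time.perf_counter()
        try:
            cds = read_cds_set(site.cds_paths)
            table = search_site(
                sps, cds, config.threshold_bits, site_id, config.alignment_mode
            )
        except PhoscanError as exc:
            raise StageError(f"search failed at site {site_id}: {exc}") from exc
        write_table(hit_table_rows(table), out / f"{site_id}.tsv",
                    fieldnames=HIT_COLUMNS)
        tables.append(table)
        logger.info(
            "searched site %s: %d CDS, %d accepted hits (%.1fs)",
            site_id, len(cds), len(table.hits), time.perf_counter() - t0,
        )
    return tables


def load_hit_tables(config: RunConfig) -> list[HitTable]:
    out = _out(config) / "hits"
    tables = []
    for site_id in sorted(config.sites):
        path = out / f"{site_id}.tsv"
        if not path.exists():
            raise StageError(f"missing hit table for site {site_id}; run search")
        frame = read_table(path)
        table = HitTable(site_id=site_id)
        for fam in config.families:
            table.counts[fam] = 0
        from .search import Hit  # local import to avoid cycle at module load

        for row in frame.itertuples(index=False):
            table.counts[row.family] = table.counts.get(row.family, 0) + 1
            table.hits.append(
                Hit(row.site_id, row.family, row.cds_id,
                    float(row.bit_score), float(row.viterbi_bits), bool(row.accepted))
            )
        tables.append(table)
    return tables


def quantify_stage(
    config: RunConfig,
    hit_tables: list[HitTable],
    profiles: dict[str, ProfileHMM],
) -> pd.DataFrame:
    try:
        abundance = quantify_sites(hit_tables, profiles, config)
    except PhoscanError as exc:
        raise StageError(f"quantify failed: {exc}") from exc
    write_table(abundance, _out(config) / "abundance.tsv")
    return abundance


def compare_stage(config: RunConfig, abundance: pd.DataFrame) -> pd.DataFrame:
    try:
        comparisons = compare_groups(abundance, config)
    except PhoscanError as exc:
        raise StageError(f"compare failed: {exc}") from exc
    write_table(comparisons, _out(config) / "comparisons.tsv",
                fieldnames=COMPARISON_COLUMNS)
    for row in comparisons.itertuples(index=False):
        logger.info(
            "family %s: mean low=%.4f high=%.4f t=%.3f p=%.4g%s",
            row.family, row.mean_low, row.mean_high, row.t, row.p,
            " *" if row.significant else "",
        )
    return comparisons


def taxonomy_stage(
    config: RunConfig, hit_tables: list[HitTable]
) -> tuple[pd.DataFrame, Path | None]:
    """Best-hit assignment of APase hits against the curated reference DB.

    At most ``max_taxonomy_hits_per_site`` hits per (site, family) are
    aligned (deterministically the first in CDS order) to keep the
    all-vs-all alignment affordable; the cap is a diversity-summary
    subsample, not a filter on abundance.
    """
    out = _out(config)
    if config.refdb_path is None:
        logger.info("no reference DB configured; skipping taxonomy")
        return pd.DataFrame(), None
    try:
        refdb = read_fasta(config.refdb_path)
        queries: list[tuple[str, str, str]] = []
        apase = [f for f in APASE_FAMILIES if f in config.families]
        for table in hit_tables:
            site = config.sites[table.site_id]
            cds_by_id = {
                rec.id: rec.sequence for rec in read_cds_set(site.cds_paths)
            }
            per_family: dict[str, int] = {}
            for hit in table.hits:
                if hit.family_name not in apase:
                    continue
                k = per_family.get(hit.family_name, 0)
                if k >= config.max_taxonomy_hits_per_site:
                    continue
                per_family[hit.family_name] = k + 1
                queries.append(
                    (hit.cds_id, hit.family_name, cds_by_id[hit.cds_id])
                )
        assignments, unassigned = assign_hits(
            queries, refdb, config.min_align_score
        )
    except PhoscanError as exc:
        raise StageError(f"taxonomy failed: {exc}") from exc
    frame = pd.DataFrame(
        assignment_rows(assignments),
        columns=["cds_id", "family", "best_ref_id", "percent_identity",
                 "bit_score", "lineage"],
    )
    write_table(frame, out / "assignments.tsv",
                fieldnames=["cds_id", "family", "best_ref_id",
                            "percent_identity", "bit_score", "lineage"])
    krona_path = None
    if assignments:
        hierarchy = aggregate_ranks(assignments)
        krona_path = out / "krona.txt"
        write_krona_text(hierarchy, krona_path)
        logger.info(
            "assigned %d/%d hits; mean identity %.1f%%",
            len(assignments), len(assignments) + len(unassigned),
            mean_identity(assignments),
        )
    return frame, krona_path


# ---------------------------------------------------------------------------
# the whole run

def run_all(config: RunConfig) -> RunResult:
    """Execute every stage and write the run manifest."""
    config.validate()
    out = _out(config)
    result = RunResult(output_dir=out)
    profiles = build_profiles_stage(config)
    result.profile_paths = {f: out / "profiles" / f"{f}.json" for f in profiles}
    tables = search_stage(config, profiles)
    result.hit_table_paths = {
        t.site_id: out / "hits" / f"{t.site_id}.tsv" for t in tables
    }
    abundance = quantify_stage(config, tables, profiles)
    result.abundance_path = out / "abundance.tsv"
    compare_stage(config, abundance)
    result.comparison_path = out / "comparisons.tsv"
    _, krona = taxonomy_stage(config, tables)
    result.assignment_path = out / "assignments.tsv"
    result.krona_path = krona
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "phoscan_version": __version__,
        "outputs": {
            "profiles": sorted(str(p) for p in result.profile_paths.values()),
            "hit_tables": sorted(str(p) for p in result.hit_table_paths.values()),
            "abundance": str(result.abundance_path),
            "comparisons": str(result.comparison_path),
            "assignments": str(result.assignment_path),
            "krona": str(krona) if krona else None,
        },
    }
    result.manifest_path = out / "manifest.json"
    with open(result.manifest_path, "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for name, path in (
        ("abundance", result.abundance_path),
        ("comparisons", result.comparison_path),
    ):
        if not Path(path).exists() or Path(path).stat().st_size == 0:
            raise StageError(f"run_all produced an empty {name} table")
    return result
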