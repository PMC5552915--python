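"""Normalized abundances, genome equivalents, and per-genome gene frequencies.

Raw hit counts are not comparable across gene families because a longer
protein sheds more read-derived CDS fragments.  Each family's count is
therefore rescaled by the RecA length ratio,

    normalized = raw * L_RecA / L_family,

so every family is expressed in RecA-sized units.  The mean normalized
count over the five single-copy housekeeping families (RecA, RpoB,
AtpB, GyrB, SucD) gives the site's *average genome equivalent* G — an
estimate of how many genomes the metagenome sampled.  Dividing a target
family's normalized count by G (and an assumed per-genome copy number,
one by default) yields the gene frequency: the fraction of bacteria at
the site carrying that gene, reported as a percentage.

``census_genomes`` is the complementary whole-genome mode: given
complete genomes it records presence/absence per alkaline-phosphatase
family and the per-taxon fraction of genomes with at least one APase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ANCHOR_FAMILY, RunConfig
from .io import PhoscanError, ProteinRecord
from .profiles import ProfileHMM
from .search import HitTable, ScoringProfile, search_site

logger = logging.getLogger("phoscan")


class QuantifyError(PhoscanError):
    pass


def normalize_count(
    n: float, L_f: int, L_recA: int, direction: str = "divide_by_ratio"
) -> float:
    """Rescale a raw hit count by the family/RecA length ratio.

    The default direction divides by ``L_f / L_recA`` (i.e. multiplies by
    ``L_recA / L_f``): fragment-derived hit counts grow with protein
    length, so longer families are corrected down.  The alternative
    direction multiplies by the ratio instead.
    """
    if L_f <= 0 or L_recA <= 0:
        raise QuantifyError("reference lengths must be >= 1")
    if n < 0:
        raise QuantifyError("raw count must be non-negative")
    ratio = L_f / L_recA
    if direction == "divide_by_ratio":
        return n / ratio
    if direction == "multiply_by_ratio":
        return n * ratio
    raise QuantifyError(f"unknown normalization direction {direction!r}")


def genome_equivalents(
    housekeeping_normalized: dict[str, float],
    families: tuple[str, ...] = ("RecA", "RpoB", "AtpB", "GyrB", "SucD"),
) -> float:
    """Mean normalized count over the single-copy housekeeping families."""
    for fam in families:
        if fam not in housekeeping_normalized:
            raise QuantifyError(f"housekeeping family missing: {fam}")
        if housekeeping_normalized[fam] < 0:
            raise QuantifyError(f"negative normalized count for {fam}")
    g = float(np.mean([housekeeping_normalized[f] for f in families]))
    if g == 0.0:
        logger.warning(
            "all housekeeping counts are zero; genome equivalents undefined"
        )
    return g


def gene_frequency(
    normalized: float, G: float, copy_number: float = 1.0
) -> tuple[float, float]:
    """Fraction (and percent) of genomes carrying the gene.

    Frequencies above 1 are legitimate output (they diagnose multi-copy
    genes or a threshold problem) and are flagged downstream, never
    clamped.
    """
    if G <= 0:
        raise QuantifyError("gene frequency undefined: genome equivalents <= 0")
    if copy_number < 1:
        raise QuantifyError("copy number must be >= 1")
    f = normalized / (G * copy_number)
    return f, 100.0 * f


#: column order of the abundance table TSV
ABUNDANCE_COLUMNS = [
    "site_id", "group", "family", "role", "raw_count", "reference_length",
    "normalized_count", "genome_equivalents", "frequency", "percent", "flag",
]


def quantify_sites(
    hit_tables: list[HitTable],
    profiles: dict[str, ProfileHMM],
    config: RunConfig,
) -> pd.DataFrame:
    """Full abundance table over all sites and families.

    One row per (site, family) with raw count, normalized count, the
    site's genome equivalents and — for target families — the gene
    frequency and percentage (``flag`` marks frequencies above 100% and
    sites with undefined G).
    """
    if ANCHOR_FAMILY not in profiles:
        raise QuantifyError(f"profiles must include the anchor family {ANCHOR_FAMILY}")
    L_recA = profiles[ANCHOR_FAMILY].reference_length
    rows = []
    for table in hit_tables:
        site = config.sites.get(table.site_id)
        group = site.group if site is not None else ""
        normalized = {}
        for fam, prof in profiles.items():
            n = table.n(fam)
            normalized[fam] = normalize_count(
                n, prof.reference_length, L_recA, config.normalization_direction
            )
        hk = {f: normalized[f] for f in config.housekeeping}
        G = genome_equivalents(hk, config.housekeeping)
        for fam, prof in profiles.items():
            role = config.families[fam].role if fam in config.families else "target"
            freq = percent = np.nan
            flag = ""
            if role == "target":
                if G > 0:
                    c = config.families[fam].copy_number if fam in config.families else 1.0
                    freq, percent = gene_frequency(normalized[fam], G, c)
                    if freq > 1.0:
                        flag = "frequency>100%"
                else:
                    flag = "undefined:G=0"
            rows.append(
                {
                    "site_id": table.site_id,
                    "group": group,
                    "family": fam,
                    "role": role,
                    "raw_count": table.n(fam),
                    "reference_length": prof.reference_length,
                    "normalized_count": normalized[fam],
                    "genome_equivalents": G,
                    "frequency": freq,
                    "percent": percent,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


# ---------------------------------------------------------------------------
# genome census

@dataclass
class CensusResult:
    """Per-genome APase presence and per-taxon 'at least one APase' fractions."""

    presence: pd.DataFrame  # genome_id, taxon, one bool column per family, any_apase
    by_taxon: pd.DataFrame  # taxon, n_with_apase, n_total, fraction


def census_genomes(
    genomes: dict[str, tuple[list[ProteinRecord], str]],
    apase_profiles: dict[str, ProfileHMM],
    threshold: float,
    mode: str = "local",
) -> CensusResult:
    """Scan whole genomes for alkaline-phosphatase families.

    ``genomes`` maps genome id to (protein records, taxon label).  A
    genome counts as an APase carrier when at least one of the supplied
    families (typically PhoX, PhoD, PhoA) accepts at least one of its
    proteins; carrying several families still counts once.
    """
    if not genomes:
        raise QuantifyError("census needs at least one genome")
    sps = {f: ScoringProfile(p) for f, p in apase_profiles.items()}
    rows = []
    for gid, (records, taxon) in genomes.items():
        table = search_site(list(sps.values()), records, threshold, gid, mode)
        row = {"genome_id": gid, "taxon": taxon}
        for fam in apase_profiles:
            row[fam] = table.n(fam) > 0
        row["any_apase"] = any(row[f] for f in apase_profiles)
        rows.append(row)
    presence = pd.DataFrame(rows)
    grouped = presence.groupby("taxon", sort=True)["any_apase"]
    by_taxon = pd.DataFrame(
        {
            "taxon": grouped.sum().index,
            "n_with_apase": grouped.sum().astype(int).values,
            "n_total": grouped.count().astype(int).values,
        }
    )
    by_taxon["fraction"] = by_taxon["n_with_apase"] / by_taxon["n_total"]
    return CensusResult(presence=presence, by_taxon=by_taxon)
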