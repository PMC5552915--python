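"""Synthetic communities, CDS sets and reference databases with known truth.

Every pipeline stage is exercised on data generated here, so the whole
analysis is testable without any external downloads.  The generator
emulates the statistical structure of an eight-site, two-pH-group soil
survey:

* a protein *family* is a random consensus plus ``n_refs`` reference
  sequences diverged from it by i.i.d. substitutions (no indels, so the
  true alignment is the trivial one);
* a *community* is a set of genomes, each carrying exactly one copy of
  every housekeeping family and each target family independently with
  its planted carriage probability; carried sequences are diverged
  copies of the family consensus;
* a *site CDS set* fragments every carried protein into read-derived
  partial proteins (Poisson fragment counts, geometric-tailed lengths,
  uniform starts) plus unrelated background proteins;
* a *study* is 4 + 4 sites with group-specific carriage fractions, a
  ready-to-run config manifest and a ground-truth table.

All generators are pure functions of their parameters and seed.

The default study mirrors the contrasts of the soil survey the pipeline
is built for: alkaline phosphatases strongly depleted in the low-pH
group (PhoX 0.47 vs 0.03, PhoD 0.56 vs 0.07, PhoA 0.20 vs 0.01), class B
acid phosphatase mildly depleted, UshA depleted, and class A/C acid
phosphatases, GlpQ and PhnI unchanged between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    APASE_FAMILIES,
    HIGH_PH,
    HOUSEKEEPING_FAMILIES,
    LOW_PH,
    FamilyConfig,
    RunConfig,
    SiteConfig,
)
from .io import AMINO_ACIDS, AlignmentRecord, PhoscanError, ProteinRecord, write_fasta, write_table

N_AA = len(AMINO_ACIDS)
_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


class SyntheticError(PhoscanError):
    pass


# ---------------------------------------------------------------------------
# defaults: the study conditions

#: desk-scale consensus lengths (aa) per family; lengths deliberately differ
#: across families so the RecA length-ratio normalization is exercised.
DEFAULT_FAMILY_LENGTHS: dict[str, int] = {
    "RecA": 90, "RpoB": 110, "AtpB": 100, "GyrB": 115, "SucD": 80,
    "PhoX": 110, "PhoD": 100, "PhoA": 90,
    "ClassA": 85, "ClassB": 80, "ClassC": 95,
    "UshA": 120, "GlpQ": 105, "PhnI": 85,
}

DEFAULT_CARRIAGE_HIGH: dict[str, float] = {
    "PhoX": 0.47, "PhoD": 0.56, "PhoA": 0.20,
    "ClassA": 0.30, "ClassB": 0.20, "ClassC": 0.25,
    "UshA": 0.35, "GlpQ": 0.20, "PhnI": 0.15,
}

DEFAULT_CARRIAGE_LOW: dict[str, float] = {
    "PhoX": 0.03, "PhoD": 0.07, "PhoA": 0.01,
    "ClassA": 0.30, "ClassB": 0.10, "ClassC": 0.25,
    "UshA": 0.10, "GlpQ": 0.20, "PhnI": 0.15,
}

#: lineage pool with sampling weights; the three dominant phyla sum to 0.70
LINEAGE_POOL: list[tuple[str, float]] = [
    ("Bacteria;Proteobacteria;Alphaproteobacteria", 0.13),
    ("Bacteria;Proteobacteria;Betaproteobacteria", 0.10),
    ("Bacteria;Proteobacteria;Gammaproteobacteria", 0.13),
    ("Bacteria;Actinobacteria;Actinomycetia", 0.19),
    ("Bacteria;Firmicutes;Bacilli", 0.15),
    ("Bacteria;Acidobacteria;Acidobacteriia", 0.12),
    ("Bacteria;Bacteroidetes;Sphingobacteriia", 0.12),
    ("Bacteria;Cyanobacteria;Cyanophyceae", 0.06),
]


@dataclass
class SiteDesign:
    """Parameters of the 4 + 4 two-group study the generator emulates."""

    n_sites_per_group: int = 4
    n_genomes: int = 500
    coverage: float = 2.0  # expected fragments per RecA-length protein
    ref_divergence: float = 0.30  # references vs family consensus
    community_divergence: float = 0.15  # community sequences vs consensus
    n_refs: int = 60
    fragment_length_mean: int = 45
    fragment_min_length: int = 20
    background_per_site: int = 200
    family_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_LENGTHS)
    )
    carriage_high: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIAGE_HIGH)
    )
    carriage_low: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIAGE_LOW)
    )
    length_scaled_fragments: bool = True

    def validate(self) -> None:
        if self.n_sites_per_group < 1:
            raise SyntheticError("need at least one site per group")
        if self.fragment_min_length < 10:
            raise SyntheticError("fragment min length must be >= 10 aa")
        for table in (self.carriage_high, self.carriage_low):
            for fam, c in table.items():
                if not 0.0 <= c <= 1.0:
                    raise SyntheticError(f"carriage for {fam} outside [0, 1]: {c}")
        if set(self.carriage_high) != set(self.carriage_low):
            raise SyntheticError("carriage tables must list the same families")

    @property
    def target_families(self) -> list[str]:
        return sorted(self.carriage_high)


# ---------------------------------------------------------------------------
# sequence-level helpers

def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, N_AA, size=length, dtype=np.int64)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. substitution to a uniformly chosen *other* residue."""
    out = seq.copy()
    mask = rng.random(seq.size) < rate
    n_mut = int(mask.sum())
    if n_mut:
        shift = rng.integers(1, N_AA, size=n_mut)
        out[mask] = (out[mask] + shift) % N_AA
    return out


def _to_str(seq: np.ndarray) -> str:
    return _AA_ARRAY[seq].tobytes().decode()


@dataclass
class FamilyModel:
    """A synthetic protein family: consensus plus diverged references."""

    name: str
    consensus: str
    references: list[ProteinRecord]
    alignment: list[AlignmentRecord]
    ref_lineages: dict[str, str]


def make_family(
    consensus_length: int,
    n_refs: int,
    divergence: float,
    seed: int,
    family_name: str = "Fam",
) -> FamilyModel:
    """Generate a family: random consensus and i.i.d.-substituted references.

    References carry no indels, so the true alignment is the gapless one
    and the reference length equals the consensus length exactly.
    Reference lineages are drawn from the weighted lineage pool.
    """
    if consensus_length < 30:
        raise SyntheticError("consensus_length must be >= 30 aa")
    if not 0.0 <= divergence <= 0.5:
        raise SyntheticError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    consensus = _random_sequence(consensus_length, rng)
    lineage_names = [l for l, _ in LINEAGE_POOL]
    weights = np.array([w for _, w in LINEAGE_POOL])
    weights = weights / weights.sum()
    refs: list[ProteinRecord] = []
    alignment: list[AlignmentRecord] = []
    lineages: dict[str, str] = {}
    for i in range(n_refs):
        seq = _to_str(_mutate(consensus, divergence, rng))
        rid = f"{family_name}_ref{i:03d}"
        lineage = lineage_names[rng.choice(len(lineage_names), p=weights)]
        lineages[rid] = lineage
        refs.append(ProteinRecord(rid, seq, f"lineage={lineage}"))
        alignment.append(AlignmentRecord(rid, seq))
    return FamilyModel(
        name=family_name,
        consensus=_to_str(consensus),
        references=refs,
        alignment=alignment,
        ref_lineages=lineages,
    )


# ---------------------------------------------------------------------------
# communities

@dataclass
class Genome:
    genome_id: str
    lineage: str
    carried: frozenset[str]
    proteins: dict[str, str]  # family -> full-length protein


@dataclass
class SyntheticCommunity:
    genomes: list[Genome]
    planted_carriage: dict[str, float]
    realized_carriage: dict[str, float]
    seed: int


def simulate_community(
    families: dict[str, FamilyModel],
    carriage: dict[str, float],
    n_genomes: int,
    divergence: float,
    seed: int,
    housekeeping: tuple[str, ...] = HOUSEKEEPING_FAMILIES,
    with_sequences: bool = True,
) -> SyntheticCommunity:
    """Draw a community of genomes with planted family carriage.

    Every genome carries one copy of each housekeeping family; each
    target family is carried independently with its planted probability.
    Carried sequences are ``divergence``-substituted copies of the family
    consensus.  ``with_sequences=False`` skips sequence materialization
    (carriage bookkeeping only) for cheap statistical replicates.
    """
    if n_genomes < 10:
        raise SyntheticError("n_genomes must be >= 10")
    for fam in carriage:
        if fam not in families:
            raise SyntheticError(f"carriage given for unknown family {fam}")
    rng = np.random.default_rng(seed)
    lineage_names = [l for l, _ in LINEAGE_POOL]
    weights = np.array([w for _, w in LINEAGE_POOL])
    weights = weights / weights.sum()
    consensus_int = {
        name: np.frombuffer(fm.consensus.encode(), dtype=np.uint8)
        for name, fm in families.items()
    }
    aa_index = {c: i for i, c in enumerate(AMINO_ACIDS)}
    consensus_idx = {
        name: np.array([aa_index[chr(c)] for c in arr], dtype=np.int64)
        for name, arr in consensus_int.items()
    }
    target_names = sorted(carriage)
    carried_counts = {fam: 0 for fam in target_names}
    genomes: list[Genome] = []
    for g in range(n_genomes):
        gid = f"g{g:04d}"
        lineage = lineage_names[rng.choice(len(lineage_names), p=weights)]
        carried = set(housekeeping)
        for fam in target_names:
            if rng.random() < carriage[fam]:
                carried.add(fam)
                carried_counts[fam] += 1
        proteins: dict[str, str] = {}
        if with_sequences:
            for fam in sorted(carried):
                proteins[fam] = _to_str(
                    _mutate(consensus_idx[fam], divergence, rng)
                )
        genomes.append(Genome(gid, lineage, frozenset(carried), proteins))
    realized = {fam: carried_counts[fam] / n_genomes for fam in target_names}
    return SyntheticCommunity(
        genomes=genomes,
        planted_carriage=dict(carriage),
        realized_carriage=realized,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fragmentation into CDS sets

def fragment_cds(
    community: SyntheticCommunity,
    fragment_length_mean: int,
    min_length: int,
    coverage: float,
    seed: int,
    background_n: int = 0,
    background_length: int = 100,
    length_scale: int | None = None,
) -> list[ProteinRecord]:
    """Fragment every carried protein into read-derived partial CDS.

    Each protein yields a Poisson number of fragments; with the default
    ``length_scale=None`` the Poisson mean is exactly ``coverage`` per
    protein, while an integer ``length_scale`` makes it
    ``coverage * len(protein) / length_scale`` so that fragment counts
    scale with protein length the way shotgun-read ORFs do.  Fragment
    lengths are ``min_length`` plus a geometric tail with overall mean
    ``fragment_length_mean``, clipped to the protein length; start
    positions are uniform.  ``background_n`` unrelated i.i.d.-background
    proteins are appended.
    """
    if coverage <= 0:
        raise SyntheticError("coverage must be > 0")
    if fragment_length_mean < min_length:
        raise SyntheticError("fragment_length_mean must be >= min_length")
    rng = np.random.default_rng(seed)
    p_geom = 1.0 / (fragment_length_mean - min_length + 1)
    records: list[ProteinRecord] = []
    for genome in community.genomes:
        for fam in sorted(genome.proteins):
            protein = genome.proteins[fam]
            rate = coverage
            if length_scale is not None:
                rate = coverage * len(protein) / length_scale
            n_frags = rng.poisson(rate)
            for j in range(n_frags):
                length = min_length + int(rng.geometric(p_geom)) - 1
                length = min(length, len(protein))
                start = int(rng.integers(0, len(protein) - length + 1))
                records.append(
                    ProteinRecord(
                        f"{genome.genome_id}_{fam}_{j}",
                        protein[start:start + length],
                        f"source={fam}",
                    )
                )
    for b in range(background_n):
        seq = _to_str(_random_sequence(background_length, rng))
        records.append(ProteinRecord(f"bg_{b:05d}", seq, "source=background"))
    return records


# ---------------------------------------------------------------------------
# the full study

@dataclass
class StudyData:
    """Everything ``make_study`` wrote, plus in-memory handles."""

    config: RunConfig
    config_path: Path
    truth: pd.DataFrame
    truth_path: Path
    families: dict[str, FamilyModel]
    site_paths: dict[str, Path]
    refdb_path: Path


def _site_ids(design: SiteDesign) -> list[tuple[str, str]]:
    ids = []
    for i in range(design.n_sites_per_group):
        ids.append((f"siteL{i + 1}", LOW_PH))
    for i in range(design.n_sites_per_group):
        ids.append((f"siteH{i + 1}", HIGH_PH))
    return ids


def make_study(design: SiteDesign, seed: int, outdir: str | Path) -> StudyData:
    """Materialize a full synthetic study under ``outdir``.

    Writes one CDS FASTA per site, per-family reference alignments, a
    lineage-labeled APase reference database, a ready-to-run YAML config
    and a ground-truth table (planted and realized carriage per site and
    family).  Byte-identical output for identical (design, seed).
    """
    design.validate()
    outdir = Path(outdir).resolve()
    (outdir / "sites").mkdir(parents=True, exist_ok=True)
    (outdir / "refs").mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    family_names = list(HOUSEKEEPING_FAMILIES) + design.target_families
    child_seeds = ss.spawn(len(family_names) + 2 * design.n_sites_per_group * 2)
    seed_iter = iter(child_seeds)

    families: dict[str, FamilyModel] = {}
    for fam in family_names:
        length = design.family_lengths.get(fam)
        if length is None:
            raise SyntheticError(f"no consensus length configured for family {fam}")
        fam_seed = int(next(seed_iter).generate_state(1)[0] % (2**31))
        families[fam] = make_family(
            length, design.n_refs, design.ref_divergence, fam_seed, fam
        )

    fam_configs: dict[str, FamilyConfig] = {}
    for fam, model in families.items():
        path = outdir / "refs" / f"{fam}.afa"
        write_fasta(model.references, path)
        role = "housekeeping" if fam in HOUSEKEEPING_FAMILIES else "target"
        fam_configs[fam] = FamilyConfig(fam, str(path), role)

    refdb_records = [
        rec
        for fam in APASE_FAMILIES
        if fam in families
        for rec in families[fam].references
    ]
    refdb_path = outdir / "refdb.faa"
    if refdb_records:
        write_fasta(refdb_records, refdb_path)

    recA_length = design.family_lengths["RecA"]
    truth_rows = []
    site_paths: dict[str, Path] = {}
    site_configs: dict[str, SiteConfig] = {}
    for site_id, group in _site_ids(design):
        carriage = (
            design.carriage_low if group == LOW_PH else design.carriage_high
        )
        comm_seed = int(next(seed_iter).generate_state(1)[0] % (2**31))
        frag_seed = int(next(seed_iter).generate_state(1)[0] % (2**31))
        community = simulate_community(
            families, carriage, design.n_genomes,
            design.community_divergence, comm_seed,
        )
        cds = fragment_cds(
            community,
            design.fragment_length_mean,
            design.fragment_min_length,
            design.coverage,
            frag_seed,
            background_n=design.background_per_site,
            length_scale=recA_length if design.length_scaled_fragments else None,
        )
        path = outdir / "sites" / f"{site_id}.faa"
        write_fasta(cds, path)
        site_paths[site_id] = path
        site_configs[site_id] = SiteConfig(site_id, [str(path)], group)
        for fam in design.target_families:
            truth_rows.append(
                {
                    "site_id": site_id,
                    "group": group,
                    "family": fam,
                    "true_carriage": carriage[fam],
                    "realized_carriage": community.realized_carriage[fam],
                }
            )

    truth = pd.DataFrame(truth_rows)
    truth_path = outdir / "truth.tsv"
    write_table(truth, truth_path)

    config = RunConfig(
        families=fam_configs,
        sites=site_configs,
        seed=seed,
        refdb_path=str(refdb_path) if refdb_records else None,
        output_dir=str(outdir / "results"),
    )
    config.validate()
    # the YAML manifest stores paths relative to the study directory so the
    # whole directory stays relocatable; the in-memory config is absolute
    config_path = outdir / "config.yaml"
    portable = RunConfig.from_dict(config.to_dict())
    for fam in portable.families.values():
        fam.reference_path = str(Path(fam.reference_path).relative_to(outdir))
    for site in portable.sites.values():
        site.cds_paths = [
            str(Path(p).relative_to(outdir)) for p in site.cds_paths
        ]
    if portable.refdb_path is not None:
        portable.refdb_path = str(Path(portable.refdb_path).relative_to(outdir))
    portable.output_dir = "results"
    portable.to_yaml(config_path)

    return StudyData(
        config=config,
        config_path=config_path,
        truth=truth,
        truth_path=truth_path,
        families=families,
        site_paths=site_paths,
        refdb_path=refdb_path,
    )


def draw_frequency_design(design: SiteDesign, seed: int) -> pd.DataFrame:
    """Frequency-level view of the study: realized carriage per site.

    Draws each site's realized carriage fractions from the community
    model's binomial distribution without materializing sequences.
    Returns an abundance-shaped frame (site_id, group, family,
    frequency) usable directly by :func:`phoscan.compare.compare_groups`
    for cheap statistical replicates.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for site_id, group in _site_ids(design):
        carriage = design.carriage_low if group == LOW_PH else design.carriage_high
        for fam in design.target_families:
            realized = rng.binomial(design.n_genomes, carriage[fam]) / design.n_genomes
            rows.append(
                {
                    "site_id": site_id,
                    "group": group,
                    "family": fam,
                    "frequency": realized,
                }
            )
    return pd.DataFrame(rows)
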