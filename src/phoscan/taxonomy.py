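"""Best-hit taxonomic assignment and diversity summaries.

Accepted hits are aligned against a curated, lineage-labeled reference
protein database (Smith-Waterman local alignment, BLOSUM62, gap open
11 / extend 1) and each hit inherits the lineage of its single
best-scoring reference.  Reference FASTA headers carry the lineage in a
parseable convention::

    >ref_id lineage=Bacteria;Proteobacteria;Alphaproteobacteria

Assignments aggregate into a rank hierarchy (domain, phylum, class, ...)
whose per-node counts are conserved at every level, and export as Krona
``ktImportText`` text (one ``count<TAB>rank1<TAB>rank2...`` line per
leaf).  ``mean_identity`` reports the mean percent amino-acid identity
of hits to their best references — the statistic that summarizes how
diverged environmental sequences are from the curated database.

Alignment scores are reported in bits using the standard gapped
BLOSUM62-11-1 Karlin-Altschul parameters (lambda = 0.267, K = 0.041);
the default acceptance floor of 50 bits plays the role of a fixed
E-value cutoff without requiring database-size calibration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .io import PhoscanError, ProteinRecord

logger = logging.getLogger("phoscan")

#: gapped BLOSUM62-11-1 Karlin-Altschul parameters (BLAST defaults)
KA_LAMBDA = 0.267
KA_K = 0.041

GAP_OPEN = 11  # cost of the first residue of a gap
GAP_EXTEND = 1  # cost of each further residue


class TaxonomyError(PhoscanError):
    pass


def raw_to_bits(raw_score: float) -> float:
    """Convert a raw BLOSUM62 alignment score to a bit score."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -float(GAP_OPEN)
    aligner.extend_gap_score = -float(GAP_EXTEND)
    return aligner


_ALIGNER = _make_aligner()


def alignment_identity(alignment) -> float:
    """Percent identity over aligned columns, gap columns in the denominator."""
    qa, ta = alignment[0], alignment[1]
    identical = sum(1 for x, y in zip(qa, ta) if x == y and x != "-")
    columns = len(qa)
    if columns == 0:
        return 0.0
    return 100.0 * identical / columns


def pairwise_align(query: str, ref: str) -> tuple[float, float]:
    """Local alignment of two protein strings.

    Returns ``(bit_score, percent_identity)`` under BLOSUM62 with affine
    gaps (open 11, extend 1).  Identity counts identical columns over
    all aligned columns including gapped ones.
    """
    if not query or not ref:
        raise TaxonomyError("pairwise_align needs two non-empty sequences")
    alignments = _ALIGNER.align(query, ref)
    best = alignments[0]
    return raw_to_bits(best.score), alignment_identity(best)


def pairwise_score(query: str, ref: str) -> float:
    """Bit score only (no traceback; used for the best-hit scan)."""
    return raw_to_bits(_ALIGNER.score(query, ref))


# ---------------------------------------------------------------------------
# reference database and assignment

def parse_lineage(description: str, record_id: str = "?") -> tuple[str, ...]:
    """Extract the ``lineage=A;B;C`` ranks from a reference header."""
    for token in description.split():
        if token.startswith("lineage="):
            ranks = tuple(r for r in token[len("lineage="):].split(";") if r)
            if ranks:
                return ranks
    raise TaxonomyError(f"record {record_id!r}: no parseable lineage= field")


@dataclass(frozen=True)
class TaxonAssignment:
    cds_id: str
    family_name: str
    best_ref_id: str
    percent_identity: float
    bit_score: float
    lineage: tuple[str, ...]


def assign_hits(
    queries: list[tuple[str, str, str]],
    refdb: list[ProteinRecord],
    min_score: float = 50.0,
) -> tuple[list[TaxonAssignment], list[str]]:
    """Assign each hit to the lineage of its best-scoring reference.

    ``queries`` are ``(cds_id, family_name, sequence)`` triples.  A hit
    scoring below ``min_score`` bits against every reference is returned
    in the unassigned list.  Score ties break by higher percent identity,
    then lexicographic reference id.
    """
    if not refdb:
        raise TaxonomyError("empty reference database")
    lineages = {rec.id: parse_lineage(rec.description, rec.id) for rec in refdb}
    assignments: list[TaxonAssignment] = []
    unassigned: list[str] = []
    for cds_id, family, seq in queries:
        scored = [(pairwise_score(seq, rec.sequence), rec) for rec in refdb]
        best_score = max(s for s, _ in scored)
        if best_score < min_score:
            unassigned.append(cds_id)
            continue
        tied = [rec for s, rec in scored if s == best_score]
        candidates = []
        for rec in tied:
            bits, identity = pairwise_align(seq, rec.sequence)
            candidates.append((identity, rec))
        candidates.sort(key=lambda t: (-t[0], t[1].id))
        identity, best_ref = candidates[0]
        assignments.append(
            TaxonAssignment(
                cds_id=cds_id,
                family_name=family,
                best_ref_id=best_ref.id,
                percent_identity=identity,
                bit_score=best_score,
                lineage=lineages[best_ref.id],
            )
        )
    return assignments, unassigned


def mean_identity(assignments: list[TaxonAssignment]) -> float:
    """Mean percent amino-acid identity of hits to their best references."""
    if not assignments:
        raise TaxonomyError("mean_identity of an empty assignment list")
    return float(
        sum(a.percent_identity for a in assignments) / len(assignments)
    )


# ---------------------------------------------------------------------------
# rank aggregation and Krona export

@dataclass
class RankNode:
    name: str
    count: int = 0  # total assignments in this subtree
    unresolved: int = 0  # assignments whose lineage ends at this node
    children: dict[str, "RankNode"] = field(default_factory=dict)


@dataclass
class RankHierarchy:
    root: RankNode
    total: int

    def check_conservation(self) -> None:
        """Every node's count must equal its children's plus unresolved."""

        def _walk(node: RankNode) -> None:
            child_sum = sum(c.count for c in node.children.values())
            if node.count != child_sum + node.unresolved:
                raise TaxonomyError(
                    f"count conservation violated at {node.name!r}: "
                    f"{node.count} != {child_sum} + {node.unresolved}"
                )
            for child in node.children.values():
                _walk(child)

        _walk(self.root)
        if self.total != self.root.count:
            raise TaxonomyError("hierarchy total does not match root count")


def aggregate_ranks(
    assignments: list[TaxonAssignment], depth: int | None = None
) -> RankHierarchy:
    """Build the rank hierarchy, truncated at ``depth`` ranks if given."""
    root = RankNode(name="root")
    for a in assignments:
        ranks = a.lineage if depth is None else a.lineage[:depth]
        node = root
        node.count += 1
        for rank in ranks:
            node = node.children.setdefault(rank, RankNode(name=rank))
            node.count += 1
        node.unresolved += 1
    hierarchy = RankHierarchy(root=root, total=len(assignments))
    hierarchy.check_conservation()
    return hierarchy


def krona_lines(hierarchy: RankHierarchy) -> list[str]:
    """Krona ktImportText lines: leading count then tab-separated ranks."""
    lines: list[tuple[tuple[str, ...], int]] = []

    def _walk(node: RankNode, path: tuple[str, ...]) -> None:
        if node.unresolved > 0 and path:
            lines.append((path, node.unresolved))
        for name in node.children:
            _walk(node.children[name], path + (name,))

    _walk(hierarchy.root, ())
    lines.sort(key=lambda t: t[0])
    return [f"{count}\t" + "\t".join(path) for path, count in lines]


def write_krona_text(hierarchy: RankHierarchy, path: str | Path) -> None:
    """Write the hierarchy in the Krona ktImportText dialect (UTF-8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    content = "\n".join(krona_lines(hierarchy))
    with open(path, "wt", encoding="utf-8") as out:
        out.write(content + ("\n" if content else ""))


def assignment_rows(assignments: list[TaxonAssignment]) -> list[dict]:
    """Flatten assignments for TSV output."""
    return [
        {
            "cds_id": a.cds_id,
            "family": a.family_name,
            "best_ref_id": a.best_ref_id,
            "percent_identity": a.percent_identity,
            "bit_score": a.bit_score,
            "lineage": ";".join(a.lineage),
        }
        for a in assignments
    ]
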