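"""Pairwise alignment, best-hit assignment, rank aggregation, Krona."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oracles import sw_score
from phoscan.io import ProteinRecord
from phoscan.synthetic import _mutate, _random_sequence, _to_str, make_family
from phoscan.taxonomy import (
    GAP_EXTEND,
    GAP_OPEN,
    TaxonAssignment,
    TaxonomyError,
    aggregate_ranks,
    assign_hits,
    krona_lines,
    mean_identity,
    pairwise_align,
    parse_lineage,
    raw_to_bits,
    write_krona_text,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestPairwiseAlign:
    def test_identical_sequences(self):
        bits, ident = pairwise_align("MKVL", "MKVL")
        assert ident == 100.0

    def test_single_substitution(self):
        _, ident = pairwise_align("MKVL", "MKIL")
        assert ident == pytest.approx(75.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = _to_str(_random_sequence(15, rng))
            b = _to_str(_random_sequence(12, rng))
            assert pairwise_align(a, b)[0] == pytest.approx(pairwise_align(b, a)[0])

    def test_matches_hand_written_gotoh_dp(self):
        """Scores agree with an independent affine-gap Smith-Waterman."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            a = _to_str(_random_sequence(int(rng.integers(4, 13)), rng))
            b = _to_str(_random_sequence(int(rng.integers(4, 13)), rng))
            expected = raw_to_bits(sw_score(a, b, BLOSUM62, GAP_OPEN, GAP_EXTEND))
            assert pairwise_align(a, b)[0] == pytest.approx(expected, abs=1e-9)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(TaxonomyError):
            pairwise_align("", "MKVL")


class TestLineageParsing:
    def test_parses_semicolon_ranks(self):
        ranks = parse_lineage("lineage=Bacteria;Proteobacteria;Alpha")
        assert ranks == ("Bacteria", "Proteobacteria", "Alpha")

    def test_missing_lineage_names_record(self):
        with pytest.raises(TaxonomyError, match="ref7"):
            parse_lineage("plain description", "ref7")


class TestAssignHits:
    @pytest.fixture(scope="class")
    def refdb(self):
        fam = make_family(60, 12, 0.3, 17, "PhoX")
        return fam, fam.references

    def test_identical_hit_assigned_at_full_identity(self, refdb):
        fam, refs = refdb
        queries = [("q1", "PhoX", refs[0].sequence)]
        assignments, unassigned = assign_hits(queries, refs, min_score=50.0)
        assert not unassigned
        a = assignments[0]
        assert a.best_ref_id == refs[0].id
        assert a.percent_identity == 100.0
        assert a.lineage[0] == "Bacteria"

    def test_low_scoring_hit_is_unassigned(self, refdb):
        _, refs = refdb
        rng = np.random.default_rng(2)
        junk = _to_str(_random_sequence(40, rng))
        assignments, unassigned = assign_hits([("q1", "PhoX", junk)], refs, 50.0)
        assert unassigned == ["q1"] and not assignments

    def test_score_tie_broken_by_identity(self):
        refs = [
            ProteinRecord("refB", "MKVLMKVLMKVL", "lineage=Bacteria;P1"),
            ProteinRecord("refA", "MKVLMKVLMKVL", "lineage=Bacteria;P2"),
        ]
        assignments, _ = assign_hits(
            [("q", "PhoX", "MKVLMKVLMKVL")], refs, min_score=10.0
        )
        # equal score and identity: lexicographic ref id wins
        assert assignments[0].best_ref_id == "refA"


class TestMeanIdentity:
    def test_simple_mean(self):
        mk = lambda i: TaxonAssignment("q", "F", "r", i, 60.0, ("Bacteria",))
        assert mean_identity([mk(60), mk(70), mk(80)]) == pytest.approx(70.0)
        assert mean_identity([mk(100)]) == 100.0

    def test_empty_is_an_error(self):
        with pytest.raises(TaxonomyError):
            mean_identity([])

    def test_hits_at_30_percent_divergence_average_near_70(self):
        """Sequences mutated from references at rate 0.3 align back at
        ~70% identity (binomial expectation)."""
        fam = make_family(90, 20, 0.3, 23, "PhoD")
        rng = np.random.default_rng(23)
        aa = {c: i for i, c in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        queries = []
        for i, ref in enumerate(fam.references[:15]):
            arr = np.array([aa[c] for c in ref.sequence])
            queries.append((f"q{i}", "PhoD", _to_str(_mutate(arr, 0.3, rng))))
        assignments, _ = assign_hits(queries, fam.references, min_score=30.0)
        assert len(assignments) == 15
        assert mean_identity(assignments) == pytest.approx(70.0, abs=5.0)


def _assignments(lineages):
    return [
        TaxonAssignment(f"q{i}", "F", f"r{i}", 80.0, 60.0, tuple(l.split(";")))
        for i, l in enumerate(lineages)
    ]


class TestAggregateRanks:
    def test_counts_by_phylum(self):
        h = aggregate_ranks(_assignments([
            "Bacteria;Proteobacteria",
            "Bacteria;Proteobacteria",
            "Bacteria;Actinobacteria",
        ]))
        assert h.total == 3
        bact = h.root.children["Bacteria"]
        assert bact.count == 3
        assert bact.children["Proteobacteria"].count == 2
        assert bact.children["Actinobacteria"].count == 1

    def test_depth_truncation(self):
        h = aggregate_ranks(_assignments([
            "Bacteria;Proteobacteria", "Bacteria;Actinobacteria",
            "Bacteria;Firmicutes",
        ]), depth=1)
        bact = h.root.children["Bacteria"]
        assert bact.count == 3 and not bact.children

    def test_top_phyla_fraction_consistent_between_paths(self):
        """The top-3-phylum share computed from the hierarchy must equal
        the share computed directly from the assignment list."""
        rng = np.random.default_rng(31)
        phyla = ["Proteobacteria", "Actinobacteria", "Firmicutes",
                 "Acidobacteria", "Bacteroidetes"]
        assigns = _assignments([
            f"Bacteria;{rng.choice(phyla)};c{rng.integers(3)}"
            for _ in range(200)
        ])
        h = aggregate_ranks(assigns)
        top3 = sorted(
            h.root.children["Bacteria"].children.values(),
            key=lambda n: -n.count,
        )[:3]
        frac_tree = sum(n.count for n in top3) / h.total
        top3_names = {n.name for n in top3}
        frac_list = sum(a.lineage[1] in top3_names for a in assigns) / len(assigns)
        assert frac_tree == pytest.approx(frac_list)

    @pytest.mark.parametrize("seed", range(5))
    def test_count_conservation_fuzzed(self, seed):
        rng = np.random.default_rng(seed)
        lineages = [
            ";".join(
                f"r{d}_{rng.integers(3)}" for d in range(int(rng.integers(1, 5)))
            )
            for _ in range(int(rng.integers(1, 60)))
        ]
        h = aggregate_ranks(_assignments(lineages))
        h.check_conservation()  # raises on violation


class TestKrona:
    def test_dialect(self, tmp_path):
        h = aggregate_ranks(_assignments([
            "Bacteria;Proteobacteria",
            "Bacteria;Proteobacteria",
            "Bacteria;Actinobacteria",
        ]))
        path = tmp_path / "k.txt"
        write_krona_text(h, path)
        assert path.read_text().splitlines() == [
            "2\tBacteria\tProteobacteria",
            "1\tBacteria\tActinobacteria",
        ][::-1]  # sorted by lineage: Actinobacteria first

    def test_empty_hierarchy(self, tmp_path):
        h = aggregate_ranks(_assignments([]))
        path = tmp_path / "k.txt"
        write_krona_text(h, path)
        assert path.read_text() == ""

    @pytest.mark.parametrize("seed", range(5))
    def test_leading_counts_sum_to_total(self, seed):
        rng = np.random.default_rng(100 + seed)
        lineages = [
            ";".join(f"r{d}_{rng.integers(4)}" for d in range(int(rng.integers(1, 4))))
            for _ in range(int(rng.integers(1, 80)))
        ]
        h = aggregate_ranks(_assignments(lineages))
        counts = [int(line.split("\t")[0]) for line in krona_lines(h)]
        assert sum(counts) == h.total
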