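"""Forward/Viterbi scoring, site screening and decoy calibration."""

import math

import numpy as np
import pytest

from conftest import random_profiles, single_state_profile
from oracles import enumerate_global, enumerate_local
from phoscan.io import AlignmentRecord, ProteinRecord
from phoscan.profiles import build_profile
from phoscan.search import (
    PyhmmerEngine,
    ScoringProfile,
    SearchError,
    decoy_fdr,
    forward_bits,
    search_site,
    shuffle_sequence,
    viterbi_bits,
)
from phoscan.synthetic import make_family


class TestClosedForms:
    @pytest.mark.parametrize("p", [0.3, 0.7, 0.95])
    def test_single_state_global_score_is_log_odds(self, p):
        # one match state, deterministic transitions: the only path scores
        # the emission odds exactly
        prof = single_state_profile(p)
        expected = math.log2(p / 0.05)
        assert forward_bits(prof, "A", "global") == pytest.approx(expected, abs=1e-12)
        assert viterbi_bits(prof, "A", "global") == pytest.approx(expected, abs=1e-12)

    def test_all_x_sequence_scores_finite(self):
        # X scores as a 1/20 emission against the 1/20 background (odds 1);
        # a smoothed profile (all transitions positive) admits any length
        prof = build_profile([AlignmentRecord("r0", "ACDE")], 0.5, 1.0)
        for mode in ("local", "global"):
            assert math.isfinite(forward_bits(prof, "XXX", mode))

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(SearchError):
            forward_bits(single_state_profile(0.5), "")

    def test_unknown_mode_is_an_error(self):
        with pytest.raises(SearchError):
            forward_bits(single_state_profile(0.5), "A", "glocal")


class TestOracleEquivalence:
    """Spot-check against exhaustive path enumeration (the full grid runs
    in the acceptance suite)."""

    @pytest.mark.parametrize("mode,oracle", [
        ("local", enumerate_local), ("global", enumerate_global),
    ])
    def test_matches_enumeration(self, mode, oracle):
        rng = np.random.default_rng(42)
        profiles = random_profiles(seed=7, n_per_length=1)
        for prof in profiles:
            for n in (1, 2, 4):
                for _ in range(3):
                    seq = "".join(rng.choice(list("ACD"), size=n))
                    fo, vo = oracle(prof, seq)
                    assert forward_bits(prof, seq, mode) == pytest.approx(fo, abs=1e-9)
                    assert viterbi_bits(prof, seq, mode) == pytest.approx(vo, abs=1e-9)

    def test_forward_dominates_viterbi(self):
        rng = np.random.default_rng(1)
        for prof in random_profiles(seed=3, n_per_length=2):
            for _ in range(5):
                seq = "".join(rng.choice(list("ACDE"), size=int(rng.integers(1, 8))))
                for mode in ("local", "global"):
                    f = forward_bits(prof, seq, mode)
                    v = viterbi_bits(prof, seq, mode)
                    assert f >= v - 1e-6


class TestViterbiPath:
    def test_path_consistent_with_emissions(self):
        fam = make_family(40, 10, 0.1, 5, "F")
        prof = build_profile(fam.alignment)
        bits, path = viterbi_bits(prof, fam.consensus, "global", return_path=True)
        assert path[0][0] in ("M", "I", "D")
        emitted = sum(1 for kind, _, _ in path if kind in ("M", "I"))
        assert emitted == len(fam.consensus)

    def test_local_path_is_contiguous_match_segment_for_exact_fragment(self):
        fam = make_family(40, 10, 0.05, 6, "F")
        prof = build_profile(fam.alignment)
        frag = fam.consensus[10:30]
        bits, path = viterbi_bits(prof, frag, "local", return_path=True)
        kinds = [k for k, _, _ in path]
        assert kinds[0] == "M" and kinds[-1] == "M"
        nodes = [node for k, node, _ in path if k == "M"]
        assert nodes == list(range(nodes[0], nodes[0] + len(nodes)))


class TestConsensusDominance:
    def test_consensus_outscores_shuffled_median(self):
        """A family's own consensus must beat length-matched shuffles."""
        rng = np.random.default_rng(9)
        fam = make_family(60, 20, 0.2, 2, "F")
        prof = build_profile(fam.alignment)
        true_score = forward_bits(prof, fam.consensus)
        shuffled = [
            forward_bits(prof, shuffle_sequence(fam.consensus, rng))
            for _ in range(11)
        ]
        assert true_score > float(np.median(shuffled))


class TestSearchSite:
    @pytest.fixture(scope="class")
    def planted(self):
        rng = np.random.default_rng(12)
        fam = make_family(80, 30, 0.25, 3, "PhoX")
        prof = build_profile(fam.alignment, family_name="PhoX")
        from phoscan.synthetic import _mutate, _random_sequence, _to_str

        aa = {c: i for i, c in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        cons = np.array([aa[c] for c in fam.consensus])
        homologs = [
            ProteinRecord(f"hom{i}", _to_str(_mutate(cons, 0.15, rng)))
            for i in range(3)
        ]
        background = [
            ProteinRecord(f"bg{i}", _to_str(_random_sequence(70, rng)))
            for i in range(100)
        ]
        return prof, homologs, background

    def test_planted_homologs_counted_background_rejected(self, planted):
        prof, homologs, background = planted
        table = search_site([prof], homologs + background, 25.0, "s1")
        assert table.n("PhoX") == 3
        assert all(h.bit_score >= 25.0 for h in table.hits)
        assert all(h.bit_score >= h.viterbi_bits - 1e-6 for h in table.hits)

    def test_counts_are_order_invariant(self, planted):
        prof, homologs, background = planted
        cds = homologs + background
        t1 = search_site([prof], cds, 25.0, "s1")
        t2 = search_site([prof], cds[::-1], 25.0, "s1")
        assert t1.counts == t2.counts

    def test_empty_cds_gives_zero_counts(self, planted):
        prof, _, _ = planted
        assert search_site([prof], [], 25.0, "s1").counts == {"PhoX": 0}

    def test_infinite_threshold_rejects_everything(self, planted):
        prof, homologs, _ = planted
        table = search_site([prof], homologs, math.inf, "s1")
        assert table.n("PhoX") == 0


class TestDecoyFdr:
    @pytest.fixture(scope="class")
    def setup(self):
        rng = np.random.default_rng(8)
        fam = make_family(60, 20, 0.2, 4, "F")
        prof = build_profile(fam.alignment)
        from phoscan.synthetic import _random_sequence, _to_str

        cds = [
            ProteinRecord(f"c{i}", _to_str(_random_sequence(50, rng)))
            for i in range(30)
        ]
        return prof, cds

    def test_threshold_extremes(self, setup):
        prof, cds = setup
        assert decoy_fdr(prof, cds, -math.inf, seed=0) == 1.0
        assert decoy_fdr(prof, cds, math.inf, seed=0) == 0.0

    def test_above_max_decoy_score_gives_zero(self, setup):
        prof, cds = setup
        rng = np.random.default_rng(0)
        sp = ScoringProfile(prof)
        from phoscan.search import encode_sequence

        scores = [
            sp.score(encode_sequence(shuffle_sequence(r.sequence, rng)), "local", False)
            for r in cds
        ]
        # same seed => decoy_fdr sees exactly these shuffles
        assert decoy_fdr(prof, cds, max(scores) + 1e-6, seed=0) == 0.0


class TestPyhmmerEngine:
    def test_adapter_produces_identical_schema(self):
        pytest.importorskip("pyhmmer")
        rng = np.random.default_rng(21)
        fam = make_family(80, 30, 0.2, 13, "PhoD")
        from phoscan.synthetic import _mutate, _random_sequence, _to_str

        aa = {c: i for i, c in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        cons = np.array([aa[c] for c in fam.consensus])
        cds = [
            ProteinRecord(f"hom{i}", _to_str(_mutate(cons, 0.1, rng)))
            for i in range(3)
        ] + [
            ProteinRecord(f"bg{i}", _to_str(_random_sequence(80, rng)))
            for i in range(20)
        ]
        engine = PyhmmerEngine()
        table = engine.search_site({"PhoD": fam.alignment}, cds, 25.0, "s1")
        assert table.site_id == "s1"
        assert table.n("PhoD") == 3
        hit = table.hits[0]
        # identical schema to the native engine's HitTable
        assert {h.family_name for h in table.hits} == {"PhoD"}
        assert hit.accepted and hit.bit_score >= 25.0
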