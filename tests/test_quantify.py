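"""Length normalization, genome equivalents, gene frequencies, census."""

import numpy as np
import pytest

from phoscan.config import FamilyConfig, RunConfig, SiteConfig
from phoscan.profiles import build_profile
from phoscan.io import AlignmentRecord
from phoscan.quantify import (
    QuantifyError,
    census_genomes,
    gene_frequency,
    genome_equivalents,
    normalize_count,
    quantify_sites,
)
from phoscan.search import HitTable


class TestNormalizeCount:
    def test_long_family_corrected_down(self):
        assert normalize_count(100, 700, 350) == pytest.approx(50.0)

    def test_identity_when_lengths_equal(self):
        assert normalize_count(100, 350, 350) == pytest.approx(100.0)

    def test_zero_count(self):
        assert normalize_count(0, 123, 350) == 0.0

    def test_alternative_direction(self):
        assert normalize_count(100, 700, 350, "multiply_by_ratio") == pytest.approx(200.0)

    def test_zero_length_is_an_error(self):
        with pytest.raises(QuantifyError):
            normalize_count(10, 0, 350)


class TestGenomeEquivalents:
    def test_equal_counts(self):
        hk = dict.fromkeys(["RecA", "RpoB", "AtpB", "GyrB", "SucD"], 10.0)
        assert genome_equivalents(hk) == pytest.approx(10.0)

    def test_mean_of_spread_counts(self):
        hk = dict(zip(["RecA", "RpoB", "AtpB", "GyrB", "SucD"], [8, 9, 10, 11, 12]))
        assert genome_equivalents(hk) == pytest.approx(10.0)

    def test_missing_family_named_in_error(self):
        hk = dict.fromkeys(["RecA", "RpoB", "AtpB", "GyrB"], 10.0)
        with pytest.raises(QuantifyError, match="SucD"):
            genome_equivalents(hk)

    def test_all_zero_returns_zero_with_warning(self, caplog):
        hk = dict.fromkeys(["RecA", "RpoB", "AtpB", "GyrB", "SucD"], 0.0)
        with caplog.at_level("WARNING", logger="phoscan"):
            assert genome_equivalents(hk) == 0.0
        assert "undefined" in caplog.text


class TestGeneFrequency:
    def test_percentage(self):
        f, pct = gene_frequency(4.7, 10.0)
        assert f == pytest.approx(0.47) and pct == pytest.approx(47.0)

    def test_zero(self):
        assert gene_frequency(0.0, 10.0) == (0.0, 0.0)

    def test_copy_number_scaling(self):
        f, pct = gene_frequency(12.0, 10.0, copy_number=2)
        assert pct == pytest.approx(60.0)

    def test_undefined_when_no_genomes(self):
        with pytest.raises(QuantifyError, match="undefined"):
            gene_frequency(1.0, 0.0)


def _toy_config_and_profiles(tmp_path, pho_len=30, recA_len=30):
    """Minimal 6-family setup with controllable reference lengths."""
    hk = {"RecA": recA_len, "RpoB": 30, "AtpB": 30, "GyrB": 30, "SucD": 30}
    families = {}
    profiles = {}
    for fam, ln in {**hk, "PhoX": pho_len}.items():
        seq = "ACDEF" * (ln // 5)
        aln = [AlignmentRecord("r0", seq)]
        prof = build_profile(aln, 0.5, 1.0, family_name=fam)
        assert prof.reference_length == ln
        profiles[fam] = prof
        path = tmp_path / f"{fam}.afa"
        path.write_text(f">r0\n{seq}\n")
        role = "target" if fam == "PhoX" else "housekeeping"
        families[fam] = FamilyConfig(fam, str(path), role)
    sites = {"s1": SiteConfig("s1", [str(tmp_path / "s1.faa")], "high_pH")}
    cfg = RunConfig(families=families, sites=sites)
    return cfg, profiles


class TestQuantifySites:
    def test_identity_case(self, tmp_path):
        cfg, profiles = _toy_config_and_profiles(tmp_path)
        table = HitTable("s1", counts={
            "RecA": 10, "RpoB": 10, "AtpB": 10, "GyrB": 10, "SucD": 10, "PhoX": 5,
        })
        ab = quantify_sites([table], profiles, cfg)
        row = ab[(ab.family == "PhoX")].iloc[0]
        assert row.percent == pytest.approx(50.0)
        assert row.genome_equivalents == pytest.approx(10.0)

    def test_double_length_family_halves_frequency(self, tmp_path):
        cfg, profiles = _toy_config_and_profiles(tmp_path, pho_len=60, recA_len=30)
        table = HitTable("s1", counts={
            "RecA": 10, "RpoB": 10, "AtpB": 10, "GyrB": 10, "SucD": 10, "PhoX": 5,
        })
        ab = quantify_sites([table], profiles, cfg)
        assert ab[(ab.family == "PhoX")].iloc[0].percent == pytest.approx(25.0)

    def test_scale_invariance(self, tmp_path):
        """Multiplying every raw count by k scales counts and G but leaves
        every gene frequency unchanged."""
        cfg, profiles = _toy_config_and_profiles(tmp_path, pho_len=60)
        base = {"RecA": 7, "RpoB": 9, "AtpB": 11, "GyrB": 8, "SucD": 12, "PhoX": 6}
        t1 = HitTable("s1", counts=dict(base))
        t2 = HitTable("s1", counts={k: 5 * v for k, v in base.items()})
        a1 = quantify_sites([t1], profiles, cfg)
        a2 = quantify_sites([t2], profiles, cfg)
        f1 = a1[a1.family == "PhoX"].iloc[0]
        f2 = a2[a2.family == "PhoX"].iloc[0]
        assert f2.normalized_count == pytest.approx(5 * f1.normalized_count)
        assert f2.genome_equivalents == pytest.approx(5 * f1.genome_equivalents)
        assert f2.frequency == pytest.approx(f1.frequency)

    def test_frequency_above_one_flagged_not_clamped(self, tmp_path):
        cfg, profiles = _toy_config_and_profiles(tmp_path)
        table = HitTable("s1", counts={
            "RecA": 10, "RpoB": 10, "AtpB": 10, "GyrB": 10, "SucD": 10, "PhoX": 15,
        })
        row = quantify_sites([table], profiles, cfg)
        row = row[row.family == "PhoX"].iloc[0]
        assert row.percent == pytest.approx(150.0)
        assert row.flag == "frequency>100%"

    def test_monotonicity(self, tmp_path):
        cfg, profiles = _toy_config_and_profiles(tmp_path)
        counts = {"RecA": 10, "RpoB": 10, "AtpB": 10, "GyrB": 10, "SucD": 10}
        freqs = []
        for n in (2, 5, 9):
            ab = quantify_sites(
                [HitTable("s1", counts={**counts, "PhoX": n})], profiles, cfg
            )
            freqs.append(ab[ab.family == "PhoX"].iloc[0].frequency)
        assert freqs == sorted(freqs) and freqs[0] < freqs[-1]


class TestCensus:
    @pytest.fixture(scope="class")
    def apase_profiles(self):
        from phoscan.synthetic import make_family

        fams = {}
        for i, name in enumerate(("PhoX", "PhoD")):
            fm = make_family(60, 15, 0.2, 30 + i, name)
            fams[name] = (fm, build_profile(fm.alignment, family_name=name))
        return fams

    def _genome(self, fams, carry, gid, taxon, rng):
        from phoscan.io import ProteinRecord
        from phoscan.synthetic import _random_sequence, _to_str

        records = [
            ProteinRecord(f"{gid}_bg{i}", _to_str(_random_sequence(60, rng)))
            for i in range(3)
        ]
        for fam in carry:
            records.append(ProteinRecord(f"{gid}_{fam}", fams[fam][0].consensus))
        return records, taxon

    def test_fraction_with_at_least_one_apase(self, apase_profiles):
        rng = np.random.default_rng(0)
        genomes = {
            "g1": self._genome(apase_profiles, ["PhoX"], "g1", "Proteobacteria", rng),
            "g2": self._genome(apase_profiles, [], "g2", "Proteobacteria", rng),
        }
        res = census_genomes(
            genomes, {k: v[1] for k, v in apase_profiles.items()}, 25.0
        )
        row = res.by_taxon.iloc[0]
        assert (row.n_with_apase, row.n_total, row.fraction) == (1, 2, 0.5)

    def test_multi_family_carrier_counted_once(self, apase_profiles):
        rng = np.random.default_rng(1)
        genomes = {
            "g1": self._genome(
                apase_profiles, ["PhoX", "PhoD"], "g1", "Firmicutes", rng
            ),
            "g2": self._genome(apase_profiles, ["PhoD"], "g2", "Firmicutes", rng),
            "g3": self._genome(apase_profiles, [], "g3", "Firmicutes", rng),
            "g4": self._genome(apase_profiles, [], "g4", "Firmicutes", rng),
        }
        res = census_genomes(
            genomes, {k: v[1] for k, v in apase_profiles.items()}, 25.0
        )
        row = res.by_taxon.iloc[0]
        assert (row.n_with_apase, row.n_total) == (2, 4)
        assert row.fraction == pytest.approx(0.5)
        g1 = res.presence[res.presence.genome_id == "g1"].iloc[0]
        assert bool(g1.PhoX) and bool(g1.PhoD) and bool(g1.any_apase)
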