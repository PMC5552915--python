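"""Shared fixtures: small alignments, random profiles and a tiny study."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from phoscan.io import AlignmentRecord
from phoscan.profiles import ProfileHMM, build_profile


def random_alignment(rng, n_rows=3, n_cols=4, letters="ACD", gap_p=0.16):
    """Random gapped alignment over a small alphabet (never all-gap rows)."""
    probs = [(1 - gap_p) / len(letters)] * len(letters) + [gap_p]
    rows = []
    for r in range(n_rows):
        s = "".join(
            rng.choice(list(letters) + ["-"], p=probs) for _ in range(n_cols)
        )
        if s.count("-") == n_cols:
            s = letters[0] + s[1:]
        rows.append(AlignmentRecord(f"r{r}", s))
    return rows


def random_profiles(seed, n_per_length=3, lengths=(1, 2, 3, 4), letters="ACD"):
    """Random small profiles built from random gapped alignments."""
    rng = np.random.default_rng(seed)
    profiles = []
    for L_target in lengths:
        made = 0
        while made < n_per_length:
            aln = random_alignment(
                rng, n_rows=int(rng.integers(2, 5)),
                n_cols=int(rng.integers(L_target, L_target + 3)),
                letters=letters,
            )
            try:
                p = build_profile(aln, 0.5, float(rng.uniform(0.2, 2.0)))
            except Exception:
                continue
            if p.L <= max(lengths):
                profiles.append(p)
                made += 1
    return profiles


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A miniature 2+2-site study, shared read-only across tests."""
    from phoscan.synthetic import SiteDesign, make_study

    outdir = tmp_path_factory.mktemp("tiny_study")
    design = SiteDesign(
        n_sites_per_group=2, n_genomes=40, n_refs=15, background_per_site=30,
    )
    return make_study(design, seed=11, outdir=outdir)


def single_state_profile(p_match_A: float) -> ProfileHMM:
    """Hand-built L=1 profile emitting A with probability p; deterministic
    transitions (Begin -> M1 -> End), uniform background."""
    e = np.full(20, (1.0 - p_match_A) / 19.0)
    e[0] = p_match_A
    one = np.array([1.0, 1.0])
    zero = np.array([0.0, 0.0])
    return ProfileHMM(
        family_name="single",
        match_emissions=e[None, :],
        insert_emissions=np.full((2, 20), 0.05),
        t_mm=one.copy(), t_mi=zero.copy(), t_md=zero.copy(),
        t_im=one.copy(), t_ii=zero.copy(), t_dm=one.copy(), t_dd=zero.copy(),
        background=np.full(20, 0.05),
        reference_length=1,
    )
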