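"""Screen CDS sets against family profiles.

This is the package's search stage: every predicted-CDS protein at a
site is scored against every family :class:`~phoscan.profiles.ProfileHMM`
and accepted when its forward bit score (log2 odds of the family model
over the i.i.d. background model, summed over all alignments) reaches
the configured threshold.  The per-site, per-family accepted-hit counts
form the :class:`HitTable` the normalization stage consumes.

Scoring defaults to local alignment with free flanking residues because
read-derived CDS are fragments of full-length proteins.  A Viterbi
(best-path) score is computed alongside for accepted hits; the forward
score always dominates it.  ``decoy_fdr`` estimates an empirical
false-hit rate from per-sequence shuffled decoys so users can calibrate
the bit threshold for their own data.

An optional adapter (:class:`PyhmmerEngine`) delegates profile build and
search to the HMMER implementation exposed by ``pyhmmer``; it emits a
``HitTable`` with the identical schema so every downstream stage is
engine-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .io import PhoscanError, ProteinRecord
from .profiles import AA_INDEX, N_AA, ProfileHMM

logger = logging.getLogger("phoscan")

_X_INDEX = N_AA  # X scored with unit odds (1/20 emission over 1/20 background)


class SearchError(PhoscanError):
    pass


@dataclass(frozen=True)
class Hit:
    """One accepted CDS-vs-family match."""

    site_id: str
    family_name: str
    cds_id: str
    bit_score: float  # forward log2 odds
    viterbi_bits: float  # best-path log2 odds
    accepted: bool


@dataclass
class HitTable:
    """Accepted hits and per-family counts for one site.

    One CDS contributes at most once to any single family's count (a
    single best score per sequence; no domain splitting), but may be
    counted by several families.
    """

    site_id: str
    counts: dict[str, int] = field(default_factory=dict)
    hits: list[Hit] = field(default_factory=list)

    def n(self, family: str) -> int:
        return self.counts.get(family, 0)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a protein string to integer indices (X -> index 20)."""
    if not sequence:
        raise SearchError("cannot score an empty sequence")
    idx = np.empty(len(sequence), dtype=np.int64)
    for i, ch in enumerate(sequence):
        if ch == "X":
            idx[i] = _X_INDEX
        else:
            try:
                idx[i] = AA_INDEX[ch]
            except KeyError:
                raise SearchError(
                    f"invalid residue {ch!r} at position {i + 1}"
                ) from None
    return idx


class ScoringProfile:
    """Precomputed log2-odds arrays for one profile (built once, reused)."""

    def __init__(self, profile: ProfileHMM):
        profile.validate()
        self.profile = profile
        q = profile.background
        with np.errstate(divide="ignore"):
            lem = np.log2(profile.match_emissions / q)
            lins = np.log2(profile.insert_emissions / q)
            self.t = tuple(
                np.log2(getattr(profile, name))
                for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
            )
        # extra row of zeros: X residues have unit odds everywhere;
        # stored transposed so odds() gathers (n, L) position-major arrays
        self.lem = np.ascontiguousarray(np.vstack([lem.T, np.zeros(profile.L)]))
        self.lins = np.ascontiguousarray(np.vstack([lins.T, np.zeros(profile.L + 1)]))

    def odds(self, seq_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.lem[seq_idx], self.lins[seq_idx]

    def score(self, seq_idx: np.ndarray, mode: str, viterbi: bool) -> float:
        lom, lins = self.odds(seq_idx)
        kernel = _dp.dp_local if mode == "local" else _dp.dp_global
        return float(kernel(lom, lins, *self.t, viterbi))


def forward_bits(profile: ProfileHMM, sequence: str, mode: str = "local") -> float:
    """log2( P(seq | profile, mode) / P(seq | background) ), summed over paths."""
    _check_mode(mode)
    sp = profile if isinstance(profile, ScoringProfile) else ScoringProfile(profile)
    return sp.score(encode_sequence(sequence), mode, viterbi=False)


def viterbi_bits(
    profile: ProfileHMM,
    sequence: str,
    mode: str = "local",
    return_path: bool = False,
):
    """Best single-path log2 odds; optionally also the traced state path.

    The path is a list of ``(state, node, seq_pos)`` with ``state`` in
    {"M", "I", "D"}; ``seq_pos`` is 1-based and 0 for delete states.
    """
    _check_mode(mode)
    sp = profile if isinstance(profile, ScoringProfile) else ScoringProfile(profile)
    seq_idx = encode_sequence(sequence)
    bits = sp.score(seq_idx, mode, viterbi=True)
    if not return_path:
        return bits
    return bits, _viterbi_path(sp, seq_idx, mode)


def _check_mode(mode: str) -> None:
    if mode not in ("local", "global"):
        raise SearchError(f"unknown alignment mode {mode!r}")


def _viterbi_path(sp: ScoringProfile, seq_idx: np.ndarray, mode: str):
    """Pure-python traceback (opt-in; the fast kernels return scores only)."""
    lom, lins = sp.odds(seq_idx)
    tmm, tmi, tmd, tim, tii, tdm, tdd = sp.t
    n, L = lom.shape
    NEG = -np.inf
    M = np.full((n + 1, L + 1), NEG)
    I = np.full((n + 1, L + 1), NEG)
    D = np.full((n + 1, L + 1), NEG)
    ptr: dict[tuple[str, int, int], tuple[str, int, int] | None] = {}
    if mode == "local":
        entry = -np.log2(L)
        for i in range(1, n + 1):
            for k in range(1, L + 1):
                options = [(entry, None)]
                if k > 1:
                    options += [
                        (M[i - 1, k - 1] + tmm[k - 1], ("M", k - 1, i - 1)),
                        (I[i - 1, k - 1] + tim[k - 1], ("I", k - 1, i - 1)),
                        (D[i - 1, k - 1] + tdm[k - 1], ("D", k - 1, i - 1)),
                    ]
                best, src = max(options, key=lambda t: t[0])
                M[i, k] = lom[i - 1, k - 1] + best
                ptr[("M", k, i)] = src
                if k < L:
                    opts = [
                        (M[i - 1, k] + tmi[k], ("M", k, i - 1)),
                        (I[i - 1, k] + tii[k], ("I", k, i - 1)),
                    ]
                    best, src = max(opts, key=lambda t: t[0])
                    I[i, k] = lins[i - 1, k] + best
                    ptr[("I", k, i)] = src
                if k > 1:
                    opts = [
                        (M[i, k - 1] + tmd[k - 1], ("M", k - 1, i)),
                        (D[i, k - 1] + tdd[k - 1], ("D", k - 1, i)),
                    ]
                    best, src = max(opts, key=lambda t: t[0])
                    D[i, k] = best
                    ptr[("D", k, i)] = src
        ends = [(M[i, k], ("M", k, i)) for i in range(1, n + 1) for k in range(1, L + 1)]
        _, state = max(ends, key=lambda t: t[0])
    else:
        M[0, 0] = 0.0
        ptr[("M", 0, 0)] = None
        for k in range(1, L + 1):
            src = ("M", 0, 0) if k == 1 else ("D", k - 1, 0)
            base = M[0, 0] + tmd[0] if k == 1 else D[0, k - 1] + tdd[k - 1]
            D[0, k] = base
            ptr[("D", k, 0)] = src
        for i in range(1, n + 1):
            for k in range(0, L + 1):
                if k > 0:
                    opts = [
                        (M[i - 1, k - 1] + tmm[k - 1], ("M", k - 1, i - 1)),
                        (I[i - 1, k - 1] + tim[k - 1], ("I", k - 1, i - 1)),
                        (D[i - 1, k - 1] + tdm[k - 1], ("D", k - 1, i - 1)),
                    ]
                    best, src = max(opts, key=lambda t: t[0])
                    M[i, k] = lom[i - 1, k - 1] + best
                    ptr[("M", k, i)] = src
                opts = [
                    (M[i - 1, k] + tmi[k], ("M", k, i - 1)),
                    (I[i - 1, k] + tii[k], ("I", k, i - 1)),
                ]
                best, src = max(opts, key=lambda t: t[0])
                I[i, k] = lins[i - 1, k] + best
                ptr[("I", k, i)] = src
                if k > 0:
                    opts = [(M[i, k - 1] + tmd[k - 1], ("M", k - 1, i))]
                    if k > 1:
                        opts.append((D[i, k - 1] + tdd[k - 1], ("D", k - 1, i)))
                    best, src = max(opts, key=lambda t: t[0])
                    D[i, k] = best
                    ptr[("D", k, i)] = src
        ends = [
            (M[n, L] + tmm[L], ("M", L, n)),
            (I[n, L] + tim[L], ("I", L, n)),
            (D[n, L] + tdm[L], ("D", L, n)),
        ]
        _, state = max(ends, key=lambda t: t[0])
    path = []
    while state is not None and state != ("M", 0, 0):
        kind, k, i = state
        path.append((kind, k, i if kind != "D" else 0))
        state = ptr.get(state)
    path.reverse()
    return path


# ---------------------------------------------------------------------------
# site screening

def search_site(
    profiles,
    cds: list[ProteinRecord],
    threshold: float,
    site_id: str,
    mode: str = "local",
) -> HitTable:
    """Score every CDS against every profile and tally accepted hits.

    ``profiles`` is a list of :class:`ProfileHMM` (or prebuilt
    :class:`ScoringProfile`).  A CDS is accepted for a family when its
    forward bit score reaches ``threshold``; the Viterbi score is filled
    in for accepted hits.
    """
    if not profiles:
        raise SearchError("search_site needs at least one profile")
    _check_mode(mode)
    sps = [p if isinstance(p, ScoringProfile) else ScoringProfile(p) for p in profiles]
    table = HitTable(site_id=site_id)
    for sp in sps:
        table.counts[sp.profile.family_name] = 0
    encoded = [(rec.id, encode_sequence(rec.sequence)) for rec in cds]
    for sp in sps:
        fam = sp.profile.family_name
        for cds_id, seq_idx in encoded:
            fwd = sp.score(seq_idx, mode, viterbi=False)
            if fwd >= threshold:
                vit = sp.score(seq_idx, mode, viterbi=True)
                table.counts[fam] += 1
                table.hits.append(
                    Hit(site_id, fam, cds_id, float(fwd), float(vit), True)
                )
    logger.debug("site %s: %s", site_id, table.counts)
    return table


def shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    chars = list(sequence)
    rng.shuffle(chars)
    return "".join(chars)


def decoy_fdr(
    profile: ProfileHMM,
    cds: list[ProteinRecord],
    threshold: float,
    seed: int = 0,
    n_shuffles: int = 1,
    mode: str = "local",
) -> float:
    """Fraction of per-sequence shuffled decoys scoring at or above threshold.

    Each input CDS yields ``n_shuffles`` residue-shuffled decoys
    (composition preserved, order destroyed); the returned rate
    estimates the false-hit probability at the given bit threshold.
    """
    if not cds:
        raise SearchError("decoy_fdr needs a non-empty CDS list")
    if threshold == -np.inf:
        return 1.0
    if threshold == np.inf:
        return 0.0
    rng = np.random.default_rng(seed)
    sp = ScoringProfile(profile)
    above = 0
    total = 0
    for rec in cds:
        for _ in range(n_shuffles):
            decoy = shuffle_sequence(rec.sequence, rng)
            total += 1
            if sp.score(encode_sequence(decoy), mode, viterbi=False) >= threshold:
                above += 1
    return above / total


def hit_table_rows(table: HitTable) -> list[dict]:
    """Flatten a HitTable for TSV output."""
    return [
        {
            "site_id": h.site_id,
            "family": h.family_name,
            "cds_id": h.cds_id,
            "bit_score": h.bit_score,
            "viterbi_bits": h.viterbi_bits,
            "accepted": h.accepted,
        }
        for h in table.hits
    ]


# ---------------------------------------------------------------------------
# optional external engine

class PyhmmerEngine:
    """Adapter that scores with the HMMER implementation in ``pyhmmer``.

    Profiles are built from the same family alignments with
    ``pyhmmer.plan7.Builder`` and searched with the standard HMMER
    pipeline (bias/E-value heuristics disabled in favour of a plain bit
    threshold).  The result is a :class:`HitTable` with the identical
    schema, so the normalization, comparison and taxonomy stages do not
    know which engine produced it.  HMMER reports a single per-sequence
    bit score; it fills both score fields.
    """

    def __init__(self):
        try:
            import pyhmmer  # noqa: F401
        except ImportError as exc:  # pragma: no cover - env without pyhmmer
            raise SearchError(
                "PyhmmerEngine requires the optional dependency 'pyhmmer'"
            ) from exc
        self._pyhmmer = pyhmmer
        self.alphabet = pyhmmer.easel.Alphabet.amino()

    def build(self, family_name: str, alignment) -> "object":
        """Build a plan7 HMM from AlignmentRecords."""
        pyhmmer = self._pyhmmer
        seqs = [
            pyhmmer.easel.TextSequence(
                name=rec.id.encode(), sequence=rec.aligned_sequence
            )
            for rec in alignment
        ]
        msa = pyhmmer.easel.TextMSA(
            name=family_name.encode(), sequences=seqs
        ).digitize(self.alphabet)
        builder = pyhmmer.plan7.Builder(self.alphabet)
        hmm, _, _ = builder.build_msa(msa, pyhmmer.plan7.Background(self.alphabet))
        return hmm

    def search_site(
        self,
        alignments: dict[str, list],
        cds: list[ProteinRecord],
        threshold: float,
        site_id: str,
    ) -> HitTable:
        pyhmmer = self._pyhmmer
        table = HitTable(site_id=site_id)
        targets = pyhmmer.easel.TextSequenceBlock(
            [
                pyhmmer.easel.TextSequence(name=r.id.encode(), sequence=r.sequence)
                for r in cds
            ]
        ).digitize(self.alphabet)
        for fam, alignment in alignments.items():
            table.counts[fam] = 0
            hmm = self.build(fam, alignment)
            pipeline = pyhmmer.plan7.Pipeline(
                self.alphabet, T=threshold, bias_filter=False
            )
            for hit in pipeline.search_hmm(hmm, targets):
                if hit.score >= threshold:
                    name = hit.name
                    if isinstance(name, bytes):
                        name = name.decode()
                    table.counts[fam] += 1
                    table.hits.append(
                        Hit(site_id, fam, name, float(hit.score),
                            float(hit.score), True)
                    )
        return table
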