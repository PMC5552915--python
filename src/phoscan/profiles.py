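"""Profile hidden Markov models built from family alignments.

A :class:`ProfileHMM` is the screening instrument: a position-specific
match/insert/delete-state model of one protein family, estimated from a
multiple alignment of curated reference sequences.  Columns whose
non-gap occupancy reaches a threshold (default 0.5) become match states;
residues in the remaining columns are treated as insertions and gaps in
match columns as deletions.  Emissions and transitions are smoothed with
a background-weighted Laplace pseudocount (total weight 1 by default),
so every probability is strictly positive and small worked examples stay
hand-checkable.

The model also carries ``reference_length`` — the representative length
(in amino acids) of the family's reference proteins, which the
normalization stage uses to form the RecA length ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import AMINO_ACIDS, GAP, AlignmentRecord, PhoscanError, ProteinRecord

N_AA = len(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: uniform amino-acid background; overridable per profile
UNIFORM_BACKGROUND = np.full(N_AA, 1.0 / N_AA)

_TOL = 1e-9


class ProfileError(PhoscanError):
    """Invalid alignment or profile."""


@dataclass
class ProfileHMM:
    """Match/insert/delete profile HMM over the 20-letter protein alphabet.

    Transition arrays all have length ``L + 1`` and are indexed by node,
    where node 0 is the begin state and node ``L`` the last match state:

    ``t_mm[k]``
        M_k -> M_{k+1} for k < L (M_0 = Begin); ``t_mm[L]`` is M_L -> End.
    ``t_mi[k]``
        M_k -> I_k.
    ``t_md[k]``
        M_k -> D_{k+1} for k < L; ``t_md[L]`` = 0 (no delete after the end).
    ``t_im[k]`` / ``t_ii[k]``
        I_k -> M_{k+1} (or End at k = L) / I_k self-loop.
    ``t_dm[k]`` / ``t_dd[k]``
        D_k -> M_{k+1} (or End at k = L) / D_k -> D_{k+1}; node 0 unused.
    """

    family_name: str
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (L + 1, 20)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    background: np.ndarray  # (20,)
    reference_length: int

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        L = self.L
        if L < 1:
            raise ProfileError("profile must have at least one match state")
        if self.reference_length < 1:
            raise ProfileError("reference_length must be >= 1")
        shapes = {
            "match_emissions": (L, N_AA),
            "insert_emissions": (L + 1, N_AA),
            "background": (N_AA,),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ProfileError(f"{name} has shape {arr.shape}, expected {shape}")
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            arr = getattr(self, name)
            if arr.shape != (L + 1,):
                raise ProfileError(f"{name} has shape {arr.shape}, expected ({L + 1},)")
            if np.any(arr < -_TOL):
                raise ProfileError(f"{name}: negative probability")
        rows = np.vstack([self.match_emissions, self.insert_emissions,
                          self.background[None, :]])
        if np.any(np.abs(rows.sum(axis=1) - 1.0) > _TOL):
            raise ProfileError("an emission row does not sum to 1")
        m_rows = self.t_mm + self.t_mi + self.t_md
        i_rows = self.t_im + self.t_ii
        d_rows = (self.t_dm + self.t_dd)[1:]
        for name, sums in (("M", m_rows), ("I", i_rows), ("D", d_rows)):
            if np.any(np.abs(sums - 1.0) > _TOL):
                raise ProfileError(f"a {name}-state transition row does not sum to 1")
        if abs(self.t_md[L]) > _TOL or abs(self.t_dd[L]) > _TOL:
            raise ProfileError("t_md and t_dd must be 0 at the last node")

    def consensus(self) -> str:
        """Most probable residue at each match state."""
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))

    # ----- serialization ----------------------------------------------
    def to_json(self, path: str | Path) -> None:
        data = {
            "family_name": self.family_name,
            "L": self.L,
            "reference_length": int(self.reference_length),
            "alphabet": AMINO_ACIDS,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": {
                name: getattr(self, name).tolist()
                for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
            },
            "background": self.background.tolist(),
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wt") as out:
            json.dump(data, out)

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        with open(path) as handle:
            data = json.load(handle)
        if data.get("alphabet") != AMINO_ACIDS:
            raise ProfileError(f"profile {path}: unexpected alphabet")
        tr = data["transitions"]
        prof = cls(
            family_name=data["family_name"],
            match_emissions=np.asarray(data["match_emissions"], dtype=float),
            insert_emissions=np.asarray(data["insert_emissions"], dtype=float),
            background=np.asarray(data["background"], dtype=float),
            reference_length=int(data["reference_length"]),
            **{name: np.asarray(tr[name], dtype=float)
               for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")},
        )
        prof.validate()
        return prof


# ---------------------------------------------------------------------------
# construction

def assign_match_columns(
    alignment: list[AlignmentRecord], occupancy_threshold: float = 0.5
) -> list[int]:
    """0-based indices of columns whose non-gap fraction meets the threshold."""
    if not alignment:
        raise ProfileError("empty alignment")
    if not 0.0 < occupancy_threshold <= 1.0:
        raise ProfileError(
            f"occupancy_threshold must be in (0, 1], got {occupancy_threshold}"
        )
    n_rows = len(alignment)
    n_cols = len(alignment[0].aligned_sequence)
    occupancy = np.zeros(n_cols)
    for rec in alignment:
        occupancy += np.array([c != GAP for c in rec.aligned_sequence], dtype=float)
    occupancy /= n_rows
    cols = [i for i in range(n_cols) if occupancy[i] >= occupancy_threshold - _TOL]
    if not cols:
        raise ProfileError(
            f"no column reaches occupancy {occupancy_threshold} "
            f"(maximum is {occupancy.max():.3f}); lower the threshold"
        )
    return cols


def reference_length(records, statistic: str = "median") -> int:
    """Representative ungapped length of a family's reference sequences.

    ``statistic`` is ``median`` (default) or ``mean``; the result is
    rounded half-up to an integer number of amino acids.
    """
    records = list(records)
    if not records:
        raise ProfileError("reference_length of an empty record list")
    lengths = []
    for rec in records:
        if isinstance(rec, AlignmentRecord):
            lengths.append(len(rec.ungapped))
        elif isinstance(rec, ProteinRecord):
            lengths.append(len(rec.sequence))
        else:
            lengths.append(int(rec))
    if statistic == "median":
        value = float(np.median(lengths))
    elif statistic == "mean":
        value = float(np.mean(lengths))
    else:
        raise ProfileError(f"unknown statistic {statistic!r}")
    return int(math.floor(value + 0.5))


def _smooth(counts: np.ndarray, weights: np.ndarray, pseudocount: float) -> np.ndarray:
    """(counts + pseudocount * weights) / (counts.sum() + pseudocount)."""
    return (counts + pseudocount * weights) / (counts.sum() + pseudocount)


def build_profile(
    alignment: list[AlignmentRecord],
    occupancy_threshold: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    family_name: str = "",
    reference_statistic: str = "median",
) -> ProfileHMM:
    """Estimate a :class:`ProfileHMM` from a family alignment.

    Match emission for residue r at state k is
    ``(count of r in column k + pseudocount * q_r) / (non-gap count + pseudocount)``;
    insert emissions equal the background.  Transition probabilities come
    from the observed per-sequence state paths (gap in a match column ->
    delete, residue in a non-match column -> insert), smoothed with the
    same pseudocount spread uniformly over each state's allowed moves.
    ``X`` residues count for state-path purposes but not for emissions.
    """
    if pseudocount <= 0:
        raise ProfileError("pseudocount must be > 0")
    q = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if q.shape != (N_AA,) or abs(q.sum() - 1.0) > 1e-6 or np.any(q <= 0):
        raise ProfileError("background must be 20 positive probabilities summing to 1")

    match_cols = assign_match_columns(alignment, occupancy_threshold)
    L = len(match_cols)
    n_cols = len(alignment[0].aligned_sequence)
    # node index for every column: match columns are nodes 1..L; an insert
    # column belongs to the node of the last match column before it.
    col_node = np.zeros(n_cols, dtype=int)
    is_match = np.zeros(n_cols, dtype=bool)
    node = 0
    match_set = set(match_cols)
    for c in range(n_cols):
        if c in match_set:
            node += 1
            is_match[c] = True
        col_node[c] = node

    em_counts = np.zeros((L, N_AA))
    # transition count rows per node: M -> {M, I, D}, I -> {M, I}, D -> {M, D}
    cm = np.zeros((L + 1, 3))
    ci = np.zeros((L + 1, 2))
    cd = np.zeros((L + 1, 2))

    for rec in alignment:
        seq = rec.aligned_sequence
        # previous visited core state, starting at Begin (an M at node 0)
        prev_kind, prev_node = "M", 0
        for c in range(n_cols):
            ch = seq[c]
            if is_match[c]:
                k = col_node[c]
                if ch == GAP:
                    kind = "D"
                else:
                    kind = "M"
                    if ch != "X":
                        em_counts[k - 1, AA_INDEX[ch]] += 1
            else:
                if ch == GAP:
                    continue
                kind, k = "I", col_node[c]
            _count_transition(cm, ci, cd, prev_kind, prev_node, kind, k)
            prev_kind, prev_node = kind, k
        _count_transition(cm, ci, cd, prev_kind, prev_node, "M", L + 1)  # -> End

    match_emissions = np.empty((L, N_AA))
    for k in range(L):
        match_emissions[k] = _smooth(em_counts[k], q, pseudocount)
    insert_emissions = np.tile(q, (L + 1, 1))

    t_mm = np.zeros(L + 1); t_mi = np.zeros(L + 1); t_md = np.zeros(L + 1)
    t_im = np.zeros(L + 1); t_ii = np.zeros(L + 1)
    t_dm = np.zeros(L + 1); t_dd = np.zeros(L + 1)
    for k in range(L + 1):
        if k < L:
            m = _smooth(cm[k], np.full(3, 1 / 3), pseudocount)
            t_mm[k], t_mi[k], t_md[k] = m
        else:  # last node: no delete continuation
            m = _smooth(cm[k, :2], np.full(2, 1 / 2), pseudocount)
            t_mm[k], t_mi[k] = m
        i = _smooth(ci[k], np.full(2, 1 / 2), pseudocount)
        t_im[k], t_ii[k] = i
        if 1 <= k < L:
            d = _smooth(cd[k], np.full(2, 1 / 2), pseudocount)
            t_dm[k], t_dd[k] = d
        elif k == L:
            t_dm[k] = 1.0  # D_L can only exit
    t_dm[0] = 1.0  # node-0 delete row is unused

    ref_len = reference_length(alignment, reference_statistic)
    prof = ProfileHMM(
        family_name=family_name,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        background=q.copy(),
        reference_length=ref_len,
    )
    prof.validate()
    return prof


def _count_transition(cm, ci, cd, prev_kind, prev_node, kind, node) -> None:
    """Tally one observed transition into the per-node count rows."""
    if prev_kind == "M":
        row = cm[prev_node]
        if kind == "M":
            row[0] += 1
        elif kind == "I":
            row[1] += 1
        else:
            row[2] += 1
    elif prev_kind == "I":
        row = ci[prev_node]
        row[0 if kind == "M" else 1] += 1
    else:  # D
        row = cd[prev_node]
        row[0 if kind == "M" else 1] += 1
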