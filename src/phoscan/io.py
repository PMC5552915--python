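"""Reading and writing of external formats.

All file I/O in the package goes through this module: protein FASTA
(plain and gzip), aligned FASTA and Stockholm alignments, and the
tab-separated tables every downstream stage emits.  Parsing is strict:
sequences must be over the 20 standard amino acids plus ``X`` (the
ambiguity code read-derived CDS actually contain); ``B``, ``Z``, ``U``
and ``J`` are rejected with a message naming the record and position so
that the scoring engine never has to handle them.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("phoscan")

#: canonical amino-acid alphabet, alphabetical one-letter codes
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: alphabet accepted in sequences (X = unknown residue, scored as 1/20 uniform)
SEQUENCE_ALPHABET = AMINO_ACIDS + "X"
GAP = "-"


class PhoscanError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PhoscanError):
    """Malformed or invalid input file."""


@dataclass(frozen=True)
class ProteinRecord:
    """One unaligned protein sequence.

    ``description`` is free text after the id on the FASTA header line;
    for taxonomy reference databases it embeds a lineage string (see
    :mod:`phoscan.taxonomy`).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence):
            if ch not in SEQUENCE_ALPHABET:
                raise FormatError(
                    f"record {self.id!r}: invalid character {ch!r} at position "
                    f"{pos + 1} (allowed: 20 amino acids and X)"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One row of a multiple alignment ('-' is the gap symbol)."""

    id: str
    aligned_sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("alignment record with empty id")
        ungapped = self.aligned_sequence.replace(GAP, "")
        if not ungapped:
            raise FormatError(f"alignment record {self.id!r}: all-gap row")
        for pos, ch in enumerate(self.aligned_sequence):
            if ch != GAP and ch not in SEQUENCE_ALPHABET:
                raise FormatError(
                    f"alignment record {self.id!r}: invalid character {ch!r} "
                    f"at column {pos + 1}"
                )

    @property
    def ungapped(self) -> str:
        return self.aligned_sequence.replace(GAP, "")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _normalize_sequence(raw: str) -> str:
    """Uppercase and strip trailing stop symbols ('*')."""
    return str(raw).upper().rstrip("*")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved; lowercase residues are uppercased and terminal
    ``*`` stop symbols stripped.  Duplicate ids, empty files and
    non-amino-acid characters are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate id: {rec.id}")
            seen.add(rec.id)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            seq = _normalize_sequence(str(rec.seq))
            if GAP in seq or "." in seq:
                raise FormatError(
                    f"record {rec.id!r}: gap character in unaligned FASTA"
                )
            records.append(ProteinRecord(rec.id, seq, desc))
    if not records:
        raise FormatError(f"empty FASTA file: {path}")
    return records


def read_cds_set(paths: Sequence[str | Path]) -> list[ProteinRecord]:
    """Read and pool one site's CDS FASTA files.

    A site's CDS set is the union of all files listed for it; an id that
    recurs across files gets a ``.f<index>`` suffix so records stay
    distinguishable (within one file duplicates remain an error).
    """
    pooled: list[ProteinRecord] = []
    seen: set[str] = set()
    for idx, p in enumerate(paths):
        for rec in read_fasta(p):
            rid = rec.id
            if rid in seen:
                rid = f"{rec.id}.f{idx}"
            seen.add(rid)
            pooled.append(ProteinRecord(rid, rec.sequence, rec.description))
    return pooled


def _looks_like_stockholm(path: Path) -> bool:
    with _open_text(path) as handle:
        first = handle.readline()
    return first.startswith("# STOCKHOLM")


def read_alignment(path: str | Path) -> list[AlignmentRecord]:
    """Read a multiple alignment from aligned FASTA or Stockholm.

    '.' gaps are normalized to '-'; all rows must have equal length.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = "stockholm" if _looks_like_stockholm(path) else "fasta"
    rows: list[AlignmentRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            if rec.id in seen:
                raise FormatError(f"duplicate id: {rec.id}")
            seen.add(rec.id)
            aligned = str(rec.seq).upper().replace(".", GAP).replace("*", GAP)
            rows.append(AlignmentRecord(rec.id, aligned))
    if not rows:
        raise FormatError(f"empty alignment file: {path}")
    length = len(rows[0].aligned_sequence)
    for rec in rows[1:]:
        if len(rec.aligned_sequence) != length:
            raise FormatError(
                f"ragged alignment: {length} vs {len(rec.aligned_sequence)}"
            )
    return rows


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as plain FASTA (60-column wrapped)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt") as out:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                out.write(rec.sequence[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# tabular output

#: float format used for every TSV the pipeline writes; 10 significant
#: digits so that write -> read round-trips to well under 1e-9 relative.
FLOAT_FORMAT = "%.10g"


def _row_fields(row) -> tuple:
    if isinstance(row, dict):
        return tuple(row.keys())
    return tuple(f.name for f in row.__dataclass_fields__.values())  # type: ignore[attr-defined]


def write_table(rows, path: str | Path, fieldnames: Sequence[str] | None = None) -> None:
    """Write uniform records (dicts, dataclasses or a DataFrame) as TSV.

    Header line plus one row per record, input order preserved.  All rows
    must share one field set.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(rows, pd.DataFrame):
        rows.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        return
    rows = list(rows)
    if rows:
        fields = _row_fields(rows[0])
        for r in rows[1:]:
            if _row_fields(r) != fields:
                raise PhoscanError(
                    f"heterogeneous rows: {fields} vs {_row_fields(r)}"
                )
        dicts = [r if isinstance(r, dict) else r.__dict__ for r in rows]
        frame = pd.DataFrame(dicts)
    else:
        if fieldnames is None:
            raise PhoscanError("empty row list needs explicit fieldnames")
        frame = pd.DataFrame(columns=list(fieldnames))
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def setup_logging(verbose: bool = False) -> None:
    """Configure stderr logging for CLI runs."""
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%H:%M:%S",
    )
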