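"""Sequence and table I/O plus the input-cleaning rules applied to raw ESTs.

ESTs arrive as DNA, reference mature miRNAs as RNA (miRBase convention).
Everything downstream compares sequences on a single canonical DNA-like
alphabet (U -> T), so both kinds of input interoperate directly.
"""

from __future__ import annotations

import dataclasses
import typing
from dataclasses import dataclass, fields
from pathlib import Path

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALLOWED_CHARS = frozenset("ACGTUN")

#: reason tags attached by :func:`clean_sequences`
TOO_LONG = "too_long"
BAD_ALPHABET = "bad_alphabet"


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (e.g. sequence data before a header)."""


class DuplicateIdError(ValueError):
    """Raised when a FASTA file contains the same record id twice."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (EST, transcript or mature miRNA)."""

    id: str
    seq: str
    description: str = ""
    alphabet_hint: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def canonical(self) -> str:
        """Sequence with U mapped to T, the pipeline's comparison alphabet."""
        return self.seq.replace("U", "T")


def read_fasta(path: str | Path, alphabet_hint: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into an ordered list of :class:`SequenceRecord`.

    The first whitespace-delimited header token is the id; the remainder is
    kept as the description. Sequences are upper-cased. Duplicate ids raise
    :class:`DuplicateIdError`; sequence data before any header raises
    :class:`FastaFormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        # Bio.SeqIO silently tolerates leading junk; reject it explicitly.
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: sequence data before first FASTA header"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(
                id=rec.id, seq=str(rec.seq), description=desc,
                alphabet_hint=alphabet_hint,
            )
        )
    return records


def write_fasta(records: typing.Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


@dataclass(frozen=True)
class RejectedRecord:
    record: SequenceRecord
    reason: str  # TOO_LONG | BAD_ALPHABET


def clean_sequences(
    records: typing.Iterable[SequenceRecord], max_len: int = 3000,
) -> tuple[list[SequenceRecord], list[RejectedRecord]]:
    """Partition records by the study's inclusion rules.

    A record is rejected iff it is longer than ``max_len`` nucleotides
    (exactly ``max_len`` is kept) or contains a character outside
    {A, C, G, T, U, N}. Returns ``(kept, rejected)``; the union is always
    exactly the input.
    """
    kept: list[SequenceRecord] = []
    rejected: list[RejectedRecord] = []
    for rec in records:
        if len(rec.seq) > max_len:
            rejected.append(RejectedRecord(rec, TOO_LONG))
        elif not set(rec.seq) <= ALLOWED_CHARS:
            rejected.append(RejectedRecord(rec, BAD_ALPHABET))
        else:
            kept.append(rec)
    return kept, rejected


# ---------------------------------------------------------------------------
# Generic dataclass <-> TSV round-tripping for result tables
# ---------------------------------------------------------------------------

def _format_cell(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (list, tuple)):
        return ",".join(str(v) for v in value)
    return str(value)


def write_table(rows: typing.Sequence, path: str | Path,
                row_type: type | None = None) -> None:
    """Write dataclass rows as a TSV with a header line.

    All rows must share one dataclass type. ``row_type`` is required only
    for an empty collection (to emit the header).
    """
    rows = list(rows)
    if rows:
        row_type = type(rows[0])
    if row_type is None or not dataclasses.is_dataclass(row_type):
        raise ValueError("write_table needs dataclass rows or an explicit row_type")
    names = [f.name for f in fields(row_type)]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for row in rows:
            if type(row) is not row_type:
                raise ValueError("write_table rows must share one schema")
            fh.write("\t".join(_format_cell(getattr(row, n)) for n in names) + "\n")


def _parse_cell(text: str, ftype: object):
    origin = typing.get_origin(ftype)
    if origin is typing.Union:  # Optional[...]
        args = [a for a in typing.get_args(ftype) if a is not type(None)]
        if text == "NA":
            return None
        return _parse_cell(text, args[0])
    if text == "NA":
        return None
    if ftype is bool or ftype == "bool":
        return text == "true"
    if ftype is int or ftype == "int":
        return int(text)
    if ftype is float or ftype == "float":
        return float(text)
    if origin in (list, tuple) or ftype in ("list[str]", "tuple[str, ...]"):
        if text == "":
            return () if origin is tuple else []
        parts = text.split(",")
        inner = typing.get_args(ftype)
        if inner:
            parts = [_parse_cell(p, inner[0]) for p in parts]
        return tuple(parts) if origin is tuple else parts
    return text


def read_table(path: str | Path, row_type: type) -> list:
    """Read a TSV written by :func:`write_table` back into dataclass rows."""
    hints = typing.get_type_hints(row_type)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            kwargs = {
                name: _parse_cell(cell, hints[name])
                for name, cell in zip(header, cells)
            }
            rows.append(row_type(**kwargs))
    return rows
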