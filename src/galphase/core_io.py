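"""Typed records and file I/O for sequences and per-residue disorder tracks.

The pipeline works on plain multi-record FASTA files and on disorder-score
tracks in the tab-separated ``POS  RES  SCORE`` layout emitted by common
per-residue disorder predictors (``#``-prefixed comment lines are ignored).
Residue positions are 1-based inclusive everywhere in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids plus X for unknown/ambiguous residues.
ALLOWED_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Malformed input file (FASTA or track syntax, illegal characters)."""


class AlignmentError(ValueError):
    """A disorder track does not line up with its protein sequence."""


class SchemaError(ValueError):
    """Rows passed to a table writer do not share one key set."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with an identifier.

    ``sequence`` is upper-case, whitespace-free, and restricted to the
    20 canonical residue letters plus ``X``.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in ALLOWED_ALPHABET:
                raise FormatError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder scores aligned 1:1 to a :class:`ProteinRecord`."""

    record_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        for pos, s in enumerate(self.scores, start=1):
            if not (0.0 <= s <= 1.0):
                raise ValueError(
                    f"track {self.record_id!r}: score {s} at position {pos} "
                    "outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.scores)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file, preserving record order.

    Sequences are whitespace-stripped and upper-cased.  Raises
    :class:`FormatError` on an empty file, an empty sequence, or a
    character outside the canonical-plus-X alphabet.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq,
                                     description=rec.description))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seqrecs)


def read_disorder_track(path: str | Path, record: ProteinRecord) -> DisorderTrack:
    """Parse a ``POS RES SCORE`` disorder-track file for ``record``.

    Lines starting with ``#`` are comments.  The residue column, when
    present, is cross-checked against ``record.sequence``; a mismatch in
    length or letter raises :class:`AlignmentError`, a score outside
    [0, 1] raises :class:`ValueError`.
    """
    path = Path(path)
    scores: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected POS RES SCORE columns")
            if len(parts) == 2:  # POS SCORE layout, no residue column
                pos_s, res, score_s = parts[0], None, parts[1]
            else:
                pos_s, res, score_s = parts[0], parts[1], parts[2]
            try:
                pos = int(pos_s)
                score = float(score_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if pos != len(scores) + 1:
                raise AlignmentError(
                    f"{path}:{lineno}: position {pos}, expected {len(scores) + 1}"
                )
            if not (0.0 <= score <= 1.0):
                raise ValueError(
                    f"{path}:{lineno}: score {score} outside [0, 1]"
                )
            if res is not None:
                if pos > len(record.sequence):
                    raise AlignmentError(
                        f"{path}:{lineno}: position {pos} beyond sequence "
                        f"length {len(record.sequence)}"
                    )
                expected = record.sequence[pos - 1]
                if res.upper() != expected:
                    raise AlignmentError(
                        f"{path}:{lineno}: residue {res!r} at position {pos} "
                        f"does not match sequence letter {expected!r}"
                    )
            scores.append(score)
    if len(scores) != len(record.sequence):
        raise AlignmentError(
            f"{path}: {len(scores)} scores for {len(record.sequence)}-residue "
            f"record {record.id!r}"
        )
    return DisorderTrack(record_id=record.id, scores=tuple(scores))


def write_disorder_track(track: DisorderTrack, record: ProteinRecord,
                         path: str | Path) -> None:
    """Write a track in the ``# header`` + ``POS\\tRES\\tSCORE`` layout."""
    if len(track) != len(record):
        raise AlignmentError(
            f"track length {len(track)} != sequence length {len(record)}"
        )
    with open(path, "w") as fh:
        fh.write(f"# disorder track for {record.id}\n# POS\tRES\tSCORE\n")
        for i, score in enumerate(track.scores):
            fh.write(f"{i + 1}\t{record.sequence[i]}\t{score:.6f}\n")


def write_table(rows: Sequence[dict[str, Any]], path: str | Path,
                fmt: str = "tsv", columns: Sequence[str] | None = None) -> None:
    """Write keyed rows as TSV or JSON with a deterministic column order.

    All rows must share one key set (:class:`SchemaError` otherwise).
    Columns are alphabetical unless ``columns`` gives an explicit order.
    An empty row list with explicit ``columns`` yields a header-only TSV.
    """
    if fmt not in ("tsv", "json"):
        raise ValueError(f"unknown format {fmt!r}")
    rows = list(rows)
    if rows:
        keys = set(rows[0])
        for i, row in enumerate(rows):
            if set(row) != keys:
                raise SchemaError(f"row {i} keys {sorted(row)} != {sorted(keys)}")
        cols = list(columns) if columns is not None else sorted(keys)
        if set(cols) != keys:
            raise SchemaError(f"column list {cols} does not match row keys")
    else:
        cols = list(columns) if columns is not None else []

    path = Path(path)
    if fmt == "json":
        payload = [{k: row[k] for k in cols} for row in rows]
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(row[k]) for k in cols) + "\n")


def _format_cell(value: Any) -> str:
    if isinstance(value, float):
        return repr(value)  # shortest round-trippable representation
    return str(value)
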