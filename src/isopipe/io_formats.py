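"""Readers and writers for every on-disk format the pipeline touches.

This module is the single source of truth for coordinate conventions:
internally all coordinates are 0-based half-open; every file emitted here
carries 1-based inclusive coordinates, matching BLAST tabular and GFF
practice.  Minus-strand alignments in tabular files are encoded by
``s_start > s_end``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SeqRecord:
    """A named DNA sequence with optional phred qualities.

    Sequences are stored uppercase; the alphabet is restricted to A/C/G/T/N.
    """

    id: str
    sequence: str
    quality: list[int] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-DNA characters {sorted(bad)!r}"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HSPRecord:
    """One local-alignment block (high-scoring segment pair).

    Coordinates are 1-based inclusive as in BLAST tabular output; the query
    is always forward (``q_start <= q_end``) while ``s_start > s_end``
    denotes a minus-strand subject alignment.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ParseError(
                f"HSP {self.query_id}/{self.subject_id}: q_start > q_end"
            )

    @property
    def minus_strand(self) -> bool:
        return self.s_start > self.s_end


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a (possibly gzipped) FASTA file.

    Multi-line sequences are joined and uppercased.  A header without a
    following sequence, or sequence lines before the first header, raise
    :class:`ParseError` naming the offending line number.
    """
    with _open_text(path) as handle:
        header: str | None = None
        header_line = 0
        chunks: list[str] = []
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    if not chunks:
                        raise ParseError(
                            f"{path}:{header_line}: header {header!r} has no sequence"
                        )
                    yield _fasta_record(header, chunks)
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(line)
        if header is not None:
            if not chunks:
                raise ParseError(
                    f"{path}:{header_line}: header {header!r} has no sequence"
                )
            yield _fasta_record(header, chunks)


def _fasta_record(header: str, chunks: list[str]) -> SeqRecord:
    fields = header.split(None, 1)
    desc = fields[1] if len(fields) > 1 else ""
    return SeqRecord(id=fields[0], sequence="".join(chunks), description=desc)


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream 4-line FASTQ records with phred+33 qualities decoded."""
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {title!r}: sequence/quality length mismatch"
                    )
                fields = title.split(None, 1)
                yield SeqRecord(
                    id=fields[0],
                    sequence=seq,
                    quality=[ord(c) - 33 for c in qual],
                    description=fields[1] if len(fields) > 1 else "",
                )
        except ValueError as exc:  # Biopython signals malformed records
            raise ParseError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            handle.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            qual = rec.quality
            if qual is None:
                qual = [30] * len(rec.sequence)
            handle.write(
                f"@{rec.id}\n{rec.sequence}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )


_HSP_COLUMNS = 12


def read_hsp_table(path: str | Path) -> list[HSPRecord]:
    """Parse a 12-column BLAST-style tabular alignment file.

    Lines starting with ``#`` are comments.  Any other line with a column
    count other than 12 raises :class:`ParseError` with its line number.
    """
    hsps: list[HSPRecord] = []
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _HSP_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_HSP_COLUMNS} columns, got {len(cols)}"
                )
            try:
                hsps.append(
                    HSPRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=float(cols[2]),
                        aln_len=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hsps


def write_hsp_table(hsps: Iterable[HSPRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for h in hsps:
            handle.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.pct_identity,
                        h.aln_len,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        h.evalue,
                        h.bitscore,
                    )
                )
                + "\n"
            )


def write_feature_table(
    rows: Iterable[Sequence],
    columns: Sequence[str],
    path: str | Path,
) -> None:
    """Write a tab-separated feature/summary table with a ``#`` header line.

    Callers are responsible for converting internal 0-based half-open
    coordinates to 1-based inclusive before passing rows; the helpers
    :func:`to_one_based` / :func:`from_one_based` do the arithmetic.
    """
    with _open_text(path, "wt") as handle:
        handle.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            handle.write("\t".join(str(v) for v in row) + "\n")


def read_feature_table(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read back a table written by :func:`write_feature_table`."""
    with _open_text(path) as handle:
        header = handle.readline()
        if not header.startswith("#"):
            raise ParseError(f"{path}:1: missing '#' header line")
        columns = header[1:].rstrip("\n").split("\t")
        rows = [
            line.rstrip("\n").split("\t")
            for line in handle
            if line.strip()
        ]
    return columns, rows


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive (start+1, end)."""
    return start0 + 1, end0


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1
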