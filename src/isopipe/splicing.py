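"""Reference-free alternative-splicing detection from pairwise alignments.

Without a genome, an exon-skipping event between two transcripts of the
same gene leaves a distinctive signature in their pairwise local
alignment: exactly two HSPs of the same orientation, where one transcript
(the *continuous* side) is covered almost end to end with the HSPs nearly
abutting (inter-HSP distance strictly smaller than 5 bp, negative values
being a small overlap), while the other (the *gapped* side) shows an "AS
gap" strictly larger than 100 bp between the HSPs, at least 100 bp away
from both of its ends.

The all-vs-all alignment step runs through the NCBI BLAST+ command line
(``makeblastdb``/``blastn``); precomputed 12-column tabular files are
accepted interchangeably via :func:`isopipe.io_formats.read_hsp_table`.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import HSPRecord, SeqRecord, read_hsp_table, write_fasta


@dataclass
class ASEvent:
    continuous_id: str
    gapped_id: str
    gap_start: int  # 1-based inclusive, on the gapped transcript
    gap_end: int
    gap_len: int
    overlap_or_gap_on_continuous: int  # signed; negative = overlap
    orientation: str
    hsp_pair: tuple[HSPRecord, HSPRecord]


def pairwise_hsps(
    transcripts: Sequence[SeqRecord],
    min_identity: float = 95.0,
    min_hsp_len: int = 50,
) -> list[HSPRecord]:
    """All-vs-all high-identity local alignment via BLAST+ ``blastn``.

    Self-hits are removed; HSPs below ``min_identity`` percent identity or
    shorter than ``min_hsp_len`` are dropped.  Minus-strand HSPs arrive
    with ``s_start > s_end`` per BLAST tabular convention.
    """
    if len(transcripts) < 2:
        raise ValueError("need at least two transcripts")
    for tool in ("makeblastdb", "blastn"):
        if shutil.which(tool) is None:
            raise RuntimeError(f"{tool} not found on PATH; supply an HSP table instead")
    with tempfile.TemporaryDirectory(prefix="isopipe_blast_") as tmp:
        tmp = Path(tmp)
        fasta = tmp / "tx.fasta"
        write_fasta(transcripts, fasta)
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "nucl",
             "-out", str(tmp / "db")],
            check=True, capture_output=True,
        )
        out = tmp / "hits.tsv"
        subprocess.run(
            ["blastn", "-query", str(fasta), "-db", str(tmp / "db"),
             "-outfmt", "6", "-perc_identity", str(min_identity),
             "-dust", "no", "-soft_masking", "false",
             "-evalue", "1e-6", "-out", str(out)],
            check=True, capture_output=True,
        )
        hsps = read_hsp_table(out)
    return [
        h for h in hsps
        if h.query_id != h.subject_id
        and h.pct_identity >= min_identity
        and h.aln_len >= min_hsp_len
    ]


def _orient(h: HSPRecord, subject_len: int) -> HSPRecord:
    """Normalize a minus-strand HSP onto the reverse-complemented subject so
    both HSP subject spans run forward."""
    if not h.minus_strand:
        return h
    return replace(
        h,
        s_start=subject_len - h.s_start + 1,
        s_end=subject_len - h.s_end + 1,
    )


def _merge_micro_splits(
    hsps: list[HSPRecord], max_sep: int = 5
) -> list[HSPRecord]:
    """Heal HSPs fragmented by micro-indels: merge pairs separated by
    < ``max_sep`` bp on *both* sequences (after orientation)."""
    hsps = sorted(hsps, key=lambda h: h.q_start)
    merged: list[HSPRecord] = []
    for h in hsps:
        if merged:
            prev = merged[-1]
            dq = h.q_start - prev.q_end - 1
            ds = h.s_start - prev.s_end - 1
            if -max_sep < dq < max_sep and -max_sep < ds < max_sep:
                merged[-1] = replace(
                    prev,
                    q_end=max(prev.q_end, h.q_end),
                    s_end=max(prev.s_end, h.s_end),
                    aln_len=prev.aln_len + h.aln_len,
                    bitscore=prev.bitscore + h.bitscore,
                )
                continue
        merged.append(h)
    return merged


def call_as_events(
    hsps: Iterable[HSPRecord],
    transcript_lengths: dict[str, int],
    max_overlap: int = 5,
    min_gap: int = 100,
    min_end_dist: int = 100,
    min_pair_coverage: float = 0.90,
) -> list[ASEvent]:
    """Apply the two-HSP AS rules to HSPs grouped by ordered transcript pair.

    A pair qualifies when, after micro-indel healing, it has exactly two
    HSPs of the same orientation such that: the continuous side's inter-HSP
    distance d satisfies |d| < ``max_overlap`` (negative d is an overlap);
    the gapped side's distance g satisfies g > ``min_gap`` (strict); the gap
    lies >= ``min_end_dist`` from both ends of the gapped transcript; and
    the two HSPs jointly cover >= ``min_pair_coverage`` of the continuous
    sequence.  Thresholds are strict exactly as stated: a gap of exactly
    100 or an overlap of exactly 5 is rejected.
    """
    groups: dict[tuple[str, str], list[HSPRecord]] = {}
    for h in hsps:
        groups.setdefault((h.query_id, h.subject_id), []).append(h)

    events: list[ASEvent] = []
    for (qid, sid), pair_hsps in sorted(groups.items()):
        orientations = {h.minus_strand for h in pair_hsps}
        if len(orientations) != 1:
            continue  # mixed-orientation alignments never qualify
        minus = orientations.pop()
        slen = transcript_lengths[sid]
        oriented = [_orient(h, slen) for h in pair_hsps]
        oriented = _merge_micro_splits(oriented)
        if len(oriented) != 2:
            continue
        a, b = sorted(oriented, key=lambda h: h.q_start)
        if b.s_start <= a.s_start:
            continue  # not collinear on the subject
        dq = b.q_start - a.q_end - 1
        ds = b.s_start - a.s_end - 1
        qlen = transcript_lengths[qid]

        event = None
        if abs(dq) < max_overlap and ds > min_gap:
            # query continuous, subject gapped
            gap_start, gap_end = a.s_end + 1, b.s_start - 1
            if gap_start >= min_end_dist and (slen - gap_end) >= min_end_dist:
                cov = ((a.q_end - a.q_start + 1) + (b.q_end - b.q_start + 1)) / qlen
                if cov >= min_pair_coverage:
                    event = ASEvent(
                        continuous_id=qid, gapped_id=sid,
                        gap_start=gap_start, gap_end=gap_end, gap_len=ds,
                        overlap_or_gap_on_continuous=dq,
                        orientation="-" if minus else "+",
                        hsp_pair=(a, b),
                    )
        elif abs(ds) < max_overlap and dq > min_gap:
            # subject continuous, query gapped
            gap_start, gap_end = a.q_end + 1, b.q_start - 1
            if gap_start >= min_end_dist and (qlen - gap_end) >= min_end_dist:
                cov = ((a.s_end - a.s_start + 1) + (b.s_end - b.s_start + 1)) / slen
                if cov >= min_pair_coverage:
                    event = ASEvent(
                        continuous_id=sid, gapped_id=qid,
                        gap_start=gap_start, gap_end=gap_end, gap_len=dq,
                        overlap_or_gap_on_continuous=ds,
                        orientation="-" if minus else "+",
                        hsp_pair=(a, b),
                    )
        if event is not None:
            events.append(event)
    return events


def as_summary(events: Sequence[ASEvent]) -> tuple[int, list[ASEvent]]:
    """Deduplicate events per unordered transcript pair (a pair found in
    both alignment directions counts once) and return (total, kept)."""
    seen: set[frozenset] = set()
    kept: list[ASEvent] = []
    for ev in events:
        key = frozenset((ev.continuous_id, ev.gapped_id))
        if key in seen:
            continue
        seen.add(key)
        kept.append(ev)
    return len(kept), kept
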