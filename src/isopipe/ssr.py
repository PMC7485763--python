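"""MISA-compatible microsatellite (SSR) scanning of transcripts.

Perfect tandem repeats of primitive 1–6 bp motifs are reported when they
reach the period-specific repeat minimum (defaults 10/6/5/5/5/5 — the MISA
published defaults).  Only transcripts strictly longer than 500 bp enter
the scan.  Nearby SSRs separated by at most 100 interrupting bases form a
compound SSR.  Coordinates are internal 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass
class SSRMotif:
    transcript_id: str
    motif: str
    n_repeats: int
    start: int  # 0-based half-open
    end: int
    compound_group: int | None = None

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SsrSummary:
    n_sequences_examined: int
    total_bases_examined: int
    n_ssr: int
    n_seq_with_ssr: int
    n_seq_with_gt1_ssr: int
    n_compound: int
    per_period: dict[int, int]


def is_primitive(motif: str) -> bool:
    """True when the motif is not itself a repetition of a shorter motif."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def select_ssr_input(
    transcripts: Sequence[tuple[str, str]], min_len: int = 500
) -> list[tuple[str, str]]:
    """Keep transcripts strictly longer than ``min_len`` bp."""
    return [(tid, seq) for tid, seq in transcripts if len(seq) > min_len]


def _candidate_runs(
    seq: str, min_repeats: Mapping[int, int]
) -> list[tuple[int, int, str, int]]:
    """All maximal primitive perfect tandem runs meeting the period minimum,
    as (start, end, motif, n_repeats).  Runs containing N are excluded."""
    n = len(seq)
    out = []
    for p in sorted(min_repeats):
        need = min_repeats[p]
        i = 0
        while i + p * need <= n:
            motif = seq[i : i + p]
            if "N" in motif or not is_primitive(motif):
                i += 1
                continue
            k = 1
            while seq[i + k * p : i + (k + 1) * p] == motif:
                k += 1
            if k >= need and seq[i - p : i] != motif:  # leftmost occurrence only
                out.append((i, i + k * p, motif, k))
                i += k * p  # next run of this period starts after this one
            else:
                i += 1
    return out


def resolve_overlaps(
    runs: list[tuple[int, int, str, int]]
) -> list[tuple[int, int, str, int]]:
    """Left-to-right greedy acceptance; conflicts resolved by longest total
    length, then smallest period, then leftmost."""
    accepted: list[tuple[int, int, str, int]] = []
    for r in sorted(runs, key=lambda r: (-(r[1] - r[0]), len(r[2]), r[0])):
        if all(r[1] <= a[0] or r[0] >= a[1] for a in accepted):
            accepted.append(r)
    accepted.sort()
    return accepted


def find_ssrs(
    seq: str,
    transcript_id: str = "",
    min_repeats: Mapping[int, int] | None = None,
) -> list[SSRMotif]:
    """Maximal perfect tandem repeats per period meeting the period minimum.

    Motifs are primitive (ATATATAT is a period-2 AT run, never period-4) and
    reported as found — no canonical-class collapsing.  Overlapping calls of
    different periods are resolved by longest total length, then smallest
    period.  No two reported SSRs overlap.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    runs = resolve_overlaps(_candidate_runs(seq.upper(), min_repeats))
    return [
        SSRMotif(transcript_id=transcript_id, motif=m, n_repeats=k, start=s, end=e)
        for s, e, m, k in runs
    ]


def group_compound(
    ssrs: Sequence[SSRMotif], max_interruption: int = 100
) -> list[SSRMotif]:
    """Assign compound groups: consecutive SSRs on one transcript separated
    by <= ``max_interruption`` bases share a group.  Returns the same
    records with ``compound_group`` set (None for solitary SSRs)."""
    by_tx: dict[str, list[SSRMotif]] = {}
    for s in ssrs:
        by_tx.setdefault(s.transcript_id, []).append(s)
    group_id = 0
    for tx, items in sorted(by_tx.items()):
        items.sort(key=lambda s: s.start)
        chain: list[SSRMotif] = []
        for s in items:
            if chain and s.start - chain[-1].end <= max_interruption:
                chain.append(s)
            else:
                if len(chain) > 1:
                    for c in chain:
                        c.compound_group = group_id
                    group_id += 1
                chain = [s]
        if len(chain) > 1:
            for c in chain:
                c.compound_group = group_id
            group_id += 1
    return list(ssrs)


def summarize_ssrs(
    ssrs: Sequence[SSRMotif], examined: Sequence[tuple[str, str]]
) -> SsrSummary:
    """Count table over the examined transcripts; ``n_ssr`` equals the sum
    of the per-period counts by construction."""
    per_period = {p: 0 for p in range(1, 7)}
    per_tx: dict[str, int] = {}
    for s in ssrs:
        per_period[s.period] += 1
        per_tx[s.transcript_id] = per_tx.get(s.transcript_id, 0) + 1
    return SsrSummary(
        n_sequences_examined=len(examined),
        total_bases_examined=sum(len(seq) for _, seq in examined),
        n_ssr=sum(per_period.values()),
        n_seq_with_ssr=len(per_tx),
        n_seq_with_gt1_ssr=sum(1 for v in per_tx.values() if v > 1),
        n_compound=sum(1 for s in ssrs if s.compound_group is not None),
        per_period=per_period,
    )
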