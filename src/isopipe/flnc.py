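"""Full-length non-chimeric (FLNC) classification of ROIs.

A read of insert is *full-length* when the 5' cDNA primer, the 3' cDNA
primer and a poly-A tail are all found; it is FLNC when additionally no
primer copy sits deep inside the read (internal primers betray artificial
concatemers created during library construction).  Trimming removes the
terminal primers and the poly-A tail.

Summary rows mirror the published FL-statistics layout: FL% uses the
full-length count (chimeras included) over ROIs, average FLNC length is a
floor division, and the concatemer percentage is truncated (not rounded)
to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .align import find_approx_matches
from .io_formats import revcomp
from .roi import ROI


@dataclass
class PrimerHit:
    start: int  # 0-based half-open span on the scanned sequence
    end: int
    strand: str  # '+' primer as given, '-' its reverse complement
    edits: int


@dataclass
class PolyAHit:
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FLNCRead:
    read_id: str
    sequence: str          # trimmed cDNA (primers and poly-A removed)
    strand: str
    has5p: bool
    has3p: bool
    has_polya: bool
    chimera: bool
    primer_hits: list[PrimerHit] = field(default_factory=list)
    library_bin: str = ""
    trimmed_len: int = 0

    @property
    def full_length(self) -> bool:
        return self.has5p and self.has3p and self.has_polya

    @property
    def is_flnc(self) -> bool:
        return self.full_length and not self.chimera


def detect_primer(
    seq: str,
    primer: str,
    max_edit_frac: float = 0.2,
    window: tuple[int, int] | None = None,
) -> list[PrimerHit]:
    """All non-overlapping approximate matches of ``primer`` or its reverse
    complement, each within ``ceil(max_edit_frac * len(primer))`` edits.

    ``window=None`` scans the whole read (needed for chimera detection);
    otherwise only the 0-based half-open slice ``window`` is scanned.
    """
    if len(primer) < 10:
        raise ValueError("primer length must be >= 10")
    max_edits = math.ceil(max_edit_frac * len(primer))
    lo, hi = window if window is not None else (0, len(seq))
    region = seq[lo:hi]
    hits = [
        PrimerHit(start=lo + s, end=lo + e, strand="+", edits=d)
        for s, e, d in find_approx_matches(primer, region, max_edits)
    ]
    rc = revcomp(primer)
    hits += [
        PrimerHit(start=lo + s, end=lo + e, strand="-", edits=d)
        for s, e, d in find_approx_matches(rc, region, max_edits)
    ]
    # a palindromic-ish region could match both orientations: keep the
    # better (fewer edits, then '+') of any overlapping pair
    hits.sort(key=lambda h: (h.edits, 0 if h.strand == "+" else 1))
    kept: list[PrimerHit] = []
    for h in hits:
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def detect_polya(
    seq: str,
    min_len: int = 20,
    max_nona_frac: float = 0.2,
    search_window: int = 60,
) -> PolyAHit | None:
    """Longest run of >= ``min_len`` bases with A-fraction >= 1 - ``max_nona_frac``
    ending within ``search_window`` of the 3' end.  N never counts as A.
    Ties prefer the rightmost run."""
    n = len(seq)
    lo = max(0, n - search_window - 400)  # tails beyond 400 bp are not modeled
    is_a = [1 if c == "A" else 0 for c in seq[lo:]]
    prefix = [0]
    for v in is_a:
        prefix.append(prefix[-1] + v)
    m = len(is_a)
    best: PolyAHit | None = None
    min_end = max(0, (n - search_window) - lo)
    for end in range(m, max(min_end, min_len) - 1, -1):
        if not is_a[end - 1]:
            continue  # runs are A-bounded on both sides
        for start in range(0, end - min_len + 1):
            if not is_a[start]:
                continue
            run = end - start
            a = prefix[end] - prefix[start]
            if a >= (1.0 - max_nona_frac) * run:
                if best is None or run > best.length:
                    best = PolyAHit(start=lo + start, end=lo + end)
                break  # longest run for this end found (earliest start)
    return best


def classify_read(
    roi: ROI,
    primer5: str,
    primer3: str,
    max_edit_frac: float = 0.2,
    terminal_window: int = 100,
    internal_min_dist: int = 100,
    polya_min_len: int = 20,
    min_trimmed_len: int = 50,
) -> FLNCRead:
    """Orient an ROI by its primer pair and classify it.

    The insert construct is ``primer5 + cDNA + polyA + revcomp(primer3)``,
    so on the sense strand the 5' primer sits at the start and the reverse
    complement of the 3' primer at the end.  Full-length requires both
    primers plus a poly-A tail; a further primer hit at least
    ``internal_min_dist`` from both ends marks a concatemer (chimera).
    """
    seq = roi.sequence
    hits5 = detect_primer(seq, primer5, max_edit_frac)
    hits3 = detect_primer(seq, primer3, max_edit_frac)

    def terminal_evidence(s: str, h5: list[PrimerHit], h3: list[PrimerHit]):
        n = len(s)
        lead = [h for h in h5 if h.strand == "+" and h.start < terminal_window]
        tail = [h for h in h3 if h.strand == "-" and h.end > n - terminal_window]
        return lead, tail

    lead_f, tail_f = terminal_evidence(seq, hits5, hits3)
    # antisense evidence in raw coordinates: the 5' primer of the oriented
    # read maps to a '-' hit of primer5 at the raw 3' end, and the oriented
    # rc(primer3) maps to a '+' hit of primer3 at the raw 5' end
    n = len(seq)
    lead_r = [h for h in hits5 if h.strand == "-" and h.end > n - terminal_window]
    tail_r = [h for h in hits3 if h.strand == "+" and h.start < terminal_window]

    if len(lead_f) + len(tail_f) >= len(lead_r) + len(tail_r):
        strand = "+"
        oriented = seq
        lead, tail = lead_f, tail_f
        all_hits = hits5 + hits3
    else:
        strand = "-"
        oriented = revcomp(seq)
        # recompute hits on the oriented sequence for uniform coordinates
        hits5 = detect_primer(oriented, primer5, max_edit_frac)
        hits3 = detect_primer(oriented, primer3, max_edit_frac)
        lead, tail = terminal_evidence(oriented, hits5, hits3)
        all_hits = hits5 + hits3

    has5p = bool(lead)
    has3p = bool(tail)
    n = len(oriented)
    search_end = min(h.start for h in tail) if tail else n
    polya = detect_polya(oriented[:search_end], min_len=polya_min_len)
    has_polya = polya is not None

    chimera = any(
        h.start >= internal_min_dist and h.end <= n - internal_min_dist
        for h in all_hits
    )

    trim_start = max(h.end for h in lead) if lead else 0
    trim_end = polya.start if polya is not None else search_end
    trim_end = max(trim_end, trim_start)
    trimmed = oriented[trim_start:trim_end]

    return FLNCRead(
        read_id=roi.read_id,
        sequence=trimmed,
        strand=strand,
        has5p=has5p,
        has3p=has3p,
        has_polya=has_polya,
        chimera=chimera,
        primer_hits=all_hits,
        library_bin=roi.library_bin,
        trimmed_len=len(trimmed),
    )


def truncate2(x: float) -> float:
    """Truncate (not round) to 2 decimals; summary convention for the
    concatemer percentage."""
    return math.floor(x * 100) / 100


@dataclass
class FlncBinRow:
    bin_name: str
    n_roi: int
    n_5p: int
    n_3p: int
    n_polya: int
    n_filtered_short: int
    n_nonfl: int
    n_fl: int
    n_flnc: int
    flnc_bases: int
    avg_flnc_len: int
    fl_pct: float
    concatemer_pct: float


@dataclass
class FlncSummary:
    bins: list[FlncBinRow]
    all_row: FlncBinRow | None


def _flnc_row(name: str, group: Sequence[FLNCRead], min_trimmed_len: int) -> FlncBinRow:
    n_roi = len(group)
    short = [r for r in group if r.trimmed_len < min_trimmed_len]
    usable = [r for r in group if r.trimmed_len >= min_trimmed_len]
    fl = [r for r in usable if r.full_length]
    flnc = [r for r in fl if not r.chimera]
    nonfl = [r for r in usable if not r.full_length]
    flnc_bases = sum(r.trimmed_len for r in flnc)
    return FlncBinRow(
        bin_name=name,
        n_roi=n_roi,
        n_5p=sum(1 for r in group if r.has5p),
        n_3p=sum(1 for r in group if r.has3p),
        n_polya=sum(1 for r in group if r.has_polya),
        n_filtered_short=len(short),
        n_nonfl=len(nonfl),
        n_fl=len(fl),
        n_flnc=len(flnc),
        flnc_bases=flnc_bases,
        avg_flnc_len=flnc_bases // len(flnc) if flnc else 0,
        fl_pct=round(100.0 * len(fl) / n_roi, 2) if n_roi else 0.0,
        concatemer_pct=truncate2(100.0 * (len(fl) - len(flnc)) / len(fl)) if fl else 0.0,
    )


def summarize_flnc(
    classified: Sequence[FLNCRead],
    min_trimmed_len: int = 50,
) -> FlncSummary:
    """Per-bin rows plus an "All" row computed from the summed counts.

    Invariants: ``n_roi = n_fl + n_nonfl + n_filtered_short`` per row;
    ``avg_flnc_len = floor(flnc_bases / n_flnc)``; ``fl_pct`` rounds and
    ``concatemer_pct`` truncates to 2 decimals.
    """
    if not classified:
        return FlncSummary(bins=[], all_row=None)
    groups: dict[str, list[FLNCRead]] = {}
    for r in classified:
        groups.setdefault(r.library_bin or "all", []).append(r)
    from .roi import _BIN_ORDER

    order = [b for b in _BIN_ORDER if b in groups] + sorted(
        set(groups) - set(_BIN_ORDER)
    )
    rows = [_flnc_row(name, groups[name], min_trimmed_len) for name in order]
    return FlncSummary(bins=rows, all_row=aggregate_flnc_bins(rows))


def aggregate_flnc_bins(rows: Sequence[FlncBinRow]) -> FlncBinRow:
    """The "All" row: count columns are sums; derived columns recomputed
    from the summed counts with the same floor/round/truncate rules."""
    n_roi = sum(r.n_roi for r in rows)
    n_fl = sum(r.n_fl for r in rows)
    n_flnc = sum(r.n_flnc for r in rows)
    flnc_bases = sum(r.flnc_bases for r in rows)
    return FlncBinRow(
        bin_name="All",
        n_roi=n_roi,
        n_5p=sum(r.n_5p for r in rows),
        n_3p=sum(r.n_3p for r in rows),
        n_polya=sum(r.n_polya for r in rows),
        n_filtered_short=sum(r.n_filtered_short for r in rows),
        n_nonfl=sum(r.n_nonfl for r in rows),
        n_fl=n_fl,
        n_flnc=n_flnc,
        flnc_bases=flnc_bases,
        avg_flnc_len=flnc_bases // n_flnc if n_flnc else 0,
        fl_pct=round(100.0 * n_fl / n_roi, 2) if n_roi else 0.0,
        concatemer_pct=truncate2(100.0 * (n_fl - n_flnc) / n_fl) if n_fl else 0.0,
    )
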