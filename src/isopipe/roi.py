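"""Raw-read filtering, subread disconnection, and per-read consensus (ROI).

A polymerase read holds several passes of one insert separated by adapter
copies.  The stage (i) drops raw reads shorter than 50 bp or below 0.8
accuracy, (ii) cuts reads at approximate adapter matches and discards
fragments under 50 bp, and (iii) collapses each read's subreads into a
majority-vote consensus — the read of insert (ROI) — retained when its
predicted quality reaches 0.8.  Summaries follow the library-bin layout
with the "All" mean columns being unweighted means of the per-bin means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .align import center_star_consensus, find_approx_matches, global_identity
from .simulate import library_bin


@dataclass
class PolymeraseRead:
    read_id: str
    sequence: str
    accuracy: float | None = None
    n_passes: int | None = None
    bin_hint: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ROI:
    """Per-read consensus (read of insert)."""

    read_id: str
    sequence: str
    full_passes: int
    read_quality: float
    library_bin: str = ""

    def __post_init__(self) -> None:
        if not self.library_bin:
            self.library_bin = library_bin(len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RoiBinRow:
    bin_name: str
    n_reads: int
    total_bases: int
    mean_length: float
    mean_quality: float
    mean_passes: int


@dataclass
class RoiSummary:
    bins: list[RoiBinRow]
    all_row: RoiBinRow | None


def filter_polymerase_reads(
    reads: Sequence[PolymeraseRead], min_len: int = 50, min_acc: float = 0.8
) -> list[PolymeraseRead]:
    """Remove reads with length < min_len or accuracy < min_acc.

    Boundaries are retained (a 50 bp read at exactly 0.8 accuracy stays).
    """
    kept = []
    for r in reads:
        if r.accuracy is None:
            raise ValueError(f"read {r.read_id}: accuracy missing")
        if len(r) >= min_len and r.accuracy >= min_acc:
            kept.append(r)
    return kept


def split_subreads(
    polymerase_read: str | PolymeraseRead,
    adapter: str,
    max_edit_frac: float = 0.10,
    min_subread_len: int = 50,
) -> list[str]:
    """Cut a polymerase read at approximate adapter matches and drop
    fragments shorter than ``min_subread_len``.

    Adapter matches tolerate up to ``max_edit_frac`` of the adapter length
    in edits (indel noise would otherwise miss joints).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = polymerase_read.sequence if isinstance(polymerase_read, PolymeraseRead) else polymerase_read
    max_edits = int(math.floor(max_edit_frac * len(adapter)))
    cuts = find_approx_matches(adapter, seq, max_edits)
    frags = []
    pos = 0
    for s, e, _ in cuts:
        frags.append(seq[pos:s])
        pos = e
    frags.append(seq[pos:])
    return [f for f in frags if len(f) >= min_subread_len]


def build_roi(
    subreads: Sequence[str],
    read_id: str = "",
    min_quality: float = 0.8,
    single_pass_accuracy: float | None = None,
) -> ROI | None:
    """Majority-vote consensus over a center-star alignment of subreads.

    ``full_passes`` is the number of subreads; ``read_quality`` is the mean
    identity of the subreads to the consensus.  A single subread becomes its
    own consensus with quality ``single_pass_accuracy`` when supplied, else
    0.8 (retained at the boundary).  Returns ``None`` below ``min_quality``.
    """
    if not subreads:
        raise ValueError("need at least one subread")
    if len(subreads) == 1:
        quality = single_pass_accuracy if single_pass_accuracy is not None else 0.8
        roi = ROI(read_id=read_id, sequence=subreads[0], full_passes=1,
                  read_quality=quality)
        return roi if quality >= min_quality else None
    consensus = center_star_consensus(subreads)
    quality = sum(global_identity(s, consensus) for s in subreads) / len(subreads)
    if quality < min_quality:
        return None
    return ROI(read_id=read_id, sequence=consensus,
               full_passes=len(subreads), read_quality=quality)


def rois_from_reads(
    reads: Sequence[PolymeraseRead],
    adapter: str,
    min_len: int = 50,
    min_acc: float = 0.8,
) -> list[ROI]:
    """Full stage: filter raw reads, split subreads, build consensi."""
    rois = []
    for r in filter_polymerase_reads(reads, min_len=min_len, min_acc=min_acc):
        subs = split_subreads(r, adapter)
        if not subs:
            continue
        roi = build_roi(subs, read_id=r.read_id, single_pass_accuracy=r.accuracy)
        if roi is not None:
            if r.bin_hint:
                roi.library_bin = r.bin_hint
            rois.append(roi)
    return rois


_BIN_ORDER = ("1-2kb", "2-3kb", "3-6kb")


def summarize_rois(rois: Sequence[ROI]) -> RoiSummary:
    """Per-bin statistics plus an "All" row.

    "All" counts and bases are sums over bins; the "All" mean columns are
    unweighted arithmetic means of the bin means, reported to 2 decimals
    (mean passes to the nearest integer).
    """
    if not rois:
        return RoiSummary(bins=[], all_row=None)
    groups: dict[str, list[ROI]] = {}
    for roi in rois:
        groups.setdefault(roi.library_bin, []).append(roi)
    order = [b for b in _BIN_ORDER if b in groups] + sorted(
        set(groups) - set(_BIN_ORDER)
    )
    rows = []
    for name in order:
        g = groups[name]
        n = len(g)
        bases = sum(len(r) for r in g)
        rows.append(
            RoiBinRow(
                bin_name=name,
                n_reads=n,
                total_bases=bases,
                mean_length=round(bases / n, 2),
                mean_quality=round(sum(r.read_quality for r in g) / n, 2),
                mean_passes=int(round(sum(r.full_passes for r in g) / n)),
            )
        )
    all_row = aggregate_roi_bins(rows)
    return RoiSummary(bins=rows, all_row=all_row)


def aggregate_roi_bins(rows: Sequence[RoiBinRow]) -> RoiBinRow:
    """The "All" row convention: sums for counts/bases, unweighted means of
    the bin means for the mean columns."""
    k = len(rows)
    return RoiBinRow(
        bin_name="All",
        n_reads=sum(r.n_reads for r in rows),
        total_bases=sum(r.total_bases for r in rows),
        mean_length=round(sum(r.mean_length for r in rows) / k, 2),
        mean_quality=round(sum(r.mean_quality for r in rows) / k, 2),
        mean_passes=int(round(sum(r.mean_passes for r in rows) / k)),
    )
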