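"""ORF discovery and CDS selection by length, hexamer log-likelihood and
nucleotide composition.

Candidate ORFs of at least ``min_aa`` codons are enumerated over all six
frames and classed as complete (ATG..stop), 5'-partial (runs into the
transcript start), 3'-partial (runs off the transcript end) or internal.
A hexamer model — per-hexamer log2 likelihood ratio of a coding corpus
against a mononucleotide-composition-preserving shuffled background, with
add-one smoothing — scores each ORF; the selected CDS is the best
positively scoring ORF by completeness rank, then score, then length.
The model self-trains on the longest candidate ORFs of the input, in the
spirit of two-pass ORF predictors.

ORF spans exclude the stop codon; internal coordinates are 0-based
half-open on the forward strand of the transcript.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import revcomp

STOPS = frozenset(("TAA", "TAG", "TGA"))
_COMPLETENESS_RANK = {"complete": 3, "5prime_partial": 2, "3prime_partial": 2, "internal": 1}


@dataclass
class ORFRecord:
    transcript_id: str
    start: int  # 0-based half-open span on the forward strand, stop excluded
    end: int
    strand: str
    frame: int
    completeness: str
    ll_score: float = 0.0
    gc_frac: float = float("nan")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def orf_sequence(transcript: str, orf: ORFRecord) -> str:
    seg = transcript[orf.start : orf.end]
    return seg if orf.strand == "+" else revcomp(seg)


def _frame_orfs(seq: str, frame: int, min_aa: int) -> list[tuple[int, int, str]]:
    """ORFs in one forward frame of ``seq`` as (start, end, completeness) in
    sequence coordinates (stop codon excluded from the span)."""
    n = len(seq)
    codon_starts = range(frame, n - 2, 3)
    out: list[tuple[int, int, str]] = []
    seg_begin = frame        # first codon position of the current segment
    seg_atg: int | None = None
    at_seq_start = True      # no stop seen yet in this frame
    for pos in codon_starts:
        codon = seq[pos : pos + 3]
        if codon in STOPS:
            out.extend(_close_segment(seg_begin, pos, seg_atg, at_seq_start, True, min_aa))
            seg_begin = pos + 3
            seg_atg = None
            at_seq_start = False
        elif codon == "ATG" and seg_atg is None:
            seg_atg = pos
    last = (n - frame) // 3 * 3 + frame  # end of last full codon
    out.extend(_close_segment(seg_begin, last, seg_atg, at_seq_start, False, min_aa))
    return out


def _close_segment(
    begin: int, end: int, atg: int | None, at_seq_start: bool,
    stopped: bool, min_aa: int,
) -> list[tuple[int, int, str]]:
    if end <= begin:
        return []
    if atg is not None:
        start = atg
        completeness = "complete" if stopped else "3prime_partial"
    elif at_seq_start:
        start = begin
        completeness = "5prime_partial" if stopped else "internal"
    else:
        return []  # stop-bounded segment with no start codon cannot code
    if (end - start) // 3 < min_aa:
        return []
    return [(start, end, completeness)]


def find_orfs(
    seq: str,
    transcript_id: str = "",
    min_aa: int = 100,
    both_strands: bool = True,
) -> list[ORFRecord]:
    """All maximal ORFs of >= ``min_aa`` codons in up to six frames.

    Minus-strand ORFs are reported with forward-strand coordinates (the
    span on the given sequence) and ``strand='-'``.
    """
    seq = seq.upper()
    n = len(seq)
    records: list[ORFRecord] = []
    for frame in range(3):
        for s, e, comp in _frame_orfs(seq, frame, min_aa):
            records.append(
                ORFRecord(transcript_id=transcript_id, start=s, end=e,
                          strand="+", frame=frame, completeness=comp)
            )
    if both_strands:
        rc = revcomp(seq)
        for frame in range(3):
            for s, e, comp in _frame_orfs(rc, frame, min_aa):
                records.append(
                    ORFRecord(transcript_id=transcript_id,
                              start=n - e, end=n - s,
                              strand="-", frame=frame, completeness=comp)
                )
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return records


def _hexamer_counts(seqs: Sequence[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - 5):
            h = s[i : i + 6]
            if "N" not in h:
                counts[h] = counts.get(h, 0) + 1
    return counts


ALL_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]


def shuffle_preserving_composition(seq: str, rng: np.random.Generator) -> str:
    """Random permutation of the letters: mononucleotide composition is kept
    exactly, all higher-order structure destroyed."""
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def train_hexamer_model(
    coding_seqs: Sequence[str],
    background_seqs: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Per-hexamer log2(freq_coding / freq_background) with add-one smoothing.

    When no background corpus is given, each coding sequence is shuffled
    (mononucleotide-preserving) to form one; ``seed`` fixes the shuffle.
    """
    if len(coding_seqs) < 1:
        raise ValueError("need at least one coding sequence")
    if background_seqs is None:
        rng = np.random.default_rng(seed)
        background_seqs = [shuffle_preserving_composition(s, rng) for s in coding_seqs]
    cod = _hexamer_counts(coding_seqs)
    bg = _hexamer_counts(background_seqs)
    tot_c = sum(cod.values()) + len(ALL_HEXAMERS)
    tot_b = sum(bg.values()) + len(ALL_HEXAMERS)
    return {
        h: math.log2(((cod.get(h, 0) + 1) / tot_c) / ((bg.get(h, 0) + 1) / tot_b))
        for h in ALL_HEXAMERS
    }


def mean_hexamer_score(seq: str, model: Mapping[str, float]) -> float:
    """Mean per-hexamer log-likelihood ratio over all overlapping hexamers."""
    scores = [model[seq[i : i + 6]] for i in range(len(seq) - 5)
              if "N" not in seq[i : i + 6]]
    return sum(scores) / len(scores) if scores else 0.0


def score_orfs(
    transcript: str, orfs: Sequence[ORFRecord], model: Mapping[str, float]
) -> None:
    for orf in orfs:
        seq = orf_sequence(transcript, orf)
        orf.ll_score = mean_hexamer_score(seq, model)
        orf.gc_frac = (seq.count("G") + seq.count("C")) / len(seq)


def select_cds(
    transcript: str, orfs: Sequence[ORFRecord], model: Mapping[str, float]
) -> ORFRecord | None:
    """Best ORF among those with positive mean hexamer score, ranked by
    completeness, then *total* log-likelihood (mean score times hexamer
    count — evidence accumulates with length, so a long genuine ORF beats a
    short nested one with a slightly higher mean), then length.  ``None``
    when no ORF scores above zero."""
    score_orfs(transcript, orfs, model)
    kept = [o for o in orfs if o.ll_score > 0]
    if not kept:
        return None
    return max(kept, key=lambda o: (_COMPLETENESS_RANK[o.completeness],
                                    o.ll_score * max(o.length_nt - 5, 1),
                                    o.length_nt))


def self_train_model(
    transcripts: Sequence[tuple[str, str]],
    min_aa: int = 100,
    top_n: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Train the hexamer model on the longest ``top_n`` candidate ORFs of
    the input transcripts (all, if fewer)."""
    candidates: list[str] = []
    for tid, seq in transcripts:
        for orf in find_orfs(seq, tid, min_aa=min_aa):
            candidates.append(orf_sequence(seq, orf))
    if not candidates:
        raise ValueError("no candidate ORFs to train on")
    candidates.sort(key=len, reverse=True)
    return train_hexamer_model(candidates[:top_n], seed=seed)


def cds_length_histogram(
    selected: Sequence[ORFRecord], bin_width: int = 100
) -> dict[int, int]:
    """Counts of complete-ORF CDS lengths per ``bin_width`` nt bin, keyed by
    the bin's left edge."""
    hist: dict[int, int] = {}
    for orf in selected:
        if orf.completeness != "complete":
            continue
        left = orf.length_nt // bin_width * bin_width
        hist[left] = hist.get(left, 0) + 1
    return dict(sorted(hist.items()))
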