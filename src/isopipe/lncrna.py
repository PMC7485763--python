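"""Long non-coding RNA filtering by length and coding-potential consensus.

A transcript is a lncRNA candidate when longer than 200 nt; it is called a
lncRNA only when three independent coding-potential methods unanimously
vote non-coding:

* ``fickett`` — the classic TESTCODE statistic combining the positional
  bias (period-3 asymmetry) and composition of each base, via the
  published lookup tables; coding-like sequences score high.
* ``hexamer`` — mean per-hexamer log-likelihood ratio under the model
  trained by the ORF stage; positive means coding-like.
* ``orf_coverage`` — longest-ORF length over transcript length; protein
  coders devote a large fraction of their length to the ORF.

Method verdicts and Venn-region counts over the per-method non-coding
sets are reported alongside the final intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .orf import ORFRecord, mean_hexamer_score, orf_sequence

# Fickett (TESTCODE) lookup tables: probability that a sequence with the
# given position value / content value is coding, per base.
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_BOUNDS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.61, 0.42, 0.29, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_BOUNDS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17]

METHODS = ("fickett", "hexamer", "orf_coverage")

DEFAULT_THRESHOLDS = {"fickett": 0.95, "hexamer": 0.0, "orf_coverage": 0.3}


def _lookup(value: float, bounds: list[float], probs: list[float]) -> float:
    for i, b in enumerate(bounds):
        if value >= b:
            return probs[i]
    return probs[-1]


def fickett_score(seq: str) -> float:
    """TESTCODE statistic of a sequence of length >= 200.

    For each base B: the position value is max/(min+1) of B's counts in the
    three codon phases, and the content value is B's overall frequency;
    both are mapped through the published probability tables and combined
    with the published weights.  Higher = more coding-like.
    """
    seq = seq.upper()
    if len(seq) < 200:
        raise ValueError(f"fickett_score needs >= 200 nt, got {len(seq)}")
    total = len(seq)
    score = 0.0
    for base in "ACGT":
        phase = [seq[i::3].count(base) for i in range(3)]
        position_value = max(phase) / (min(phase) + 1.0)
        content_value = sum(phase) / total
        score += _lookup(position_value, _POSITION_BOUNDS,
                         _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content_value, _CONTENT_BOUNDS,
                         _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def orf_coverage_score(seq: str, orfs: Sequence[ORFRecord]) -> float:
    """Longest-ORF length over transcript length; 0 without an ORF."""
    if not orfs:
        return 0.0
    return max(o.length_nt for o in orfs) / len(seq)


@dataclass
class LncRNAVerdict:
    transcript_id: str
    length_nt: int
    scores: dict[str, float]
    verdicts: dict[str, str]  # method -> "coding" | "noncoding"
    final: bool  # True = lncRNA


def classify_lncrna(
    transcripts: Sequence[tuple[str, str]],
    orfs_by_transcript: Mapping[str, Sequence[ORFRecord]],
    model: Mapping[str, float],
    thresholds: Mapping[str, float] | None = None,
    min_len: int = 200,
) -> tuple[list[LncRNAVerdict], dict[str, int]]:
    """Vote each method independently and intersect.

    final lncRNA = length > ``min_len`` and every method votes non-coding.
    Venn counts are over the per-method non-coding sets restricted to
    length-qualified candidates, keyed by '+'-joined method combinations.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    verdicts: list[LncRNAVerdict] = []
    noncoding_sets: dict[str, set[str]] = {m: set() for m in METHODS}
    for tid, seq in transcripts:
        n = len(seq)
        orfs = orfs_by_transcript.get(tid, ())
        if n <= min_len:
            verdicts.append(LncRNAVerdict(tid, n, {}, {}, final=False))
            continue
        # hexamer is scored on the best candidate ORF when one exists (the
        # reading frame is what carries codon bias); transcript-wide
        # otherwise.  A transcript whose ORF scores positive therefore votes
        # coding here, making the final lncRNA set disjoint from the
        # selected-CDS carriers by construction.
        if orfs:
            hex_score = max(
                mean_hexamer_score(orf_sequence(seq, o), model) for o in orfs
            )
        else:
            hex_score = mean_hexamer_score(seq, model)
        scores = {
            "fickett": fickett_score(seq),
            "hexamer": hex_score,
            "orf_coverage": orf_coverage_score(seq, orfs),
        }
        vote = {
            m: "coding" if scores[m] >= thresholds[m] else "noncoding"
            for m in METHODS
        }
        # hexamer votes coding strictly above its threshold (default 0:
        # a exactly-zero mean is indistinguishable from background)
        vote["hexamer"] = "coding" if scores["hexamer"] > thresholds["hexamer"] else "noncoding"
        for m in METHODS:
            if vote[m] == "noncoding":
                noncoding_sets[m].add(tid)
        final = all(v == "noncoding" for v in vote.values())
        verdicts.append(LncRNAVerdict(tid, n, scores, vote, final=final))
    return verdicts, venn_counts(noncoding_sets)


def venn_counts(sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Exclusive region counts of the per-method non-coding sets."""
    methods = list(sets)
    ids = set().union(*sets.values()) if sets else set()
    regions: dict[str, int] = {}
    for tid in ids:
        members = [m for m in methods if tid in sets[m]]
        key = "+".join(members)
        regions[key] = regions.get(key, 0) + 1
    return dict(sorted(regions.items()))
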