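"""Isoform-level clustering, polishing, quality calling and dedup.

FLNC reads are grouped into isoform clusters by iterative greedy
assignment (seeds in descending length order, reads join the first cluster
whose consensus they match at the identity/coverage thresholds, consensi
are rebuilt and reads reassigned until stable).  Clusters are polished by
recruiting non-full-length reads into the majority-vote consensus;
a consensus is high quality (HQ) when its predicted accuracy — the mean
identity of its supporting reads to the final consensus — reaches 0.99.
Redundancy removal is greedy-incremental over descending length, merging a
transcript into an existing representative at >= 99% identity over the
shorter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .align import center_star_consensus, infix_identity


@dataclass
class Cluster:
    cluster_id: int
    consensus: str
    members: list[int] = field(default_factory=list)  # read indices


@dataclass
class IsoformConsensus:
    cluster_id: int
    sequence: str
    n_flnc_support: int
    n_nonfl_support: int
    predicted_accuracy: float

    @property
    def quality_class(self) -> str:
        return "HQ" if self.predicted_accuracy >= 0.99 else "LQ"


@dataclass
class ClusterSummary:
    n_consensus: int
    mean_consensus_len: int
    n_hq: int
    n_lq: int
    pct_hq: float


def _matches(seq: str, consensus: str, min_identity: float, min_coverage: float) -> bool:
    """Identity/coverage test over the shorter of the two sequences."""
    if len(seq) <= len(consensus):
        query, target = seq, consensus
    else:
        query, target = consensus, seq
    res = edlib.align(query, target, mode="HW", task="locations")
    dist = res["editDistance"]
    identity = 1.0 - dist / len(query)
    if identity < min_identity:
        return False
    s, e = res["locations"][0]
    span = (e + 1) - (s or 0)
    return min(span, len(query)) / len(query) >= min_coverage


def ice_cluster(
    flnc_reads: Sequence[str],
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
    max_iters: int = 10,
) -> list[Cluster]:
    """Iterative greedy clustering of FLNC sequences.

    Deterministic: seeds are taken in descending length (ties by input
    order); each read joins the first (lowest cluster_id) matching cluster.
    Returns a partition — every read index appears in exactly one cluster.
    """
    if not flnc_reads:
        raise ValueError("need at least one FLNC read")
    order = sorted(range(len(flnc_reads)), key=lambda i: (-len(flnc_reads[i]), i))
    clusters: list[Cluster] = []
    assignment: dict[int, int] = {}
    # initial greedy pass
    for i in order:
        seq = flnc_reads[i]
        for cl in clusters:
            if _matches(seq, cl.consensus, min_identity, min_coverage):
                cl.members.append(i)
                assignment[i] = cl.cluster_id
                break
        else:
            clusters.append(Cluster(cluster_id=len(clusters), consensus=seq, members=[i]))
            assignment[i] = clusters[-1].cluster_id
    # iterate: rebuild consensi, reassign until no read moves
    for _ in range(max_iters):
        for cl in clusters:
            if cl.members:
                cl.consensus = center_star_consensus([flnc_reads[i] for i in cl.members])
        moved = False
        for i in order:
            best = None
            for cl in clusters:
                if cl.members and _matches(flnc_reads[i], cl.consensus, min_identity, min_coverage):
                    best = cl.cluster_id
                    break
            if best is None:
                continue  # keeps its current cluster (its own seed)
            if best != assignment[i]:
                clusters[assignment[i]].members.remove(i)
                clusters[best].members.append(i)
                assignment[i] = best
                moved = True
        if not moved:
            break
    live = [cl for cl in clusters if cl.members]
    for new_id, cl in enumerate(live):
        cl.cluster_id = new_id
        cl.members.sort()
    return live


def polish(
    cluster: Cluster,
    flnc_reads: Sequence[str],
    nonfl_reads: Sequence[str] = (),
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> IsoformConsensus:
    """Recruit concordant non-FL reads and rebuild the consensus.

    predicted_accuracy is the mean identity of all supporting reads (FLNC
    members plus recruited non-FL) to the final consensus, measured over
    the aligned region (the shorter sequence) — a truncated but concordant
    read supports, rather than contradicts, the consensus.
    """
    if not cluster.members:
        raise ValueError("cluster has no members")
    support = [flnc_reads[i] for i in cluster.members]
    recruited = [
        s for s in nonfl_reads if _matches(s, cluster.consensus, min_identity, min_coverage)
    ]
    consensus = center_star_consensus(support + recruited)
    everyone = support + recruited

    def support_identity(s: str) -> float:
        if len(s) <= len(consensus):
            return infix_identity(s, consensus)[0]
        return infix_identity(consensus, s)[0]

    acc = sum(support_identity(s) for s in everyone) / len(everyone)
    return IsoformConsensus(
        cluster_id=cluster.cluster_id,
        sequence=consensus,
        n_flnc_support=len(support),
        n_nonfl_support=len(recruited),
        predicted_accuracy=acc,
    )


def classify_quality(consensi: Sequence[IsoformConsensus]) -> ClusterSummary:
    """HQ iff predicted accuracy >= 0.99; percentage rounded to 2 decimals."""
    n = len(consensi)
    if n == 0:
        return ClusterSummary(0, 0, 0, 0, 0.0)
    n_hq = sum(1 for c in consensi if c.quality_class == "HQ")
    return ClusterSummary(
        n_consensus=n,
        mean_consensus_len=int(round(sum(len(c.sequence) for c in consensi) / n)),
        n_hq=n_hq,
        n_lq=n - n_hq,
        pct_hq=round(100.0 * n_hq / n, 2),
    )


def hq_summary_from_counts(n_hq: int, n_consensus: int) -> float:
    """The HQ-isoform percentage convention applied to bare counts."""
    return round(100.0 * n_hq / n_consensus, 2)


def dedup(
    transcripts: Sequence[tuple[str, str]],
    identity: float = 0.99,
    coverage: float = 0.0,
) -> list[tuple[str, str]]:
    """Greedy-incremental redundancy removal over (id, sequence) pairs.

    Longest-first: a transcript joins an existing representative when its
    identity over the shorter sequence reaches ``identity``; otherwise it
    founds a new representative.  Output preserves the order of first
    appearance of representatives.  Idempotent and never count-increasing.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    order = sorted(range(len(transcripts)), key=lambda i: (-len(transcripts[i][1]), i))
    reps: list[tuple[str, str]] = []
    for i in order:
        tid, seq = transcripts[i]
        merged = False
        for rid, rseq in reps:
            if _matches(seq, rseq, identity, coverage):
                merged = True
                break
        if not merged:
            reps.append((tid, seq))
    return reps
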