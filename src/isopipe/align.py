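"""Thin alignment primitives over edlib shared by several stages.

Everything here returns 0-based half-open coordinates.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import edlib


def edit_distance(a: str, b: str, mode: str = "NW") -> int:
    return edlib.align(a, b, mode=mode)["editDistance"]


def global_identity(a: str, b: str) -> float:
    """1 - NW edit distance / max length; symmetric, in [0, 1]."""
    if not a or not b:
        return 0.0
    return 1.0 - edit_distance(a, b) / max(len(a), len(b))


def infix_identity(query: str, target: str) -> tuple[float, tuple[int, int]]:
    """Identity of ``query`` aligned as an infix of ``target`` (free end gaps
    on the target).  Returns (1 - dist/len(query), target span)."""
    res = edlib.align(query, target, mode="HW", task="locations")
    dist = res["editDistance"]
    loc = res["locations"][0]
    return 1.0 - dist / len(query), (loc[0] or 0, (loc[1] or 0) + 1)


def find_approx_matches(
    pattern: str, text: str, max_edits: int
) -> list[tuple[int, int, int]]:
    """All non-overlapping approximate occurrences of ``pattern`` in ``text``
    with edit distance <= ``max_edits``, best-first; returned sorted by start
    as (start, end, edits) 0-based half-open spans.

    edlib reports only the best-scoring locations, so matches are recovered
    by recursive interval splitting around each accepted hit.
    """
    hits: list[tuple[int, int, int]] = []

    def search(lo: int, hi: int) -> None:
        if hi - lo < max(1, len(pattern) - max_edits):
            return
        res = edlib.align(pattern, text[lo:hi], mode="HW", task="locations")
        dist = res["editDistance"]
        if dist < 0 or dist > max_edits:
            return
        # one representative location per distinct non-overlapping region
        locs = sorted((s or 0, e + 1) for s, e in res["locations"])
        chosen: list[tuple[int, int]] = []
        for s, e in locs:
            if not chosen or s >= chosen[-1][1]:
                chosen.append((s, e))
        for s, e in chosen:
            hits.append((lo + s, lo + e, dist))
        # recurse into the gaps to pick up worse-scoring occurrences
        bounds = [lo] + [x for s, e in chosen for x in (lo + s, lo + e)] + [hi]
        for i in range(0, len(bounds), 2):
            search(bounds[i], bounds[i + 1])

    search(0, len(text))
    hits.sort()
    # drop overlaps, keeping the lower-edit (then leftmost) hit
    kept: list[tuple[int, int, int]] = []
    for h in sorted(hits, key=lambda t: (t[2], t[0])):
        if all(h[1] <= k[0] or h[0] >= k[1] for k in kept):
            kept.append(h)
    kept.sort()
    return kept


def center_star_consensus(seqs: Sequence[str]) -> str:
    """Majority-vote consensus over a center-star alignment to the longest
    sequence.  Deterministic: ties break toward the center's own base, then
    lexicographically."""
    if not seqs:
        raise ValueError("need at least one sequence")
    if len(seqs) == 1:
        return seqs[0]
    center = max(seqs, key=len)
    n = len(center)
    # votes[i] over {A,C,G,T,N,'-'} for center column i;
    # ins[i] collects strings inserted *before* center column i (n = end)
    votes: list[Counter] = [Counter() for _ in range(n)]
    ins: list[Counter] = [Counter() for _ in range(n + 1)]
    n_seqs = 0
    for s in seqs:
        n_seqs += 1
        if s == center:
            for i, ch in enumerate(center):
                votes[i][ch] += 1
            continue
        res = edlib.align(s, center, mode="NW", task="path")
        qpos = 0
        tpos = 0
        pending_ins: list[str] = []
        for count, op in _parse_cigar(res["cigar"]):
            if op in "=XM":
                if pending_ins:
                    ins[tpos]["".join(pending_ins)] += 1
                    pending_ins = []
                for _ in range(count):
                    votes[tpos][s[qpos]] += 1
                    qpos += 1
                    tpos += 1
            elif op == "I":  # in query, insertion relative to center
                pending_ins.extend(s[qpos : qpos + count])
                qpos += count
            elif op == "D":  # gap in query
                if pending_ins:
                    ins[tpos]["".join(pending_ins)] += 1
                    pending_ins = []
                for _ in range(count):
                    votes[tpos]["-"] += 1
                    tpos += 1
        if pending_ins:
            ins[tpos]["".join(pending_ins)] += 1
    out: list[str] = []
    half = n_seqs / 2.0
    for i in range(n + 1):
        if ins[i]:
            total_ins = sum(ins[i].values())
            if total_ins > half:
                best = min(
                    (s for s, c in ins[i].items()
                     if c == max(ins[i].values())),
                )
                out.append(best)
        if i < n:
            col = votes[i]
            if not col:
                out.append(center[i])
                continue
            top = max(col.values())
            cands = sorted(ch for ch, c in col.items() if c == top)
            best = center[i] if center[i] in cands else cands[0]
            if best != "-":
                out.append(best)
    return "".join(out)


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops
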