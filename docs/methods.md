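# Methods

## Scope and design

`isopipe` characterizes a full-length transcriptome directly from
multi-pass long reads, with no reference genome. The chain is: raw-read
filtering → subread consensus (ROI) → full-length non-chimeric (FLNC)
classification → isoform clustering + polishing → redundancy removal →
feature calling (alternative splicing, SSRs, ORFs/CDS, lncRNAs). Every
stage is a pure library function; the CLI and the `analysis/` drivers are
thin wrappers. A planted-truth simulator is first-class: it is the only
way to measure recall/precision for a reference-free pipeline, so its
guarantees are part of the package contract.

## The simulator and what it does (not) emulate

A simulated sequencing reaction produces one *polymerase read*:
`n_passes` copies of the insert construct
`primer5 + cDNA + polyA + revcomp(primer3)` joined by adapter copies.
Defaults, chosen to reproduce the regime of a size-selected
(1–2 / 2–3 / 3–6 kb) multi-pass cDNA library:

| parameter | default | rationale |
|---|---|---|
| pass count | geometric, mean 5 | matches reported mean passes; spans the 0.8 ROI quality threshold |
| per-pass error | 5% (tests), jittered U[0.5, 1.5]× per read | long-read raw error regime; jitter exercises the accuracy filter |
| error mix | 55% ins / 30% del / 15% sub | indel-dominant chemistry |
| concatemer rate | 3–5% | two full inserts joined, internal primer copy |
| poly-A length | 30 nt | typical tail after cDNA synthesis |
| primers | two distinct 25-mers, edit distance > 10 | kit sequences are proprietary; detection logic is what matters |

Planted features give each caller a measurable truth surface: 30% of
genes carry a second isoform with a contiguous block (U[110, 400] bp,
≥ 120 bp from both ends) removed — satisfying the AS caller's gap/end
rules by construction; the block's terminal 10-mers are replaced by
barriers dissimilar to the flanking continuation under every small
alignment shift, so a local aligner cannot extend an HSP across the
junction and recall is measurable without edge ambiguity. Planted SSRs
cycle the six period classes with repeat counts above the MISA minima and
T-barriers (planted motifs are T-free) that terminate the tract. Planted
ORFs are ATG + ≥ 100 biased codons + stop, drawn from a plant-like codon
weight table — enough hexamer signal to separate from uniform DNA.

Not modeled: strand alternation between passes (all passes share one
orientation), ZMW loading artifacts, adapter dimers, base-level kinetics,
expression-level variation, and sequence-context-dependent error rates.
Passing tests therefore demonstrate the *logic* of each stage under
realistic read structure and noise, not performance on any particular
instrument's error profile.

## Numerical and algorithmic choices

**Consensus.** Center-star majority vote anchored on the longest subread
(edlib global alignments; insertions kept when supported by a strict
majority; ties break to the anchor's base, then lexicographically). The
vendor's HMM polishing is not public and is out of scope; the stand-in is
deterministic and adequate at desk scale. ROI quality = mean identity of
subreads to the consensus; a single-pass read keeps its own accuracy
estimate, defaulting to 0.8 (retained at the boundary, matching the
raw-read filter's inclusive semantics: "< 50 bp" and "< 0.8" are removed,
boundaries stay).

**Primer and adapter matching.** Approximate occurrences found by
recursive best-first edlib infix search with interval splitting;
tolerance 10% of adapter length for splitting (indel noise would
otherwise fragment reads) and ceil(20% of primer length) for primer
hits. Poly-A: longest A-bounded window with ≥ 80% A ending within 60 nt
of the (oriented, pre-3′-primer) end, ≥ 20 nt. The 20% non-A tolerance
means trimming may absorb a short A-rich cDNA suffix; tests allow that
slack explicitly.

**Clustering.** Greedy seeding in descending length order; a read joins
the first cluster whose consensus matches at identity ≥ 0.90 over the
shorter sequence (edlib infix alignment); consensi are rebuilt and reads
reassigned until stable (≤ 10 iterations). Deterministic by construction
(stable orderings, lowest-cluster-id tie-break). The 0.90/0.90 defaults
separate isoform pairs whose skipped block exceeds ~10% of the shared
span while merging 2% residual noise; pairs with a 110 bp block inside a
multi-kb transcript sit above 0.90 identity and merge — an intrinsic
resolution limit of identity-threshold clustering, which is why the
clustering benchmarks use transcripts ≤ 1.1 kb, where the planted
partition is the unique correct answer.

**Polishing and HQ.** Non-FL reads are recruited at the same thresholds;
predicted accuracy is the mean identity of supporting reads to the final
consensus measured over the aligned region (the shorter sequence), so a
truncated but concordant read supports rather than contradicts the
consensus. HQ ⇔ predicted accuracy ≥ 0.99.

**Dedup.** Greedy incremental, longest first, join at ≥ 0.99 identity
over the shorter sequence (threshold exposed in config). Idempotent, never
count-increasing.

**AS calling.** HSPs come from BLAST+ (`blastn`, dust off, 1e-6) or a
user-supplied 12-column table. Minus-strand HSPs are normalized onto the
reverse-complemented subject. HSPs separated by < 5 bp on both sequences
are merged first (micro-indel healing); then exactly-two-HSP pairs are
tested with strict thresholds: continuous-side |d| < 5, gap > 100,
gap ≥ 100 bp from both ends of the gapped transcript (end distance is
measured on the gapped side — the skipped block is internal to it), and
joint HSP coverage ≥ 0.90 of the continuous side (quantifying "aligns
almost completely"; no published number exists). Events are counted once
per unordered transcript pair. The noisy-recall benchmark uses ~2%
divergence between the two aligned transcripts (1% residual error each):
at ~4% divergence the pair sits below the 95%-identity alignment setting
and recall is capped by the aligner, not the caller.

**SSR.** Maximal perfect tandem runs of primitive 1–6 bp motifs, minima
10/6/5/5/5/5 (MISA's published defaults). Runs containing N are excluded; motifs are
reported as found (no canonical collapsing — the summary counts raw
motifs per period). Overlaps are resolved longest-total-length first,
then smallest period, then leftmost. Compound grouping chains SSRs
≤ 100 bp apart.

**ORF/CDS.** Six-frame enumeration, ≥ 100 codons, spans exclude the stop
codon; completeness classes complete / 5′-partial / 3′-partial /
internal. The hexamer model is per-hexamer log2(coding/background) with
add-one smoothing, background = mononucleotide-preserving shuffles,
self-trained on the longest ≤ 500 candidate ORFs. CDS selection keeps
ORFs with positive mean score and ranks by completeness, then **total**
log-likelihood (mean × hexamer count), then length: ranking by mean alone
lets short nested ORFs with slightly higher density beat the genuine long
ORF, which measurably breaks planted-ORF recovery.

**lncRNA.** Candidates are transcripts > 200 nt; three in-house methods
vote (database-backed external predictors in the CPC/CNCI/CPAT/Pfam
mold need reference databases that are out of scope here, but the
per-method-vote + intersection contract is preserved and method names
are pluggable): Fickett TESTCODE
(published lookup tables and weights) calls coding at ≥ 0.95; the hexamer
model, scored on the best candidate ORF when one exists (the reading
frame carries the codon bias; this also makes the lncRNA set disjoint
from selected-CDS carriers by construction), calls coding above 0; ORF
coverage (longest ORF / transcript length) calls coding at ≥ 0.3. Final
lncRNA = unanimous non-coding. The exon-count criterion used alongside
length in genome-based workflows requires a mapping that does not exist
here and is omitted.

**Summary-table conventions** (pinned by the published tables'
arithmetic): "All" mean columns are unweighted means of the per-bin
means; counts and base totals are sums; FL% = full-length (chimeras
included) / ROIs, rounded to 2 dp; average FLNC length = floor(bases /
reads); concatemer % = truncated (not rounded) to 2 dp; HQ % rounded to
2 dp. One published bin cell (3–6 kb concatemer %) is inconsistent with
the truncation rule its own "All" row pins down and cannot be reproduced
under any single rule.

## Problem sizes

The suite and acceptance script run at desk scale: 20–50 gene sets,
transcripts 0.5–2.5 kb, 1000 reads for FLNC benchmarking, 260 reads for
clustering ARI, 50 planted AS pairs, 1000 random 1 kb sequences for the
SSR oracle and 100 random 5 kb sequences for the ORF oracle. These sizes
are the package's chosen benchmark conditions; all are configurable.

## Known limitations

- Identity-threshold clustering cannot separate isoforms whose skipped
  block is below ~10% of transcript length (see above).
- The ROI consensus is majority-vote, not a probabilistic model; its
  quality estimate is an identity average, so "0-pass" reads (no
  complete pass) are not modeled — at least one subread is required.
- AS events are reported per transcript pair without subtype
  classification (exon-skip vs alternative 5′/3′).
- SSR calling is perfect-repeat only (no interrupted single-SSR model).
- The poly-A boundary is tolerance-based and can absorb a short A-rich
  cDNA suffix (bounded by the 20% non-A allowance).
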