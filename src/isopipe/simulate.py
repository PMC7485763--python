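"""Synthetic long-read generator with planted truth.

Emulates the structure of multi-pass circular-consensus sequencing of a
size-selected cDNA library: each sequencing reaction yields one *polymerase
read* containing ``n_passes`` copies of the insert construct

    5' primer + cDNA + poly-A + revcomp(3' primer)

separated by adapter sequences.  Per-pass errors are indel-dominant
(default 55% insertion / 30% deletion / 15% substitution), characteristic
of the long-read chemistry; accuracy of the per-read consensus therefore
rises with pass count.  A configurable fraction of reads are artificial
concatemers (chimeras) joining two inserts with an internal primer copy.

Planted features per gene — a skipped-exon isoform pair (the "AS" truth),
one SSR per period class, and an ATG..stop ORF with hexamer/codon bias —
give every downstream caller a measurable recall surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import SeqRecord, revcomp, write_fasta, write_feature_table

# Two distinct 25-mers (edit distance > 10) standing in for the proprietary
# kit primers; detection logic, not the exact sequence, is what matters.
DEFAULT_PRIMER5 = "AAGCAGTGGTATCAACGCAGAGTAC"
DEFAULT_PRIMER3 = "GTACTCTGCGTTGCCACCGTATCAA"
DEFAULT_ADAPTER = "ATCTCTCTCTTTTCCTCCTCCTCCGTTGTTGTTGTTGAGAGAGAT"

# Moderately biased plant-like codon weights (relative, stops excluded):
# enough bias that coding hexamer composition separates from uniform DNA.
_CODON_WEIGHTS = {
    "GCT": 28, "GCA": 22, "GCC": 12, "GCG": 6,
    "GAA": 30, "GAG": 24, "GAT": 32, "GAC": 14,
    "AAA": 26, "AAG": 30, "CGT": 8, "AGA": 16,
    "TTT": 18, "TTC": 16, "CTT": 20, "CTC": 12,
    "ATT": 22, "ATC": 14, "ATG": 18, "GTT": 20,
    "GTG": 14, "TCT": 18, "TCA": 14, "AGC": 8,
    "CCT": 16, "CCA": 18, "ACT": 16, "ACA": 16,
    "GGT": 20, "GGA": 22, "CAA": 20, "CAG": 14,
    "CAT": 12, "CAC": 8, "TAT": 12, "TAC": 8,
    "AAT": 20, "AAC": 14, "TGG": 8, "TGT": 6,
}
STOP_CODONS = ("TAA", "TAG", "TGA")

# One primitive motif per SSR period class, cycled across planted genes.
_SSR_MOTIFS = ["A", "AG", "AAG", "AAGG", "AAGGC", "AAGGCC"]
# Repeat counts comfortably above the period minima (10/6/5/5/5/5).
_SSR_REPEATS = [14, 9, 7, 6, 6, 6]

LIBRARY_BINS = (("1-2kb", 0, 2000), ("2-3kb", 2000, 3000), ("3-6kb", 3000, 10**9))


def library_bin(insert_len: int) -> str:
    for name, lo, hi in LIBRARY_BINS:
        if lo <= insert_len < hi:
            return name
    return LIBRARY_BINS[-1][0]


@dataclass
class PlantedSSR:
    motif: str
    n_repeats: int
    start: int  # 0-based on the isoform

    @property
    def end(self) -> int:
        return self.start + len(self.motif) * self.n_repeats


@dataclass
class PlantedORF:
    start: int  # 0-based, position of the ATG
    end: int    # 0-based half-open, excludes the stop codon
    frame: int


@dataclass
class GeneModelTruth:
    """One gene with 1–2 isoforms and its planted feature annotations."""

    gene_id: str
    isoforms: dict[str, str]
    skipped_block: tuple[int, int] | None = None  # (start, length) on the long isoform
    ssr: PlantedSSR | None = None
    orf: PlantedORF | None = None

    @property
    def is_as_pair(self) -> bool:
        return len(self.isoforms) == 2 and self.skipped_block is not None


@dataclass
class SimulatedRead:
    read_id: str
    true_isoform_id: str
    sequence: str          # the full polymerase read
    insert: str            # error-free insert construct
    cdna: str              # error-free cDNA (no primers/poly-A)
    n_passes: int
    true_accuracy: float   # 1 - per-pass error rate of this read
    is_chimera: bool
    library_bin: str


class GenerationError(ValueError):
    """Raised when requested constraints cannot be satisfied."""


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _biased_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = list(_CODON_WEIGHTS)
    w = np.array([_CODON_WEIGHTS[c] for c in codons], dtype=float)
    w /= w.sum()
    body = "".join(rng.choice(codons, size=n_codons, p=w))
    return "ATG" + body + str(rng.choice(STOP_CODONS))


def _junction_barrier(rng: np.random.Generator, context: str, k: int = 10) -> str:
    """A ``k``-mer with at most 2 matches against every length-``k`` window
    of ``context``, so no alignment shift can pair it with the flank."""
    windows = [context[i : i + k] for i in range(max(1, len(context) - k + 1))]
    while True:
        cand = _random_dna(rng, k)
        if all(
            sum(a == b for a, b in zip(cand, w)) <= 2
            for w in windows
            if len(w) == k
        ):
            return cand


def generate_gene_models(
    n_genes: int,
    as_fraction: float = 0.3,
    ssr_fraction: float = 0.5,
    orf_fraction: float = 0.5,
    length_range: tuple[int, int] = (500, 6000),
    seed: int = 0,
) -> list[GeneModelTruth]:
    """Generate gene models with exactly ``round(fraction * n_genes)`` genes
    carrying each planted feature class.  Deterministic given ``seed``.

    AS genes get a second isoform with a contiguous block of length
    U[110, 400] bp removed, at least 120 bp from both transcript ends, so
    planted events satisfy the caller's gap/end thresholds by construction.
    """
    for name, frac in (("as", as_fraction), ("ssr", ssr_fraction), ("orf", orf_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise GenerationError(f"{name}_fraction must be in [0,1], got {frac}")
    lo, hi = length_range
    if lo < 350:
        raise GenerationError(
            f"minimum transcript length {lo} cannot host an AS block "
            "(needs >= 110 + 2*120 bp)"
        )
    rng = np.random.default_rng(seed)
    n_as = int(round(n_genes * as_fraction))
    n_ssr = int(round(n_genes * ssr_fraction))
    n_orf = int(round(n_genes * orf_fraction))
    idx = np.arange(n_genes)
    as_genes = set(rng.choice(idx, size=n_as, replace=False)) if n_as else set()
    ssr_genes = set(rng.choice(idx, size=n_ssr, replace=False)) if n_ssr else set()
    orf_genes = set(rng.choice(idx, size=n_orf, replace=False)) if n_orf else set()

    models: list[GeneModelTruth] = []
    ssr_cycle = 0
    for g in range(n_genes):
        gid = f"gene{g:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_dna(rng, length)

        orf = None
        if g in orf_genes:
            max_codons = max(101, (length - 6) // 3 - 2)
            n_codons = int(rng.integers(101, min(max_codons, 400) + 1))
            cds = _biased_cds(rng, n_codons)
            if len(cds) + 20 > length:
                length = len(cds) + 200
                seq = _random_dna(rng, length)
            start = int(rng.integers(0, length - len(cds) + 1))
            # plant in frame; remove in-frame premature ATG-upstream stops is
            # unnecessary: the planted ORF itself is stop-free by construction
            seq = seq[:start] + cds + seq[start + len(cds):]
            orf = PlantedORF(start=start, end=start + len(cds) - 3, frame=start % 3)

        ssr = None
        if g in ssr_genes:
            period = ssr_cycle % 6
            ssr_cycle += 1
            motif = _SSR_MOTIFS[period]
            nrep = _SSR_REPEATS[period]
            tract = motif * nrep
            # keep the SSR clear of the planted ORF
            zone_lo, zone_hi = 20, length - len(tract) - 20
            if orf is not None and orf.start > len(tract) + 60:
                zone_hi = orf.start - len(tract) - 10
            if zone_hi <= zone_lo:
                zone_lo, zone_hi = length - len(tract) - 40, length - len(tract) - 20
            start = int(rng.integers(zone_lo, zone_hi + 1))
            # planted motifs are T-free, so a T on each side terminates the
            # tract and cannot seed a unit extension in either direction
            seq = seq[: start - 1] + "T" + tract + "T" + seq[start + len(tract) + 1:]
            ssr = PlantedSSR(motif=motif, n_repeats=nrep, start=start)

        isoforms = {f"{gid}.1": seq}
        skipped = None
        if g in as_genes:
            max_block = min(400, len(seq) - 240)
            if max_block < 110:
                raise GenerationError(
                    f"{gid}: transcript of {len(seq)} bp cannot host an AS block"
                )
            block_len = int(rng.integers(110, max_block + 1))
            bstart = int(rng.integers(120, len(seq) - block_len - 120 + 1))
            # junction-proofing: replace the block's first/last 10 bases with
            # barriers dissimilar to the flanking continuation under every
            # small alignment shift, so a local aligner cannot extend either
            # HSP across the junction (with or without gap wobble) — planted
            # events then satisfy the two-HSP overlap rule by construction
            right_flank = seq[bstart + block_len - 3 : bstart + block_len + 13]
            left_flank = seq[bstart - 13 : bstart + 3]
            seq = (
                seq[:bstart]
                + _junction_barrier(rng, right_flank)
                + seq[bstart + 10 : bstart + block_len - 10]
                + _junction_barrier(rng, left_flank)
                + seq[bstart + block_len :]
            )
            isoforms[f"{gid}.1"] = seq
            isoforms[f"{gid}.2"] = seq[:bstart] + seq[bstart + block_len:]
            skipped = (bstart, block_len)

        models.append(
            GeneModelTruth(
                gene_id=gid, isoforms=isoforms,
                skipped_block=skipped, ssr=ssr, orf=orf,
            )
        )
    return models


def apply_errors(seq: str, error_rate: float, rng: np.random.Generator,
                 mix: tuple[float, float, float] = (0.55, 0.30, 0.15)) -> str:
    """Apply indel-dominant errors: per-base error probability ``error_rate``
    split as ``mix`` = (insertion, deletion, substitution)."""
    if error_rate <= 0:
        return seq
    n = len(seq)
    err = rng.random(n) < error_rate
    if not err.any():
        return seq
    kinds = rng.choice(3, size=int(err.sum()), p=mix)
    bases = "ACGT"
    out: list[str] = []
    k = 0
    for i, ch in enumerate(seq):
        if not err[i]:
            out.append(ch)
            continue
        kind = kinds[k]
        k += 1
        if kind == 0:  # insertion before the base
            out.append(bases[rng.integers(4)])
            out.append(ch)
        elif kind == 1:  # deletion
            continue
        else:  # substitution
            out.append(bases[(bases.index(ch) + 1 + rng.integers(3)) % 4]
                       if ch in bases else ch)
    return "".join(out)


def simulate_reads(
    models: Sequence[GeneModelTruth],
    reads_per_isoform: int = 10,
    error_rate: float = 0.05,
    passes_geometric_p: float = 0.2,
    chimera_rate: float = 0.02,
    primer5: str = DEFAULT_PRIMER5,
    primer3: str = DEFAULT_PRIMER3,
    adapter: str = DEFAULT_ADAPTER,
    polyA_len: int = 30,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Simulate polymerase reads for every isoform of every model.

    Each read's per-pass error rate is jittered by U[0.5, 1.5] around
    ``error_rate`` so the raw-read accuracy filter has work to do;
    ``true_accuracy`` records 1 minus the read's own per-pass rate.
    """
    if not 0.0 <= error_rate <= 0.2:
        raise GenerationError(f"error_rate must be in [0, 0.2], got {error_rate}")
    if not primer5 or not primer3:
        raise GenerationError("primers must be non-empty")
    rng = np.random.default_rng(seed)
    isoforms = [(iso_id, seq) for m in models for iso_id, seq in m.isoforms.items()]
    reads: list[SimulatedRead] = []
    rid = 0
    for iso_id, cdna in isoforms:
        for _ in range(reads_per_isoform):
            chimera = bool(rng.random() < chimera_rate)
            if chimera:
                other_id, other = isoforms[int(rng.integers(len(isoforms)))]
                insert = (
                    primer5 + cdna + "A" * polyA_len + revcomp(primer3)
                    + primer5 + other + "A" * polyA_len + revcomp(primer3)
                )
            else:
                insert = primer5 + cdna + "A" * polyA_len + revcomp(primer3)
            n_passes = int(rng.geometric(passes_geometric_p))
            rate = error_rate * float(rng.uniform(0.5, 1.5)) if error_rate else 0.0
            passes = [apply_errors(insert, rate, rng) for _ in range(n_passes)]
            poly = adapter.join(passes)
            reads.append(
                SimulatedRead(
                    read_id=f"read{rid:06d}",
                    true_isoform_id=iso_id,
                    sequence=poly,
                    insert=insert,
                    cdna=cdna,
                    n_passes=n_passes,
                    true_accuracy=1.0 - rate,
                    is_chimera=chimera,
                    library_bin=library_bin(len(insert)),
                )
            )
            rid += 1
    return reads


def reads_to_fasta(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """Write polymerase reads as FASTA; pass count, accuracy and bin ride in
    the description so the ROI stage can recover them without a truth file."""
    write_fasta(
        (
            SeqRecord(
                id=r.read_id,
                sequence=r.sequence,
                description=(
                    f"np={r.n_passes} acc={r.true_accuracy:.4f} bin={r.library_bin}"
                ),
            )
            for r in reads
        ),
        path,
    )


def write_truth(models: Sequence[GeneModelTruth],
                reads: Sequence[SimulatedRead],
                outdir: str | Path) -> dict[str, Path]:
    """Write tab-separated truth tables (reads, AS pairs, SSRs, ORFs).

    Coordinates are emitted 1-based inclusive.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["reads"] = outdir / "truth_reads.tsv"
    write_feature_table(
        (
            (r.read_id, r.true_isoform_id, r.n_passes, f"{r.true_accuracy:.4f}",
             int(r.is_chimera), r.library_bin, len(r.cdna))
            for r in reads
        ),
        ("read_id", "isoform_id", "n_passes", "accuracy", "is_chimera",
         "library_bin", "cdna_len"),
        paths["reads"],
    )

    paths["as_pairs"] = outdir / "truth_as_pairs.tsv"
    write_feature_table(
        (
            (m.gene_id, f"{m.gene_id}.1", f"{m.gene_id}.2",
             m.skipped_block[0] + 1, m.skipped_block[0] + m.skipped_block[1],
             m.skipped_block[1])
            for m in models if m.is_as_pair
        ),
        ("gene_id", "long_isoform", "short_isoform",
         "block_start", "block_end", "block_len"),
        paths["as_pairs"],
    )

    paths["ssrs"] = outdir / "truth_ssrs.tsv"
    write_feature_table(
        (
            (m.gene_id, m.ssr.motif, m.ssr.n_repeats,
             m.ssr.start + 1, m.ssr.end)
            for m in models if m.ssr is not None
        ),
        ("gene_id", "motif", "n_repeats", "start", "end"),
        paths["ssrs"],
    )

    paths["orfs"] = outdir / "truth_orfs.tsv"
    write_feature_table(
        (
            (m.gene_id, m.orf.start + 1, m.orf.end, m.orf.frame)
            for m in models if m.orf is not None
        ),
        ("gene_id", "start", "end", "frame"),
        paths["orfs"],
    )
    return paths
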