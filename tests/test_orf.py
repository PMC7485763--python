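"""ORF enumeration vs an independent translate-based oracle, hexamer model
closed forms, CDS selection on planted codon-biased ORFs."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from isopipe import simulate as sim
from isopipe.io_formats import revcomp
from isopipe.orf import (
    cds_length_histogram,
    find_orfs,
    mean_hexamer_score,
    orf_sequence,
    select_cds,
    self_train_model,
    train_hexamer_model,
)


def oracle_orfs(seq, min_aa=100):
    """Independent oracle: translate each of the six frames with Biopython,
    split the protein on stops, and map qualifying segments back to
    nucleotide coordinates."""
    seq = seq.upper()
    n = len(seq)
    out = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            usable = s[frame : frame + (n - frame) // 3 * 3]
            prot = str(Seq(usable).translate())
            pos = 0  # codon index of current segment start
            for seg_i, segment in enumerate(prot.split("*")):
                stopped = seg_i < prot.count("*") + 0 and (
                    pos + len(segment) < len(prot)
                )
                m = segment.find("M")
                if m >= 0:
                    start_codon = pos + m
                    comp = "complete" if stopped else "3prime_partial"
                elif pos == 0:
                    start_codon = 0
                    comp = "5prime_partial" if stopped else "internal"
                else:
                    start_codon = None
                if start_codon is not None:
                    aa = pos + len(segment) - start_codon
                    if aa >= min_aa:
                        a = frame + 3 * start_codon
                        b = frame + 3 * (pos + len(segment))
                        if strand == "+":
                            out.add((a, b, "+", comp))
                        else:
                            out.add((n - b, n - a, "-", comp))
                pos += len(segment) + 1
    return out


class TestFindOrfs:
    def test_constructed_complete_orf(self):
        seq = "ATG" + "GCT" * 100 + "TAA"
        complete = [o for o in find_orfs(seq) if o.completeness == "complete"]
        (o,) = complete
        assert (o.start, o.end, o.strand, o.length_nt) == (0, 303, "+", 303)

    def test_internal_orf_without_atg_or_stop(self):
        seq = "GCT" * 110  # no ATG, no stop in frame 0
        internal = [o for o in find_orfs(seq, both_strands=False)
                    if o.completeness == "internal" and o.frame == 0]
        assert internal and internal[0].start == 0

    def test_matches_oracle_on_random_sequences(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), 5000))
            got = {(o.start, o.end, o.strand, o.completeness)
                   for o in find_orfs(seq, min_aa=100)}
            assert got == oracle_orfs(seq, min_aa=100)

    def test_matches_oracle_at_smaller_min_aa(self, rng):
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), 1200))
            got = {(o.start, o.end, o.strand, o.completeness)
                   for o in find_orfs(seq, min_aa=30)}
            assert got == oracle_orfs(seq, min_aa=30)

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 2000))
            fwd = {(o.start, o.end, o.strand) for o in find_orfs(seq, min_aa=50)}
            n = len(seq)
            flipped = {
                (n - e, n - s, "+" if strand == "-" else "-")
                for s, e, strand in fwd
            }
            rev = {(o.start, o.end, o.strand)
                   for o in find_orfs(revcomp(seq), min_aa=50)}
            assert rev == flipped


class TestHexamerModel:
    def test_identical_corpora_give_all_zero(self):
        model = train_hexamer_model(["ACGTTG" * 60], background_seqs=["ACGTTG" * 60])
        assert all(abs(v) < 1e-12 for v in model.values())

    def test_twofold_enrichment_is_one_bit(self):
        """A hexamer twice as frequent in coding as in background scores
        log2(2) = 1 bit (corpora large enough that smoothing is negligible)."""
        cod = ["A" * 60005, "C" * 60005]              # AAAAAA frequency 1/2
        bg = ["A" * 60005] + ["C" * 60005] * 3        # AAAAAA frequency 1/4
        model = train_hexamer_model(cod, background_seqs=bg)
        assert abs(model["AAAAAA"] - 1.0) < 0.05

    def test_shuffled_background_deterministic(self):
        seqs = ["ATGGCTGCTGAA" * 40]
        a = train_hexamer_model(seqs, seed=3)
        b = train_hexamer_model(seqs, seed=3)
        assert a == b


@pytest.fixture(scope="module")
def trained():
    models = sim.generate_gene_models(
        120, as_fraction=0, ssr_fraction=0, orf_fraction=1.0,
        length_range=(600, 1800), seed=41,
    )
    tx = [(m.gene_id, m.isoforms[m.gene_id + ".1"]) for m in models]
    return models, tx, self_train_model(tx, seed=42)


class TestSelectCds:
    def test_planted_orf_recovered(self, trained):
        models, tx, model = trained
        hits = 0
        for m, (tid, seq) in zip(models, tx):
            best = select_cds(seq, find_orfs(seq, tid), model)
            if best is None:
                continue
            tr = m.orf
            ov = max(0, min(best.end, tr.end) - max(best.start, tr.start))
            if ov >= 0.9 * (tr.end - tr.start):
                hits += 1
        assert hits >= 0.9 * len(models)

    def test_random_dna_rarely_selected(self, trained, rng):
        _, _, model = trained
        fp = 0
        n = 200
        for _ in range(n):
            seq = "".join(rng.choice(list("ACGT"), 600))
            if select_cds(seq, find_orfs(seq), model) is not None:
                fp += 1
        assert fp < 0.1 * n

    def test_higher_scoring_complete_orf_wins(self):
        """Two equal-length complete ORFs: the one the model scores higher
        is selected."""
        from isopipe.orf import ALL_HEXAMERS

        orf_a = "ATG" + "GCT" * 100 + "TAA"   # scores high under the model
        orf_b = "ATG" + "GAA" * 100 + "TAA"   # scores low
        seq = orf_a + "TTTT" + orf_b
        model = {h: 0.0 for h in ALL_HEXAMERS}
        for h in ALL_HEXAMERS:
            if "GCT" in h:
                model[h] = 2.0
            elif "GAA" in h:
                model[h] = 0.1
        best = select_cds(seq, find_orfs(seq), model)
        assert (best.start, best.end) == (0, 303)


class TestHistogram:
    def test_empty(self):
        assert cds_length_histogram([]) == {}

    def test_binning(self):
        from isopipe.orf import ORFRecord

        orfs = [
            ORFRecord("a", 0, 303, "+", 0, "complete"),
            ORFRecord("b", 0, 303, "+", 0, "complete"),
            ORFRecord("c", 0, 450, "+", 0, "complete"),
            ORFRecord("d", 0, 450, "+", 0, "3prime_partial"),  # excluded
        ]
        assert cds_length_histogram(orfs) == {300: 2, 400: 1}

    def test_planted_lengths(self, rng):
        models = sim.generate_gene_models(
            40, as_fraction=0, ssr_fraction=0, orf_fraction=1.0,
            length_range=(600, 1500), seed=43,
        )
        tx = [(m.gene_id, m.isoforms[m.gene_id + ".1"]) for m in models]
        model = self_train_model(tx, seed=44)
        selected = [select_cds(s, find_orfs(s, t), model) for t, s in tx]
        hist = cds_length_histogram([s for s in selected if s is not None])
        assert sum(hist.values()) == sum(
            1 for s in selected if s is not None and s.completeness == "complete"
        )
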