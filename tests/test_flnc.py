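"""Primer/poly-A detection, FLNC classification and Table-style summaries."""

import pytest

from isopipe import simulate as sim
from isopipe.flnc import (
    FlncBinRow,
    aggregate_flnc_bins,
    classify_read,
    detect_polya,
    detect_primer,
    summarize_flnc,
    truncate2,
)
from isopipe.io_formats import revcomp
from isopipe.roi import ROI

P5 = sim.DEFAULT_PRIMER5
P3 = sim.DEFAULT_PRIMER3


class TestDetectPrimer:
    def test_exact_hit_at_start(self, rng):
        tail = "".join(rng.choice(list("ACGT"), 200))
        hits = detect_primer(P5 + tail, P5)
        assert hits and hits[0].start == 0 and hits[0].edits == 0

    def test_two_edits_within_threshold(self, rng):
        mutated = "T" + P5[1:-1] + "G"  # 2 substitutions in a 25-mer
        tail = "".join(rng.choice(list("ACGT"), 200))
        hits = detect_primer(mutated + tail, P5)
        assert hits and hits[0].edits <= 5  # ceil(0.2*25) allowed

    def test_plant_and_recover_three_copies(self, rng):
        chunks = ["".join(rng.choice(list("ACGT"), 2500)) for _ in range(4)]
        seq = chunks[0] + P5 + chunks[1] + P5 + chunks[2] + P5 + chunks[3]
        hits = [h for h in detect_primer(seq, P5) if h.strand == "+"]
        assert len(hits) == 3

    def test_reverse_complement_detected(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300)) + revcomp(P5)
        hits = detect_primer(seq, P5)
        assert any(h.strand == "-" for h in hits)

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            detect_primer("ACGT" * 50, "ACGTACGTA")


class TestDetectPolya:
    def test_clean_tail(self):
        hit = detect_polya("C" * 200 + "A" * 25)
        assert (hit.start, hit.end) == (200, 225)

    def test_below_min_len_is_none(self):
        assert detect_polya("C" * 200 + "A" * 10) is None

    def test_tail_with_scattered_non_a(self, rng):
        tail = list("A" * 30)
        for p in [5, 11, 17, 23, 28]:
            tail[p] = "G"
        seq = "C" * 200 + "A" + "".join(tail) + "A"
        hit = detect_polya(seq)
        assert hit is not None and hit.length >= 25

    def test_tail_too_far_from_end_is_none(self):
        assert detect_polya("C" * 100 + "A" * 30 + "C" * 100) is None


def _clean_roi(cdna, rid="r", polya=30):
    seq = P5 + cdna + "A" * polya + revcomp(P3)
    return ROI(rid, seq, full_passes=3, read_quality=0.99)


class TestClassifyRead:
    def test_clean_read_is_flnc_and_trimmed_to_cdna(self, rng):
        cdna = "".join(rng.choice(list("CGT"), 800))  # A-free: trimming is exact
        c = classify_read(_clean_roi(cdna), P5, P3)
        assert c.full_length and c.is_flnc and not c.chimera
        assert c.sequence == cdna

    def test_antisense_read_is_oriented(self, rng):
        cdna = "".join(rng.choice(list("CGT"), 800))
        roi = _clean_roi(cdna)
        roi.sequence = revcomp(roi.sequence)
        c = classify_read(roi, P5, P3)
        assert c.strand == "-" and c.is_flnc
        assert c.sequence == cdna

    def test_missing_3p_primer_is_non_fl(self, rng):
        cdna = "".join(rng.choice(list("CGT"), 800))
        roi = ROI("r", P5 + cdna + "A" * 30, 3, 0.99)
        c = classify_read(roi, P5, P3)
        assert not c.has3p and not c.full_length

    def test_simulated_chimera_is_fl_but_flagged(self, rng):
        a = "".join(rng.choice(list("CGT"), 1400))
        b = "".join(rng.choice(list("CGT"), 1400))
        roi = ROI("r", P5 + a + "A" * 30 + revcomp(P3) + P5 + b + "A" * 30 + revcomp(P3),
                  3, 0.99)
        c = classify_read(roi, P5, P3)
        assert c.full_length and c.chimera and not c.is_flnc

    def test_simulated_reads_classified_against_truth(self, small_models):
        reads = sim.simulate_reads(small_models, reads_per_isoform=2,
                                   error_rate=0.0, chimera_rate=0.0, seed=13)
        for r in reads:
            roi = ROI(r.read_id, r.insert, r.n_passes, 1.0)
            c = classify_read(roi, P5, P3)
            assert c.is_flnc
            # the poly-A boundary is tolerance-driven (20% non-A allowed),
            # so trimming may absorb a short A-rich cDNA suffix
            assert r.cdna.startswith(c.sequence)
            assert len(r.cdna) - len(c.sequence) <= 40


class TestSummary:
    def test_published_all_row_arithmetic(self):
        rows = [
            FlncBinRow("1-2kb", 60768, 29868, 34965, 35769, 5344, 30620,
                       24804, 24719, 35410268, 0, 0.0, 0.0),
            FlncBinRow("2-3kb", 82481, 67290, 69380, 68092, 939, 22155,
                       59387, 59167, 151411494, 0, 0.0, 0.0),
            FlncBinRow("3-6kb", 72387, 48656, 51394, 49502, 810, 33665,
                       37912, 37768, 130361660, 0, 0.0, 0.0),
        ]
        allr = aggregate_flnc_bins(rows)
        assert allr.fl_pct == 56.62            # 122103/215636, FL incl. chimeras
        assert allr.avg_flnc_len == 2607       # floor(317183422/121654)
        assert allr.concatemer_pct == 0.36     # truncate(449/122103*100)
        assert allr.n_fl == 122103 and allr.n_flnc == 121654

    @pytest.mark.parametrize(
        "row,avg,flpct,conc",
        [
            (0, 1432, 40.82, 0.34),
            (1, 2559, 72.00, 0.37),
        ],
    )
    def test_published_bin_rows(self, row, avg, flpct, conc):
        rows = [
            FlncBinRow("1-2kb", 60768, 29868, 34965, 35769, 5344, 30620,
                       24804, 24719, 35410268, 0, 0.0, 0.0),
            FlncBinRow("2-3kb", 82481, 67290, 69380, 68092, 939, 22155,
                       59387, 59167, 151411494, 0, 0.0, 0.0),
        ]
        one = aggregate_flnc_bins([rows[row]])
        assert one.avg_flnc_len == avg
        assert one.fl_pct == flpct
        assert one.concatemer_pct == conc

    def test_avg_length_uses_floor_not_round(self):
        # 130361660/37768 = 3451.64..., printed as 3451
        r = FlncBinRow("3-6kb", 72387, 0, 0, 0, 0, 0, 37912, 37768,
                       130361660, 0, 0.0, 0.0)
        assert aggregate_flnc_bins([r]).avg_flnc_len == 3451

    def test_concatemer_zero_when_fl_equals_flnc(self):
        r = FlncBinRow("1-2kb", 10, 0, 0, 0, 0, 0, 5, 5, 5000, 0, 0.0, 0.0)
        assert aggregate_flnc_bins([r]).concatemer_pct == 0.00

    def test_truncation_semantics(self):
        assert truncate2(0.3677) == 0.36
        assert truncate2(0.3798) == 0.37

    def test_partition_invariant_on_simulated_data(self, small_models):
        reads = sim.simulate_reads(small_models, reads_per_isoform=3,
                                   error_rate=0.04, chimera_rate=0.1, seed=14)
        classified = []
        for r in reads:
            roi = ROI(r.read_id, r.insert, r.n_passes, 0.95,
                      library_bin=r.library_bin)
            classified.append(classify_read(roi, P5, P3))
        s = summarize_flnc(classified)
        for row in s.bins + [s.all_row]:
            assert row.n_roi == row.n_fl + row.n_nonfl + row.n_filtered_short
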