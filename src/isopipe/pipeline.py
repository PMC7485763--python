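"""End-to-end orchestration: raw reads -> ROI -> FLNC -> clusters ->
non-redundant transcripts -> {AS, SSR, ORF, lncRNA} feature tables.

Every stage logs a read-count ledger to stderr; all outputs are
deterministic given the configuration seed.  Summary tables mirror the
published layouts (ROI statistics, FL statistics, clustering statistics,
SSR statistics).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import cluster as cluster_mod
from . import flnc as flnc_mod
from . import lncrna as lncrna_mod
from . import orf as orf_mod
from . import roi as roi_mod
from . import splicing, ssr as ssr_mod
from .io_formats import SeqRecord, write_fasta, write_feature_table
from .roi import PolymeraseRead
from .simulate import DEFAULT_ADAPTER, DEFAULT_PRIMER5, DEFAULT_PRIMER3

log = logging.getLogger("isopipe")


@dataclass
class PipelineConfig:
    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    adapter: str = DEFAULT_ADAPTER
    min_read_len: int = 50
    min_read_acc: float = 0.8
    min_roi_quality: float = 0.8
    primer_max_edit_frac: float = 0.2
    polya_min_len: int = 20
    cluster_min_identity: float = 0.90
    cluster_min_coverage: float = 0.90
    dedup_identity: float = 0.99
    as_max_overlap: int = 5
    as_min_gap: int = 100
    as_min_end_dist: int = 100
    as_min_pair_coverage: float = 0.90
    ssr_min_transcript_len: int = 500
    orf_min_aa: int = 100
    lncrna_min_len: int = 200
    seed: int = 0
    outdir: str = "pipeline_out"

    def validate(self) -> None:
        if not (0.0 <= self.min_read_acc <= 1.0 and 0.0 <= self.min_roi_quality <= 1.0):
            raise ValueError("accuracy thresholds must be in [0,1]")
        if not self.primer5 or not self.primer3:
            raise ValueError("primers must be non-empty")
        for name in ("cluster_min_identity", "cluster_min_coverage",
                     "dedup_identity", "as_min_pair_coverage",
                     "primer_max_edit_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    rois: list
    classified: list
    consensi: list
    transcripts: list[tuple[str, str]]
    as_events: list
    ssrs: list
    selected_cds: dict[str, object]
    lncrna_verdicts: list
    venn: dict[str, int]


def run_pipeline(config: PipelineConfig, reads: Sequence[PolymeraseRead]) -> PipelineResult:
    config.validate()
    if not reads:
        raise RuntimeError("roi stage: empty read set")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- ROI stage -------------------------------------------------------
    rois = roi_mod.rois_from_reads(
        reads, config.adapter,
        min_len=config.min_read_len, min_acc=config.min_read_acc,
    )
    log.info("roi: %d polymerase reads -> %d ROIs", len(reads), len(rois))
    if not rois:
        raise RuntimeError("roi stage: no ROI passed the quality filter")
    roi_summary = roi_mod.summarize_rois(rois)
    _write_roi_table(roi_summary, outdir / "roi_summary.tsv")
    write_fasta((SeqRecord(r.read_id, r.sequence) for r in rois),
                outdir / "rois.fasta")

    # --- FLNC stage ------------------------------------------------------
    classified = [
        flnc_mod.classify_read(
            r, config.primer5, config.primer3,
            max_edit_frac=config.primer_max_edit_frac,
            polya_min_len=config.polya_min_len,
        )
        for r in rois
    ]
    flnc_reads = [c for c in classified if c.is_flnc and c.trimmed_len >= 50]
    nonfl = [c for c in classified if not c.full_length and c.trimmed_len >= 50]
    log.info("flnc: %d ROIs -> %d FLNC, %d non-FL", len(classified),
             len(flnc_reads), len(nonfl))
    flnc_summary = flnc_mod.summarize_flnc(classified)
    _write_flnc_table(flnc_summary, outdir / "flnc_summary.tsv")
    write_fasta((SeqRecord(c.read_id, c.sequence) for c in flnc_reads),
                outdir / "flnc.fasta")
    if not flnc_reads:
        raise RuntimeError("cluster stage: no FLNC reads")

    # --- clustering / polishing / dedup ---------------------------------
    seqs = [c.sequence for c in flnc_reads]
    clusters = cluster_mod.ice_cluster(
        seqs, min_identity=config.cluster_min_identity,
        min_coverage=config.cluster_min_coverage,
    )
    nonfl_seqs = [c.sequence for c in nonfl]
    consensi = [
        cluster_mod.polish(cl, seqs, nonfl_seqs,
                           min_identity=config.cluster_min_identity,
                           min_coverage=config.cluster_min_coverage)
        for cl in clusters
    ]
    csum = cluster_mod.classify_quality(consensi)
    log.info("cluster: %d FLNC -> %d consensi (%d HQ)", len(seqs),
             csum.n_consensus, csum.n_hq)
    _write_cluster_table(csum, outdir / "cluster_summary.tsv")
    named = [(f"isoform{c.cluster_id:05d}", c.sequence) for c in consensi]
    transcripts = cluster_mod.dedup(named, identity=config.dedup_identity)
    log.info("dedup: %d consensi -> %d non-redundant transcripts",
             len(named), len(transcripts))
    write_fasta((SeqRecord(t, s) for t, s in transcripts),
                outdir / "transcripts.fasta")

    # --- feature stages --------------------------------------------------
    tx_records = [SeqRecord(t, s) for t, s in transcripts]
    lengths = {t: len(s) for t, s in transcripts}
    as_events: list = []
    if len(tx_records) >= 2:
        hsps = splicing.pairwise_hsps(tx_records)
        raw_events = splicing.call_as_events(
            hsps, lengths,
            max_overlap=config.as_max_overlap, min_gap=config.as_min_gap,
            min_end_dist=config.as_min_end_dist,
            min_pair_coverage=config.as_min_pair_coverage,
        )
        _, as_events = splicing.as_summary(raw_events)
    log.info("as: %d events", len(as_events))
    write_feature_table(
        ((e.continuous_id, e.gapped_id, e.gap_start, e.gap_end, e.gap_len,
          e.overlap_or_gap_on_continuous, e.orientation) for e in as_events),
        ("continuous_id", "gapped_id", "gap_start", "gap_end", "gap_len",
         "overlap_on_continuous", "orientation"),
        outdir / "as_events.tsv",
    )

    examined = ssr_mod.select_ssr_input(transcripts, config.ssr_min_transcript_len)
    ssrs: list = []
    for tid, seq in examined:
        ssrs.extend(ssr_mod.find_ssrs(seq, tid))
    ssrs = ssr_mod.group_compound(ssrs)
    ssr_summary = ssr_mod.summarize_ssrs(ssrs, examined)
    log.info("ssr: %d SSRs on %d/%d transcripts", ssr_summary.n_ssr,
             ssr_summary.n_seq_with_ssr, len(examined))
    write_feature_table(
        ((s.transcript_id, s.motif, s.n_repeats, s.start + 1, s.end,
          s.compound_group if s.compound_group is not None else ".")
         for s in ssrs),
        ("transcript_id", "motif", "n_repeats", "start", "end", "compound_group"),
        outdir / "ssrs.tsv",
    )
    _write_ssr_table(ssr_summary, outdir / "ssr_summary.tsv")

    model = orf_mod.self_train_model(transcripts, min_aa=config.orf_min_aa,
                                     seed=config.seed)
    orfs_by_tx = {tid: orf_mod.find_orfs(seq, tid, min_aa=config.orf_min_aa)
                  for tid, seq in transcripts}
    selected: dict[str, object] = {}
    for tid, seq in transcripts:
        best = orf_mod.select_cds(seq, orfs_by_tx[tid], model)
        if best is not None:
            selected[tid] = best
    log.info("orf: %d transcripts with a selected CDS", len(selected))
    write_feature_table(
        ((tid, o.start + 1, o.end, o.strand, o.frame, o.completeness,
          f"{o.ll_score:.4f}") for tid, o in selected.items()),
        ("transcript_id", "start", "end", "strand", "frame", "completeness",
         "ll_score"),
        outdir / "cds.tsv",
    )

    verdicts, venn = lncrna_mod.classify_lncrna(
        transcripts, orfs_by_tx, model, min_len=config.lncrna_min_len,
    )
    n_lnc = sum(1 for v in verdicts if v.final)
    log.info("lncrna: %d candidates called lncRNA", n_lnc)
    write_feature_table(
        ((v.transcript_id, v.length_nt,
          f"{v.scores.get('fickett', float('nan')):.4f}",
          f"{v.scores.get('hexamer', float('nan')):.4f}",
          f"{v.scores.get('orf_coverage', float('nan')):.4f}",
          int(v.final)) for v in verdicts),
        ("transcript_id", "length", "fickett", "hexamer", "orf_coverage",
         "is_lncrna"),
        outdir / "lncrna.tsv",
    )
    write_feature_table(sorted(venn.items()), ("methods", "count"),
                        outdir / "venn.tsv")

    return PipelineResult(
        rois=rois, classified=classified, consensi=consensi,
        transcripts=transcripts, as_events=as_events, ssrs=ssrs,
        selected_cds=selected, lncrna_verdicts=verdicts, venn=venn,
    )


# --- table renderers -----------------------------------------------------

def _write_roi_table(summary, path) -> None:
    cols = ("cDNA_size", "reads_of_insert", "total_bases", "mean_length",
            "mean_quality", "mean_passes")
    rows = [
        (r.bin_name, r.n_reads, r.total_bases, f"{r.mean_length:.2f}",
         f"{r.mean_quality:.2f}", r.mean_passes)
        for r in summary.bins + ([summary.all_row] if summary.all_row else [])
    ]
    write_feature_table(rows, cols, path)


def _write_flnc_table(summary, path) -> None:
    cols = ("cDNA_size", "reads_of_insert", "n_5p", "n_3p", "n_polyA",
            "n_filtered_short", "n_non_full_length", "n_full_length",
            "n_flnc", "flnc_bases", "avg_flnc_len", "FL_pct", "concatemer_pct")
    rows = [
        (r.bin_name, r.n_roi, r.n_5p, r.n_3p, r.n_polya, r.n_filtered_short,
         r.n_nonfl, r.n_fl, r.n_flnc, r.flnc_bases, r.avg_flnc_len,
         f"{r.fl_pct:.2f}", f"{r.concatemer_pct:.2f}")
        for r in summary.bins + ([summary.all_row] if summary.all_row else [])
    ]
    write_feature_table(rows, cols, path)


def _write_cluster_table(summary, path) -> None:
    write_feature_table(
        [(summary.n_consensus, summary.mean_consensus_len, summary.n_hq,
          summary.n_lq, f"{summary.pct_hq:.2f}")],
        ("n_consensus", "mean_consensus_len", "n_hq", "n_lq", "pct_hq"),
        path,
    )


def _write_ssr_table(summary, path) -> None:
    write_feature_table(
        [(summary.n_sequences_examined, summary.total_bases_examined,
          summary.n_ssr, summary.n_seq_with_ssr, summary.n_seq_with_gt1_ssr,
          summary.n_compound, *(summary.per_period[p] for p in range(1, 7)))],
        ("n_sequences_examined", "total_bases_examined", "n_ssr",
         "n_seq_with_ssr", "n_seq_with_gt1_ssr", "n_compound",
         "mono", "di", "tri", "tetra", "penta", "hexa"),
        path,
    )
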