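#!/usr/bin/env python
"""Trim, collapse and classify the discovery cohort's reads into isomiRs.

Consumes the FASTQ files from 01_simulate_cohorts.py, runs adapter
trimming + length filtering + read collapsing, anchors every unique read
on the hairpin reference and classifies it (mature / trimming /
elongation / 5' modification / NTA-X).  Writes per-sample call tables,
the isoform and summed count matrices, RPM matrices and the panel
miRNAs' read-length distributions to results/discovery/.
"""

import argparse
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from isomirev.isomir import AlignPolicy, call_sample, write_calls
from isomirev.preprocess import process_fastq
from isomirev.quantify import (
    build_matrices,
    cohort_length_distributions,
    rpm_normalize,
    write_matrix,
)
from isomirev.refdb import load_reference

PANEL = ("miR-21-5p", "miR-204-5p", "miR-375")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)  # only names the inputs
    args = ap.parse_args()

    cohorts = REPO / "results" / "cohorts"
    fastq_dir = REPO / "scratch" / "discovery_fastq"
    out = REPO / "results" / "discovery"
    out.mkdir(parents=True, exist_ok=True)

    ref = load_reference(cohorts / "hairpins.fa", cohorts / "matures.tsv")
    policy = AlignPolicy()

    callsets = []
    for fastq in sorted(fastq_dir.glob("*.fastq")):
        urs = process_fastq(fastq)
        cs = call_sample(urs, ref, policy)
        write_calls(cs, out / f"{cs.sample_id}.calls.tsv")
        print(
            f"{cs.sample_id}: {urs.n_raw} reads, {urs.n_unique} unique, "
            f"{len(cs.calls)} isomiRs, {cs.n_unaligned} unaligned"
        )
        callsets.append(cs)

    iso, summed = build_matrices(callsets)
    write_matrix(iso, out / "counts.isoform.tsv")
    write_matrix(summed, out / "counts.mature_summed.tsv")
    write_matrix(rpm_normalize(iso), out / "rpm.isoform.tsv")
    write_matrix(rpm_normalize(summed), out / "rpm.mature_summed.tsv")

    lengths = cohort_length_distributions(callsets, PANEL)
    lengths.to_csv(out / "length_distributions.tsv", sep="\t", index=False)
    print(
        f"matrices: {iso.data.shape[0]} isoforms / {summed.data.shape[0]} miRNAs "
        f"x {iso.data.shape[1]} samples -> {out}"
    )


if __name__ == "__main__":
    main()
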