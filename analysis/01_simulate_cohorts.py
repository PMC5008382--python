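#!/usr/bin/env python
"""Generate the two synthetic study cohorts.

Discovery: 4 control vs 9 cancer samples with FASTQ reads (written under
scratch/, they are bulky), planted with the panel's effects — the 23-nt
miR-204-like isoform up 3-fold in cancer, the trimmed miR-21/miR-375-like
isomiRs down 4-fold, and a 0.7x global miRNA yield in cancer.

Validation: 26 control vs 48 cancer samples measured by simulated
stem-loop qPCR (Ct tables) with lognormal PSA.

Tables go to results/cohorts/.  Everything is seed-deterministic.
"""

import argparse
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "src"))

from isomirev.qpcr import write_ct_table
from isomirev.refdb import write_reference
from isomirev.simulate import (
    SimConfig,
    make_toy_reference,
    simulate_cohort,
    simulate_qpcr,
    validation_config,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    out = REPO / "results" / "cohorts"
    out.mkdir(parents=True, exist_ok=True)
    fastq_dir = REPO / "scratch" / "discovery_fastq"

    disc_cfg = SimConfig(seed=args.seed)
    ref = make_toy_reference(seed=args.seed, n_mirnas=disc_cfg.n_mirnas)
    write_reference(ref, out / "hairpins.fa", out / "matures.tsv")

    discovery = simulate_cohort(disc_cfg, ref, out_dir=fastq_dir)
    discovery.truth.to_csv(out / "discovery_truth.tsv", sep="\t", index=False)
    discovery.clinical.to_csv(out / "discovery_clinical.tsv", sep="\t", index=False)
    discovery.groups.rename("group").to_csv(out / "discovery_groups.tsv", sep="\t")
    total_reads = discovery.truth["count"].sum()
    print(
        f"discovery: {len(discovery.sample_ids)} samples "
        f"(4 control / 9 cancer), {total_reads} reads -> {fastq_dir}"
    )

    val_cfg = validation_config(seed=args.seed)
    val_ref = make_toy_reference(seed=args.seed, n_mirnas=val_cfg.n_mirnas)
    validation = simulate_cohort(val_cfg, val_ref, emit_fastq=False)
    ct, clinical = simulate_qpcr(validation)
    write_ct_table(ct, out / "validation_ct.tsv")
    clinical.to_csv(out / "validation_clinical.tsv", sep="\t", index=False)
    validation.truth.to_csv(out / "validation_truth.tsv", sep="\t", index=False)
    print(
        f"validation: {len(validation.sample_ids)} samples "
        f"(26 control / 48 cancer), {ct.shape[0]} Ct measurements -> {out}"
    )


if __name__ == "__main__":
    main()
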