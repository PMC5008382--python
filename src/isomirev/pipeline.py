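"""Orchestrated entry points for the two study phases.

``run_discovery`` mirrors the sequencing phase: FASTQ -> unique reads ->
isomiR calls -> count/RPM matrices -> NB differential abundance ->
candidate list, isoform-occurrence summary and per-miRNA length
distributions.  ``run_validation`` mirrors the qPCR phase: Ct table ->
pooled-reference delta-Ct normalization -> five-model LOOCV panel report.

Both write their artifacts plus a run manifest (config hash, versions) so
a rerun with the same configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .diagnostics import PanelReport, evaluate_panels
from .diffexp import (
    SELECTION_PRESETS,
    estimate_dispersions,
    isoform_occurrence,
    lrt_test,
    select_candidates,
)
from .isomir import AlignPolicy, call_sample, write_calls
from .preprocess import DEFAULT_ADAPTER, process_fastq, write_tally_log
from .qpcr import expression_matrix, normalize_delta_ct, pooled_reference
from .quantify import (
    build_matrices,
    cohort_length_distributions,
    rpm_normalize,
    write_matrix,
)
from .refdb import ReferenceSet, load_reference

log = logging.getLogger("isomirev")


@dataclass
class DiscoveryConfig:
    """Inputs and parameters for the sequencing-phase pipeline."""

    fastq: Mapping[str, str | Path]  # sample_id -> FASTQ path
    groups: Mapping[str, str]  # sample_id -> control/cancer
    ref_fasta: str | Path | None = None
    ref_table: str | Path | None = None
    reference: ReferenceSet | None = None
    adapter: str = DEFAULT_ADAPTER
    min_len: int = 15
    policy: AlignPolicy = field(default_factory=AlignPolicy)
    preset: str = "methods"
    min_rpm: float = 0.0
    panel_mirnas: Sequence[str] = ("miR-21-5p", "miR-204-5p", "miR-375")

    def resolve_reference(self) -> ReferenceSet:
        if self.reference is not None:
            return self.reference
        if self.ref_fasta is None or self.ref_table is None:
            raise ValueError("either reference or ref_fasta+ref_table is required")
        return load_reference(self.ref_fasta, self.ref_table)

    def validate(self) -> None:
        if self.preset not in SELECTION_PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {sorted(SELECTION_PRESETS)}"
            )
        for sid, path in self.fastq.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"FASTQ for sample {sid!r} not found: {path}")
        missing = set(self.fastq) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        if self.reference is None:
            for p in (self.ref_fasta, self.ref_table):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"reference file not found: {p}")


def _manifest(config_repr: dict, out_dir: Path) -> dict:
    payload = json.dumps(config_repr, sort_keys=True, default=str)
    manifest = {
        "config_hash": hashlib.sha256(payload.encode()).hexdigest(),
        "config": config_repr,
        "package_version": __version__,
        "python_version": platform.python_version(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


@dataclass
class DiscoveryResult:
    diff_table: pd.DataFrame
    candidates: pd.DataFrame
    occurrence: pd.Series
    length_distributions: pd.DataFrame
    manifest: dict


def run_discovery(cfg: DiscoveryConfig, out_dir: str | Path) -> DiscoveryResult:
    """FASTQ cohort -> differential isomiR tables.

    Stage failures abort with the stage name in the exception message.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = cfg.resolve_reference()

    callsets = []
    for sid in sorted(cfg.fastq):
        try:
            urs = process_fastq(
                cfg.fastq[sid], sample_id=sid, adapter=cfg.adapter, min_len=cfg.min_len
            )
        except Exception as exc:  # noqa: BLE001 - annotate the stage
            raise RuntimeError(f"stage preprocess failed for sample {sid!r}") from exc
        write_tally_log(urs, out_dir / f"{sid}.tally.json")
        try:
            cs = call_sample(urs, ref, cfg.policy)
        except Exception as exc:
            raise RuntimeError(f"stage isomir_caller failed for sample {sid!r}") from exc
        write_calls(cs, out_dir / f"{sid}.calls.tsv")
        log.info(
            "sample %s: %d unique reads, %d aligned reads, %d unaligned",
            sid,
            urs.n_unique,
            cs.n_aligned_reads,
            cs.n_unaligned,
        )
        callsets.append(cs)

    try:
        iso_cm, sum_cm = build_matrices(callsets)
        iso_rpm = rpm_normalize(iso_cm)
    except Exception as exc:
        raise RuntimeError("stage quantify failed") from exc
    write_matrix(iso_cm, out_dir / "counts.isoform.tsv")
    write_matrix(sum_cm, out_dir / "counts.mature_summed.tsv")
    write_matrix(iso_rpm, out_dir / "rpm.isoform.tsv")

    try:
        disp = estimate_dispersions(iso_cm, cfg.groups)
        table = lrt_test(iso_cm, cfg.groups, disp)
    except Exception as exc:
        raise RuntimeError("stage diffexp failed") from exc
    preset = SELECTION_PRESETS[cfg.preset]
    candidates = select_candidates(table, min_rpm=cfg.min_rpm, **preset)
    occurrence = isoform_occurrence(table)
    lengths = cohort_length_distributions(callsets, cfg.panel_mirnas)

    table.to_csv(out_dir / "diff_table.tsv", sep="\t")
    candidates.to_csv(out_dir / "candidates.tsv", sep="\t")
    occurrence.rename("n_significant").to_csv(out_dir / "occurrence.tsv", sep="\t")
    lengths.to_csv(out_dir / "length_distributions.tsv", sep="\t", index=False)

    manifest = _manifest(
        {
            "phase": "discovery",
            "samples": sorted(cfg.fastq),
            "groups": dict(sorted(cfg.groups.items())),
            "adapter": cfg.adapter,
            "min_len": cfg.min_len,
            "policy": vars(cfg.policy),
            "preset": cfg.preset,
            "min_rpm": cfg.min_rpm,
        },
        out_dir,
    )
    return DiscoveryResult(
        diff_table=table,
        candidates=candidates,
        occurrence=occurrence,
        length_distributions=lengths,
        manifest=manifest,
    )


@dataclass
class ValidationConfig:
    """Inputs for the qPCR-phase pipeline."""

    ct_table: pd.DataFrame
    clinical: pd.DataFrame
    log_psa: bool = True


def run_validation(cfg: ValidationConfig, out_dir: str | Path) -> PanelReport:
    """Ct table + clinical -> normalized expression -> five-model report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clinical = cfg.clinical
    if "sample_id" not in clinical.columns:
        raise ValueError("clinical table needs a sample_id column")
    controls = clinical.loc[clinical["label"] == 0, "sample_id"]
    try:
        ref = pooled_reference(cfg.ct_table, controls)
        expr = normalize_delta_ct(cfg.ct_table, ref)
        mat = expression_matrix(expr)
    except Exception as exc:
        raise RuntimeError("stage qpcr_norm failed") from exc
    try:
        report = evaluate_panels(mat, clinical, log_psa=cfg.log_psa)
    except Exception as exc:
        raise RuntimeError("stage diagnostics failed") from exc
    report.write_json(out_dir / "panel_report.json")
    expr.to_csv(out_dir / "expression.tsv", sep="\t", index=False)
    _manifest(
        {
            "phase": "validation",
            "n_samples": int(clinical.shape[0]),
            "assays": sorted(cfg.ct_table["assay_id"].unique()),
            "log_psa": cfg.log_psa,
        },
        out_dir,
    )
    return report
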