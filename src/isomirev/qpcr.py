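"""Stem-loop RT-qPCR Ct normalization against a pooled control reference.

Each assay's Ct values are referenced to the mean Ct of the control
samples (the in-silico analogue of physically pooling control cDNA), and
the resulting delta-Ct is expressed on the natural-log scale:

    ln_expr = (Ct_ref - Ct_sample) * ln 2  =  ln(2 ** -dCt)

so one PCR cycle corresponds to exactly ln 2, and higher expression gives
larger ln_expr.  Missing Ct values propagate as missing — they are never
imputed.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LN2 = math.log(2.0)

#: Assay identifiers for the three-miRNA diagnostic panel.  The isomiR
#: assays are named by the exact target sequence they were designed
#: against (a 3'-trimmed miR-21-5p, a 3'-trimmed miR-375 and a 23-nt
#: templated-elongation miR-204-5p variant).
MATURE_ASSAYS = ("miR-21-5p", "miR-204-5p", "miR-375")
ISOMIR_ASSAYS = (
    "UAGCUUAUCAGACUGAUGUU",
    "UUCCCUUUGUCAUCCUAUGCCUG",
    "UUUGUUCGUUCGGCUCGCGUG",
)

_CT_COLUMNS = ("sample_id", "assay_id", "ct")


def _check_ct_table(ct: pd.DataFrame, require_positive: bool = False) -> pd.DataFrame:
    missing = [c for c in _CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    dup = ct.duplicated(subset=["sample_id", "assay_id"])
    if dup.any():
        raise ValueError(
            f"multiple Ct values for (sample, assay): "
            f"{ct.loc[dup, ['sample_id', 'assay_id']].values.tolist()}"
        )
    if require_positive:
        present = ct["ct"].dropna()
        if (present <= 0).any():
            raise ValueError("Ct values must be positive")
    return ct


def pooled_reference(
    ct: pd.DataFrame, control_ids: Iterable[str]
) -> pd.Series:
    """Per-assay reference Ct: arithmetic mean over control samples.

    Missing control Ct values are skipped; an assay with no control Ct at
    all is an error (the reference pool cannot be formed for it).
    """
    ct = _check_ct_table(ct)
    control_ids = set(control_ids)
    sub = ct[ct["sample_id"].isin(control_ids)]
    ref = sub.groupby("assay_id")["ct"].mean()
    empty = ref[ref.isna()].index.tolist()
    all_assays = set(ct["assay_id"])
    absent = sorted((all_assays - set(ref.index)) | set(empty))
    if absent:
        raise ValueError(f"no control Ct for assay(s): {absent}")
    return ref


def normalize_delta_ct(ct: pd.DataFrame, reference: pd.Series | Mapping[str, float]) -> pd.DataFrame:
    """delta-Ct against the reference, as natural-log expression.

    Adds ``ln_expr = (Ct_ref - Ct) * ln 2`` per row; missing Ct values
    yield missing ln_expr.
    """
    ct = _check_ct_table(ct)
    reference = pd.Series(reference)
    missing_ref = sorted(set(ct["assay_id"]) - set(reference.index))
    if missing_ref:
        raise ValueError(f"no reference Ct for assay(s): {missing_ref}")
    out = ct.copy()
    ref = reference.reindex(out["assay_id"]).values
    out["ln_expr"] = (ref - out["ct"].values) * LN2
    return out


def expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pivot a normalized long table to samples x assays ln_expr."""
    return expr.pivot(index="sample_id", columns="assay_id", values="ln_expr")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t")
    return _check_ct_table(ct, require_positive=True)


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    _check_ct_table(ct, require_positive=True)[list(_CT_COLUMNS)].to_csv(
        path, sep="\t", index=False
    )
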