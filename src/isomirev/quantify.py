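"""Count matrices and RPM normalization.

Two quantification levels mirror the two ways stem-loop qPCR and
sequencing see a miRNA: *isoform* rows keyed ``mirna|d5|d3|tail`` (each
distinct end-variant is its own feature, NTA-U and NTA-UU included) and
*mature_summed* rows that pool every read assigned to a miRNA.  RPM uses
the miRNA-mapped total of each sample as denominator — never the raw read
yield — so values are comparable across samples regardless of how much
non-miRNA RNA they carried.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .isomir import CallSet, IsomirCall

LEVELS = ("isoform", "mature_summed")


@dataclass
class CountMatrix:
    """Features x samples integer counts at one quantification level.

    ``feature_meta`` (isoform level) carries mirna_id, d5, d3, nta_tail and
    variant_class per row, indexed like ``data``.
    """

    data: pd.DataFrame
    level: str
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.data.values < 0).any():
            raise ValueError("negative counts")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class RpmMatrix:
    """Reads-per-million-miRNA-mapped; same shape as its CountMatrix."""

    data: pd.DataFrame
    level: str


def build_matrices(callsets: Iterable[CallSet]) -> tuple[CountMatrix, CountMatrix]:
    """Aggregate per-sample calls into (isoform, mature_summed) matrices."""
    callsets = list(callsets)
    if not callsets:
        raise ValueError("need at least one sample")
    sample_ids = [cs.sample_id for cs in callsets]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids in {sample_ids}")

    iso_records: dict[str, dict[str, int]] = {}
    meta: dict[str, IsomirCall] = {}
    for cs in callsets:
        col = iso_records.setdefault(cs.sample_id, {})
        for call in cs.calls:
            key = call.isoform_key
            col[key] = col.get(key, 0) + call.count
            meta.setdefault(key, call)

    features = sorted(meta)
    iso = pd.DataFrame(
        {sid: [iso_records[sid].get(f, 0) for f in features] for sid in sample_ids},
        index=pd.Index(features, name="feature_id"),
        dtype=np.int64,
    )
    feature_meta = pd.DataFrame(
        {
            "mirna_id": [meta[f].mirna_id for f in features],
            "d5": [meta[f].d5 for f in features],
            "d3": [meta[f].d3 for f in features],
            "nta_tail": [meta[f].nta_tail for f in features],
            "variant_class": [meta[f].variant_class for f in features],
        },
        index=iso.index,
    )
    summed = iso.groupby(feature_meta["mirna_id"]).sum()
    summed.index.name = "feature_id"
    return (
        CountMatrix(data=iso, level="isoform", feature_meta=feature_meta),
        CountMatrix(data=summed, level="mature_summed"),
    )


def mirna_mapped_totals(m: CountMatrix) -> pd.Series:
    """Per-sample denominator for RPM: total miRNA-assigned reads."""
    return m.data.sum(axis=0)


def rpm_normalize(m: CountMatrix, totals: pd.Series | None = None) -> RpmMatrix:
    """counts / miRNA-mapped total x 1e6 per sample.

    ``totals`` defaults to the matrix's own column sums (identical between
    the isoform and mature_summed levels, since both partition the same
    aligned reads).  A sample with zero miRNA-mapped reads is an error.
    """
    if totals is None:
        totals = mirna_mapped_totals(m)
    totals = totals.reindex(m.data.columns)
    zero = totals[(totals <= 0) | totals.isna()]
    if len(zero):
        raise ValueError(
            f"zero miRNA-mapped total for sample(s): {list(zero.index)}"
        )
    return RpmMatrix(data=m.data / totals * 1e6, level=m.level)


def length_distribution(
    calls: Iterable[IsomirCall] | CallSet, mirna_id: str
) -> dict[int, float]:
    """Count-weighted read-length frequencies for one miRNA (sums to 1)."""
    if isinstance(calls, CallSet):
        calls = calls.calls
    weights: dict[int, int] = {}
    for c in calls:
        if c.mirna_id == mirna_id:
            weights[c.length] = weights.get(c.length, 0) + c.count
    total = sum(weights.values())
    if total == 0:
        raise ValueError(f"no calls for mirna_id {mirna_id!r}")
    return {length: count / total for length, count in sorted(weights.items())}


def cohort_length_distributions(
    callsets: Iterable[CallSet], mirna_ids: Iterable[str]
) -> pd.DataFrame:
    """Per-sample length distributions, long format (sample, mirna, length, freq)."""
    rows = []
    for cs in callsets:
        for mid in mirna_ids:
            try:
                dist = length_distribution(cs, mid)
            except ValueError:
                continue
            for length, freq in dist.items():
                rows.append(
                    {"sample_id": cs.sample_id, "mirna_id": mid, "length": length, "frequency": freq}
                )
    return pd.DataFrame(rows, columns=["sample_id", "mirna_id", "length", "frequency"])


def write_matrix(m: CountMatrix | RpmMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# level={m.level}\n")
        m.data.to_csv(fh, sep="\t")


def read_matrix(path: str | Path) -> CountMatrix | RpmMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# level="):
            raise ValueError(f"{path}: missing '# level=' header")
        level = first.strip().split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if np.issubdtype(df.values.dtype, np.integer):
        return CountMatrix(data=df, level=level)
    return RpmMatrix(data=df, level=level)
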