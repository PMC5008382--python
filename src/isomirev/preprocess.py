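"""Raw small-RNA FASTQ -> unique-read count tables.

Standard small-RNA preprocessing: 3' adapter trimming, removal of short
inserts (< 15 nt by default) and collapsing of identical sequences into
unique reads carrying a count.  Trimmed sequences are normalized to RNA
(U) so they compare directly against hairpin references downstream.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .refdb import normalize_rna

#: Illumina TruSeq small-RNA 3' adapter (first 21 bases).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_MIN_LEN = 15
DEFAULT_MIN_OVERLAP = 8


@dataclass
class UniqueReadSet:
    """Collapsed reads for one sample, with processing tallies.

    ``reads`` maps RNA sequence -> number of times it was sequenced; the
    counts sum to ``n_pass`` (reads surviving the length filter).
    """

    sample_id: str
    reads: dict[str, int] = field(default_factory=dict)
    n_raw: int = 0
    n_pass: int = 0
    n_no_adapter: int = 0

    @property
    def n_unique(self) -> int:
        return len(self.reads)


def trim_adapter(
    seq: str, adapter: str = DEFAULT_ADAPTER, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> tuple[str, bool]:
    """Remove the 3' adapter from a read.

    The insert ends at the leftmost position where a prefix of ``adapter``
    of at least ``min_overlap`` bases matches the read exactly (shorter
    matches are allowed only when the read itself ends first, i.e. the
    adapter runs off the 3' end is NOT accepted below min_overlap).
    Returns ``(trimmed, found)``; reads without an adapter are returned
    unmodified with ``found=False``.
    """
    if min_overlap < 6:
        raise ValueError(f"min_overlap must be >= 6, got {min_overlap}")
    s = seq.strip().upper().replace("U", "T")
    a = adapter.strip().upper().replace("U", "T")
    if not s:
        return "", False
    key = a[:min_overlap]
    start = 0
    while True:
        i = s.find(key, start)
        if i < 0:
            return seq, False
        overlap = min(len(a), len(s) - i)
        if s[i : i + overlap] == a[:overlap]:
            return seq[:i], True
        start = i + 1


def collapse_and_filter(
    sequences: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    sample_id: str = "sample",
    n_no_adapter: int = 0,
) -> UniqueReadSet:
    """Drop sequences shorter than ``min_len`` and collapse the rest.

    Input may be DNA or RNA; stored keys are RNA.  Collapsing is purely a
    multiset operation, so it is invariant to input order.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    counts: Counter[str] = Counter()
    n_raw = 0
    n_pass = 0
    for seq in sequences:
        n_raw += 1
        if len(seq) < min_len:
            continue
        counts[normalize_rna(seq, context="read")] += 1
        n_pass += 1
    return UniqueReadSet(
        sample_id=sample_id,
        reads=dict(sorted(counts.items())),
        n_raw=n_raw,
        n_pass=n_pass,
        n_no_adapter=n_no_adapter,
    )


def _open_maybe_gzip(path: str | Path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p)


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a (optionally gzipped) FASTQ file."""
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record in {path}")
            yield seq


def process_fastq(
    path: str | Path,
    sample_id: str | None = None,
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = DEFAULT_MIN_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    discard_untrimmed: bool = False,
) -> UniqueReadSet:
    """Trim + filter + collapse one FASTQ file into a UniqueReadSet.

    Reads in which no adapter is found are kept by default (the insert may
    fill the read); set ``discard_untrimmed`` to drop them instead.
    """
    if sample_id is None:
        sample_id = Path(path).name.split(".")[0]
    trimmed: list[str] = []
    n_no_adapter = 0
    n_raw = 0
    for seq in iter_fastq_sequences(path):
        n_raw += 1
        ins, found = trim_adapter(seq, adapter, min_overlap)
        if not found:
            n_no_adapter += 1
            if discard_untrimmed:
                continue
        trimmed.append(ins)
    out = collapse_and_filter(
        trimmed, min_len=min_len, sample_id=sample_id, n_no_adapter=n_no_adapter
    )
    out.n_raw = n_raw  # count discarded-untrimmed reads as raw too
    return out


def write_unique_reads(urs: UniqueReadSet, path: str | Path) -> None:
    """Collapsed reads as TSV (sequence, count)."""
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for seq, count in urs.reads.items():
            fh.write(f"{seq}\t{count}\n")


def read_unique_reads(path: str | Path, sample_id: str | None = None) -> UniqueReadSet:
    """Load a pre-collapsed (sequence, count) TSV."""
    if sample_id is None:
        sample_id = Path(path).name.split(".")[0]
    reads: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"{path}: expected header 'sequence\\tcount'")
        for line in fh:
            seq, count = line.rstrip("\n").split("\t")
            reads[normalize_rna(seq, context="read")] = int(count)
    n_pass = sum(reads.values())
    return UniqueReadSet(
        sample_id=sample_id, reads=reads, n_raw=n_pass, n_pass=n_pass
    )


def write_tally_log(urs: UniqueReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "sample_id": urs.sample_id,
                "n_raw": urs.n_raw,
                "n_pass": urs.n_pass,
                "n_no_adapter": urs.n_no_adapter,
                "n_unique": urs.n_unique,
            },
            fh,
            indent=2,
        )
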