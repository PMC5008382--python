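"""miRNA hairpin references with mature-arm annotations.

An isomiR is defined relative to a *template*: the precursor hairpin and the
annotated coordinates of the mature arm on it.  This module holds that
template — hairpin sequences plus mature annotations — and answers the one
query isomiR classification needs: "what does the hairpin say next?"
(:func:`templated_suffix`), which decides whether a 3' extension of a read is
templated elongation or a non-templated addition.

Coordinates are 0-based half-open on the hairpin's 5'->3' strand.  Sequences
are stored as RNA (ACGU); DNA input (T) is accepted and converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ARMS = ("5p", "3p")
_RNA_ALPHABET = frozenset("ACGU")


class ReferenceError(ValueError):
    """Invalid or inconsistent hairpin/mature reference data."""


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, convert T->U and validate the ACGU alphabet."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ReferenceError(
            f"{context} contains non-ACGU/T characters: {sorted(bad)!r}"
        )
    return s


@dataclass(frozen=True)
class MatureAnnotation:
    """Location of one mature miRNA arm on its hairpin.

    ``start``/``end`` are 0-based half-open; ``end - start`` is the canonical
    (miRBase-style) mature length, typically 18–25 nt.
    """

    mirna_id: str
    hairpin_id: str
    start: int
    end: int
    arm: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ReferenceError(
                f"{self.mirna_id}: arm must be one of {ARMS}, got {self.arm!r}"
            )
        if not (0 <= self.start < self.end):
            raise ReferenceError(
                f"{self.mirna_id}: invalid coordinates [{self.start},{self.end})"
            )

    @property
    def canonical_length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceSet:
    """Hairpin sequences plus the mature annotations defined on them."""

    hairpins: dict[str, str]
    matures: list[MatureAnnotation]
    _by_mirna: dict[str, MatureAnnotation] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self.hairpins = {
            hid: normalize_rna(seq, context=f"hairpin {hid!r}")
            for hid, seq in self.hairpins.items()
        }
        for hid, seq in self.hairpins.items():
            if not seq:
                raise ReferenceError(f"hairpin {hid!r} is empty")
        for ann in self.matures:
            if ann.hairpin_id not in self.hairpins:
                raise ReferenceError(
                    f"annotation {ann.mirna_id!r} references unknown hairpin "
                    f"{ann.hairpin_id!r}"
                )
            hp_len = len(self.hairpins[ann.hairpin_id])
            if ann.end > hp_len:
                raise ReferenceError(
                    f"annotation {ann.mirna_id!r}: end={ann.end} exceeds "
                    f"hairpin {ann.hairpin_id!r} length {hp_len}"
                )
            if ann.mirna_id in self._by_mirna:
                raise ReferenceError(f"duplicate mirna_id {ann.mirna_id!r}")
            self._by_mirna[ann.mirna_id] = ann

    def mature(self, mirna_id: str) -> MatureAnnotation:
        try:
            return self._by_mirna[mirna_id]
        except KeyError:
            raise ReferenceError(f"unknown mirna_id {mirna_id!r}") from None

    def canonical_sequence(self, mirna_id: str) -> str:
        """The exact hairpin substring the mature annotation covers."""
        ann = self.mature(mirna_id)
        return self.hairpins[ann.hairpin_id][ann.start : ann.end]

    @property
    def mirna_ids(self) -> list[str]:
        return [a.mirna_id for a in self.matures]


def templated_suffix(ref: ReferenceSet, hairpin_id: str, pos: int, n: int) -> str:
    """The next ``n`` templated nucleotides of a hairpin starting at ``pos``.

    Returns fewer than ``n`` bases only when the hairpin 3' end is reached.
    This is the template query behind the elongation-vs-NTA decision.
    """
    if hairpin_id not in ref.hairpins:
        raise ReferenceError(f"unknown hairpin_id {hairpin_id!r}")
    hp = ref.hairpins[hairpin_id]
    if not (0 <= pos <= len(hp)):
        raise ReferenceError(
            f"position {pos} outside hairpin {hairpin_id!r} (length {len(hp)})"
        )
    if n < 0:
        raise ReferenceError(f"n must be >= 0, got {n}")
    return hp[pos : pos + n]


_TABLE_COLUMNS = ["mirna_id", "hairpin_id", "start", "end", "arm"]


def load_reference(hairpin_fasta: str | Path, mature_table: str | Path) -> ReferenceSet:
    """Read hairpins (FASTA, U or T) and a mature annotation TSV.

    The TSV needs columns ``mirna_id, hairpin_id, start, end, arm`` with
    0-based half-open coordinates.
    """
    hairpins = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(hairpin_fasta), "fasta")
    }
    if not hairpins:
        raise ReferenceError(f"no sequences in {hairpin_fasta}")
    table = pd.read_csv(mature_table, sep="\t", comment="#")
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ReferenceError(f"mature table missing columns: {missing}")
    matures = [
        MatureAnnotation(
            mirna_id=str(row.mirna_id),
            hairpin_id=str(row.hairpin_id),
            start=int(row.start),
            end=int(row.end),
            arm=str(row.arm),
        )
        for row in table.itertuples(index=False)
    ]
    return ReferenceSet(hairpins=hairpins, matures=matures)


def write_reference(
    ref: ReferenceSet, hairpin_fasta: str | Path, mature_table: str | Path
) -> None:
    """Write a ReferenceSet back to FASTA + TSV (round-trips with load)."""
    records = [
        SeqRecord(Seq(seq), id=hid, description="") for hid, seq in ref.hairpins.items()
    ]
    SeqIO.write(records, str(hairpin_fasta), "fasta")
    rows = [
        {
            "mirna_id": a.mirna_id,
            "hairpin_id": a.hairpin_id,
            "start": a.start,
            "end": a.end,
            "arm": a.arm,
        }
        for a in ref.matures
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(mature_table, sep="\t", index=False)


def load_mirbase_gff3(hairpin_fasta: str | Path, gff3: str | Path) -> ReferenceSet:
    """Optional miRBase-style GFF3 reader.

    Expects hairpin FASTA ids matching the GFF3 ``ID``/``Name`` of
    ``miRNA_primary_transcript`` records, with ``miRNA`` children located by
    1-based inclusive coordinates *on the hairpin*; converts to the package's
    0-based half-open convention.  The arm is taken from a ``-5p``/``-3p``
    suffix on the miRNA name (default ``5p``).
    """
    hairpins = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(hairpin_fasta), "fasta")
    }
    matures: list[MatureAnnotation] = []
    with open(gff3) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "miRNA":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID")
            parent = attrs.get("Derives_from") or attrs.get("Parent")
            if name is None or parent is None:
                raise ReferenceError(f"GFF3 miRNA record lacks Name/parent: {line!r}")
            arm = "3p" if name.endswith("-3p") else "5p"
            start_1 = int(fields[3])
            end_1 = int(fields[4])
            matures.append(
                MatureAnnotation(
                    mirna_id=name,
                    hairpin_id=parent,
                    start=start_1 - 1,
                    end=end_1,
                    arm=arm,
                )
            )
    return ReferenceSet(hairpins=hairpins, matures=matures)
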