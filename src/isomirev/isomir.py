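"""Anchor unique reads on hairpins and classify them as isomiRs.

A read is first *aligned*: its 5' end is placed near an annotated mature
start (within ``max_5p_shift``) and accepted when its seed (first
``seed_len`` nt) matches the hairpin with at most ``max_mismatch``
mismatches.  Seed anchoring deliberately ignores the 3' end, so heavily
3'-modified molecules still map — the whole point of isomiR detection.

Classification then walks the read along the hairpin: the *templated span*
is the maximal read prefix matching the template (tolerating at most
``max_mismatch`` internal mismatches, never ending on one); whatever is
left is the non-templated 3' tail (NTA).  Relative to the mature
annotation this yields

* ``d5`` — read start minus canonical start (negative = 5' extension),
* ``d3`` — templated 3' end minus canonical end (negative = trimming,
  positive = templated elongation),
* ``nta_tail`` — the non-templated suffix.

One mutually exclusive variant class is assigned by precedence:
5' modification > NTA > trimming/elongation > mature.  The full
(d5, d3, tail) record is always retained so other roll-ups stay possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .preprocess import UniqueReadSet
from .refdb import ReferenceSet

VARIANT_CLASSES = (
    "mature",
    "trimming",
    "elongation",
    "fiveprime_mod",
    "NTA-A",
    "NTA-U",
    "NTA-G",
    "NTA-C",
    "NTA-other",
)


@dataclass(frozen=True)
class AlignPolicy:
    """Seed-anchoring parameters for read-to-hairpin placement."""

    seed_len: int = 16
    max_mismatch: int = 1
    max_5p_shift: int = 5

    def __post_init__(self) -> None:
        if self.seed_len < 10:
            raise ValueError(f"seed_len must be >= 10, got {self.seed_len}")
        if self.max_mismatch not in (0, 1):
            raise ValueError(f"max_mismatch must be 0 or 1, got {self.max_mismatch}")
        if self.max_5p_shift < 0:
            raise ValueError("max_5p_shift must be >= 0")


@dataclass(frozen=True)
class Hit:
    """A read's anchoring on a hairpin, tied to one mature annotation."""

    hairpin_id: str
    pos: int
    mismatches_in_template: int
    mirna_id: str


@dataclass(frozen=True)
class IsomirCall:
    """One unique read's isomiR classification (with its collapsed count)."""

    sequence: str
    mirna_id: str
    d5: int
    d3: int
    nta_tail: str
    variant_class: str
    length: int
    count: int

    @property
    def isoform_key(self) -> str:
        return f"{self.mirna_id}|{self.d5}|{self.d3}|{self.nta_tail}"


def classify_variant(d5: int, d3: int, nta_tail: str) -> str:
    """Assign the single variant class by precedence.

    5' changes dominate (any d5 != 0), then a non-empty non-templated tail
    (NTA-X when all tail bases are the same X, NTA-other otherwise), then
    3' trimming / templated elongation, else mature.
    """
    if d5 != 0:
        return "fiveprime_mod"
    if nta_tail:
        bases = set(nta_tail)
        if len(bases) == 1:
            return f"NTA-{nta_tail[0]}"
        return "NTA-other"
    if d3 < 0:
        return "trimming"
    if d3 > 0:
        return "elongation"
    return "mature"


def align_read(seq: str, ref: ReferenceSet, policy: AlignPolicy) -> Hit | None:
    """Place a read near a mature start by exact seed comparison.

    Candidate starts are every position within ``max_5p_shift`` of every
    annotated mature start; a candidate is a hit when the read's first
    ``seed_len`` nt match the hairpin there with <= ``max_mismatch``
    mismatches.  The best hit minimizes (mismatches, |5' shift|), ties
    broken by lexicographic mirna_id.  Returns None for unmappable or
    too-short reads.
    """
    if len(seq) < policy.seed_len:
        return None
    seed = seq[: policy.seed_len]
    best: tuple[int, int, str, int] | None = None
    for ann in ref.matures:
        hp = ref.hairpins[ann.hairpin_id]
        for shift in range(-policy.max_5p_shift, policy.max_5p_shift + 1):
            pos = ann.start + shift
            if pos < 0 or pos + policy.seed_len > len(hp):
                continue
            window = hp[pos : pos + policy.seed_len]
            mm = sum(a != b for a, b in zip(seed, window))
            if mm > policy.max_mismatch:
                continue
            cand = (mm, abs(shift), ann.mirna_id, pos)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    mm, _, mirna_id, pos = best
    ann = ref.mature(mirna_id)
    return Hit(
        hairpin_id=ann.hairpin_id, pos=pos, mismatches_in_template=mm, mirna_id=mirna_id
    )


def classify_read(
    seq: str, hit: Hit, ref: ReferenceSet, policy: AlignPolicy = AlignPolicy(), count: int = 1
) -> IsomirCall:
    """Split a placed read into templated span + NTA tail and classify it.

    The templated span is the maximal read prefix matching the hairpin from
    ``hit.pos`` with at most ``policy.max_mismatch`` mismatches; a span
    never ends on a mismatch (a terminal mismatch IS the NTA signal) and
    never extends past the hairpin 3' end.
    """
    hp = ref.hairpins[hit.hairpin_id]
    ann = ref.mature(hit.mirna_id)
    budget = policy.max_mismatch
    is_match: list[bool] = []
    j = 0
    used = 0
    while j < len(seq) and hit.pos + j < len(hp):
        if seq[j] == hp[hit.pos + j]:
            is_match.append(True)
        else:
            if used >= budget:
                break
            used += 1
            is_match.append(False)
        j += 1
    # the templated span must not end on a mismatch
    while j > 0 and not is_match[j - 1]:
        j -= 1
    nta_tail = seq[j:]
    d5 = hit.pos - ann.start
    d3 = (hit.pos + j) - ann.end
    return IsomirCall(
        sequence=seq,
        mirna_id=hit.mirna_id,
        d5=d5,
        d3=d3,
        nta_tail=nta_tail,
        variant_class=classify_variant(d5, d3, nta_tail),
        length=len(seq),
        count=count,
    )


@dataclass
class CallSet:
    """All isomiR calls for one sample plus the unaligned tally."""

    sample_id: str
    calls: list[IsomirCall] = field(default_factory=list)
    n_unaligned: int = 0

    @property
    def n_aligned_reads(self) -> int:
        return sum(c.count for c in self.calls)


def call_sample(
    reads: UniqueReadSet, ref: ReferenceSet, policy: AlignPolicy = AlignPolicy()
) -> CallSet:
    """Classify every unique read of a sample; output order is deterministic
    (mirna_id, d5, d3, nta_tail, sequence)."""
    calls: list[IsomirCall] = []
    n_unaligned = 0
    for seq, count in reads.reads.items():
        hit = align_read(seq, ref, policy)
        if hit is None:
            n_unaligned += count
            continue
        calls.append(classify_read(seq, hit, ref, policy, count=count))
    calls.sort(key=lambda c: (c.mirna_id, c.d5, c.d3, c.nta_tail, c.sequence))
    return CallSet(sample_id=reads.sample_id, calls=calls, n_unaligned=n_unaligned)


_CALL_COLUMNS = (
    "sequence",
    "mirna_id",
    "d5",
    "d3",
    "nta_tail",
    "variant_class",
    "length",
    "count",
)


def write_calls(callset: CallSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in callset.calls:
            fh.write(
                f"{c.sequence}\t{c.mirna_id}\t{c.d5}\t{c.d3}\t{c.nta_tail}\t"
                f"{c.variant_class}\t{c.length}\t{c.count}\n"
            )


def read_calls(path: str | Path, sample_id: str | None = None) -> CallSet:
    if sample_id is None:
        sample_id = Path(path).name.split(".")[0]
    calls: list[IsomirCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CALL_COLUMNS:
            raise ValueError(f"{path}: unexpected call-table header {header}")
        for line in fh:
            seq, mirna, d5, d3, tail, vclass, length, count = line.rstrip("\n").split("\t")
            calls.append(
                IsomirCall(
                    sequence=seq,
                    mirna_id=mirna,
                    d5=int(d5),
                    d3=int(d3),
                    nta_tail=tail,
                    variant_class=vclass,
                    length=int(length),
                    count=int(count),
                )
            )
    return CallSet(sample_id=sample_id, calls=calls)
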