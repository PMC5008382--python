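"""Independent brute-force oracles the tests compare the package against.

These re-derive expected results by exhaustive enumeration or closed
forms, sharing no code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_hit(seq, ref, policy):
    """Enumerate every (mature, 5' shift) placement; best by
    (mismatches, |shift|, mirna_id, position)."""
    if len(seq) < policy.seed_len:
        return None
    candidates = []
    for ann in ref.matures:
        hp = ref.hairpins[ann.hairpin_id]
        for shift in range(-policy.max_5p_shift, policy.max_5p_shift + 1):
            pos = ann.start + shift
            if pos < 0 or pos + policy.seed_len > len(hp):
                continue
            mm = sum(
                1
                for a, b in zip(seq[: policy.seed_len], hp[pos : pos + policy.seed_len])
                if a != b
            )
            if mm <= policy.max_mismatch:
                candidates.append((mm, abs(shift), ann.mirna_id, pos, ann))
    if not candidates:
        return None
    return min(candidates)


def brute_force_classify(seq, ref, policy):
    """Enumerate every (templated span, tail) decomposition and apply the
    variant-class precedence rule; returns None for unmappable reads,
    else (mirna_id, d5, d3, nta_tail, variant_class)."""
    best = brute_force_hit(seq, ref, policy)
    if best is None:
        return None
    _, _, mirna_id, pos, ann = best
    hp = ref.hairpins[ann.hairpin_id]
    chosen = None
    for j in range(len(seq), -1, -1):
        if pos + j > len(hp):
            continue
        span = seq[:j]
        template = hp[pos : pos + j]
        mm = sum(1 for a, b in zip(span, template) if a != b)
        if mm > policy.max_mismatch:
            continue
        if j > 0 and span[-1] != template[-1]:
            continue
        chosen = j
        break
    assert chosen is not None  # j=0 always qualifies
    tail = seq[chosen:]
    d5 = pos - ann.start
    d3 = (pos + chosen) - ann.end
    if d5 != 0:
        vclass = "fiveprime_mod"
    elif tail:
        vclass = f"NTA-{tail[0]}" if len(set(tail)) == 1 else "NTA-other"
    elif d3 < 0:
        vclass = "trimming"
    elif d3 > 0:
        vclass = "elongation"
    else:
        vclass = "mature"
    return (mirna_id, d5, d3, tail, vclass)


def bh_step_up(p):
    """Textbook BH: adjusted p_(i) = min over j>=i of min(1, n*p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    for i in range(n):
        adj_sorted[i] = min(
            min(1.0, n * p[order[j]] / (j + 1)) for j in range(i, n)
        )
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def mann_whitney_auc(scores, labels):
    """AUC as the pairwise concordance probability (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def enumerate_arm_substrings(ref, min_len=15, max_len=28):
    """All hairpin substrings of the given lengths overlapping a mature arm."""
    for ann in ref.matures:
        hp = ref.hairpins[ann.hairpin_id]
        for length in range(min_len, max_len + 1):
            for start in range(0, len(hp) - length + 1):
                end = start + length
                if end <= ann.start or start >= ann.end:
                    continue
                yield hp[start:end]
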