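"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the library's own scanning/statistics code paths:
the run oracle enumerates every (start, length) window directly, the AUC
oracle enumerates every positive-negative pair, and the chi-squared / BH
oracles follow the closed-form definitions.
"""

from __future__ import annotations

import numpy as np

_CLASS = {
    "Y": "CT",
    "R": "AG",
    "K": "GT",
    "M": "AC",
    "S": "CG",
    "W": "AT",
}


def window_runs(seq: str, phase: int, nt_class: str, min_triplets: int):
    """Every maximal in-class run found by testing each window directly.

    For each candidate window [i, j) of checked bases, tests (a) all bases
    in class, (b) not left-extendable, (c) not right-extendable, and
    (d) length >= min_triplets.  Returns sorted (start_nt, n_triplets).
    """
    members = _CLASS[nt_class]
    m = np.fromiter((c in members for c in seq[phase::3]), dtype=bool)
    K = m.size
    if K == 0:
        return []
    S = np.concatenate([[0], np.cumsum(m, dtype=np.int32)])
    lengths = np.arange(K + 1, dtype=np.int32)[None, :] - np.arange(K, dtype=np.int32)[:, None]
    full = (S[None, :] - S[:K, None]) == lengths
    left_ok = np.concatenate([[True], ~m[:-1]])
    right_ok = np.concatenate([~m, [True]])
    cand = full & (lengths >= min_triplets) & left_ok[:, None] & right_ok[None, :]
    ii, jj = np.nonzero(cand)
    return sorted((3 * int(i), int(j - i)) for i, j in zip(ii, jj))


def max_run(seq: str, phase: int, nt_class: str) -> int:
    """Longest run length by direct window enumeration (threshold 1)."""
    runs = window_runs(seq, phase, nt_class, 1)
    return max((n for _, n in runs), default=0)


def auc_pairwise(labels, scores) -> float:
    """AUC as the mean over all positive-negative pairs (ties worth 1/2)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def chi2_closed_form(table) -> float:
    """Pearson chi-squared via sum (O - E)^2 / E with marginal-product E."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row * col / t.sum()
    return float(((t - expected) ** 2 / expected).sum())


def bh_step_up(pvalues) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the step-up recursion."""
    p = list(pvalues)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adjusted = [0.0] * n
    prev = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = n - rank_from_top
        prev = min(prev, p[idx] * n / rank)
        adjusted[idx] = prev
    return adjusted


def rry_three_offsets(seq: str) -> float:
    """RRY score by explicit template expansion over the 3 offsets."""
    best = 0.0
    for offset in range(3):
        template = ("RRY" * (len(seq) // 3 + 2))[offset : offset + len(seq)]
        score = sum(
            (base in "AG") if letter == "R" else (base in "CT")
            for base, letter in zip(seq, template)
        ) / len(seq)
        best = max(best, score)
    return best


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))
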