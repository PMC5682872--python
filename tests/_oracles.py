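"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a different route than the package:
term-by-term extended-precision summation for the count-test tails,
reverse-complemented-sequence scanning for motif matches, and direct
enumeration of group assignments for the rank test.
"""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------------------
# Audic–Claverie tails by direct term summation (extended precision)
# ---------------------------------------------------------------------------


def ac_two_sided_grid(xmax: int, ymax: int, f: float) -> np.ndarray:
    """Two-sided p for all x in [0, xmax], y in [0, ymax].

    Sums the conditional terms p(k|x) = f^k (x+k)! / (x! k! (1+f)^(x+k+1))
    directly via the term recurrence in extended precision; the upper
    tail is 1 - lower + p(y|x).  Returns array indexed [x, y].
    """
    f = np.longdouble(f)
    x = np.arange(xmax + 1, dtype=np.longdouble)
    terms = np.empty((ymax + 1, xmax + 1), dtype=np.longdouble)
    terms[0] = (1.0 / (1.0 + f)) ** (x + 1)
    for k in range(1, ymax + 1):
        terms[k] = terms[k - 1] * f * (x + k) / (k * (1.0 + f))
    lower = np.cumsum(terms, axis=0)
    upper = 1.0 - lower + terms
    two = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.asarray(two.T, dtype=float)


def ac_two_sided(x: int, y: int, f: float) -> float:
    return float(ac_two_sided_grid(x, y, f)[x, y])


# ---------------------------------------------------------------------------
# IUPAC scanning by matching the pattern against the reverse-complemented
# sequence (coordinate-mirrored), rather than the pattern's reverse
# complement against the forward sequence
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
_ORDER = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _codes(seq: str) -> np.ndarray:
    lookup = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(_ORDER):
        lookup[ord(b)] = i
    return lookup[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _forward_starts(seq: str, pattern: str) -> np.ndarray:
    m, L = len(pattern), len(seq)
    if L < m:
        return np.zeros(0, dtype=int)
    codes = _codes(seq)
    table = np.zeros((m, len(_ORDER)), dtype=bool)
    for j, letter in enumerate(pattern):
        for b in _IUPAC[letter]:
            table[j, _ORDER.index(b)] = True
    ok = np.ones(L - m + 1, dtype=bool)
    for j in range(m):
        ok &= table[j][codes[j : j + L - m + 1]]
    return np.flatnonzero(ok)


def brute_scan(seq: str, pattern: str) -> set[tuple[int, int, str]]:
    """All (start, end, strand) matches of an IUPAC pattern, both strands."""
    m = len(pattern)
    out = {(int(s), int(s) + m, "+") for s in _forward_starts(seq, pattern)}
    rc_pattern = pattern.translate(_COMPLEMENT)[::-1]
    if rc_pattern != pattern.upper():
        rc_seq = seq.upper().translate(_COMPLEMENT)[::-1]
        L = len(seq)
        for s in _forward_starts(rc_seq, pattern):
            out.add((L - int(s) - m, L - int(s), "-"))
    return out


# ---------------------------------------------------------------------------
# Mann–Whitney by enumeration of group assignments (pair counting)
# ---------------------------------------------------------------------------


def mw_enumerate(sample_1, sample_2) -> tuple[float, float]:
    """Exact U and two-sided p by enumerating all group assignments."""

    def u_stat(a, b):
        return sum(
            1.0 if ai > bj else (0.5 if ai == bj else 0.0)
            for ai in a
            for bj in b
        )

    pooled = list(sample_1) + list(sample_2)
    n1 = len(sample_1)
    u_obs = u_stat(sample_1, sample_2)
    u_null = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        group1 = [pooled[i] for i in idx]
        group2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u_null.append(u_stat(group1, group2))
    u_null = np.asarray(u_null)
    p_low = np.mean(u_null <= u_obs)
    p_high = np.mean(u_null >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))
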