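"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — exhaustive enumeration, direct
summation, literal predicate evaluation — and shares no code with the
implementations under test.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

# --- secondary-structure enumeration -----------------------------------------

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_STACK = {("G", "C"): -3.0, ("C", "G"): -3.0, ("A", "U"): -2.0,
          ("U", "A"): -2.0, ("G", "U"): -1.0, ("U", "G"): -1.0}
_MIN_LOOP = 3


def enumerate_structures(seq: str) -> list[tuple[tuple[int, int], ...]]:
    """All pseudoknot-free structures (as sorted pair tuples) of ``seq``."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if j - i < _MIN_LOOP + 1:
            return [()]
        out = list(rec(i, j - 1))
        for k in range(i, j - _MIN_LOOP):
            if (seq[k], seq[j]) in _PAIRS:
                left = rec(i, k - 1) if k - 1 >= i else [()]
                right = rec(k + 1, j - 1)
                for L in left:
                    for R in right:
                        out.append(L + R + ((k, j),))
        return out

    return rec(0, n - 1) if n else [()]


def structure_energy(seq: str, pairs: tuple[tuple[int, int], ...]) -> float:
    """Loop-decomposition energy of one structure under the simplified
    nearest-neighbour model (hairpin +4, internal/bulge +3 + 0.5/nt,
    multibranch +4, stacks keyed on the closing pair)."""
    if not pairs:
        return 0.0
    sorted_pairs = sorted(pairs)
    energy = 0.0
    for (i, j) in sorted_pairs:
        enclosed = []
        k = i + 1
        while k < j:
            inner = next((p for p in sorted_pairs if p[0] == k), None)
            if inner is not None:
                enclosed.append(inner)
                k = inner[1] + 1
            else:
                k += 1
        if not enclosed:
            energy += 4.0
        elif len(enclosed) == 1:
            (a, b) = enclosed[0]
            if a == i + 1 and b == j - 1:
                energy += _STACK[(seq[i], seq[j])]
            else:
                energy += 3.0 + 0.5 * ((a - i - 1) + (j - b - 1))
        else:
            energy += 4.0
    return energy


def min_energy_bruteforce(seq: str) -> float:
    return min(structure_energy(seq, p) for p in enumerate_structures(seq))


# --- plant target-alignment scoring ------------------------------------------

_DNA_COMP = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_DNA_WOBBLE = {("G", "T"), ("T", "G")}


def _w(pos: int) -> float:
    return 2.0 if 2 <= pos <= 13 else 1.0


def _pen(mb: str, tb: str) -> float:
    if (mb, tb) in _DNA_COMP:
        return 0.0
    if (mb, tb) in _DNA_WOBBLE:
        return 0.5
    return 1.0


def allen_score_bruteforce(mirna: str, site: str) -> float:
    """Minimal score over all alignments with at most one gap, enumerated
    explicitly by gap placement."""
    m = mirna.upper().replace("U", "T")
    s = site.upper().replace("U", "T")[::-1]
    M, S = len(m), len(s)
    best = math.inf
    if M == S:
        best = sum(_pen(a, b) * _w(i + 1) for i, (a, b) in enumerate(zip(m, s)))
    elif S == M + 1:
        for skip in range(S):
            t = s[:skip] + s[skip + 1:]
            sc = 1.0 * _w(min(skip + 1, M))
            sc += sum(_pen(a, b) * _w(i + 1) for i, (a, b) in enumerate(zip(m, t)))
            best = min(best, sc)
    elif S == M - 1:
        for skip in range(M):
            t = m[:skip] + m[skip + 1:]
            sc = 1.0 * _w(skip + 1)
            sc += sum(_pen(a, b) * _w(i + 1) for i, (a, b) in enumerate(zip(t, s)))
            best = min(best, sc)
    return best


# --- statistics ---------------------------------------------------------------

def audic_claverie_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Direct summation of the Audic-Claverie posterior predictive mass."""
    ratio = n2 / n1

    def log_p(k: int) -> float:
        return (k * math.log(ratio)
                + math.lgamma(x + k + 1) - math.lgamma(x + 1) - math.lgamma(k + 1)
                - (x + k + 1) * math.log(1 + ratio))

    # sum far enough into the tail for the mass to be negligible
    kmax = max(200, 20 * (x + y + 10))
    probs = [math.exp(log_p(k)) for k in range(kmax)]
    lower = sum(probs[: y + 1])
    upper = sum(probs[y:])
    return min(1.0, 2.0 * min(lower, upper))


def bh_reference(pvals) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        q[idx] = val
        prev = val
    return q


def category_reference(profile: np.ndarray, pos1: int) -> int:
    """Literal evaluation of the t-plot category predicate at a 1-based
    position."""
    c = int(profile[pos1 - 1])
    peak = int(profile.max())
    nonzero = profile[profile > 0]
    med = float(np.median(nonzero))
    if c == peak and int((profile == peak).sum()) == 1 and c > 1:
        return 0
    if c == peak and c > 1:
        return 1
    if c == 1:
        return 4
    if c > med:
        return 2
    return 3
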