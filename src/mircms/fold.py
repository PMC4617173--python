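"""RNA secondary-structure prediction and the miRNA hairpin validity test.

Two energy backends are provided behind one interface:

* ``"vienna"`` — the ViennaRNA thermodynamic folder (used when its Python
  bindings are importable).  This is the default backend for pipeline runs.
* ``"simple"`` — a bundled simplified nearest-neighbour model solved exactly
  by dynamic programming.  Stack energies are keyed on the closing pair
  (GC/CG −3.0, AU/UA −2.0, GU/UG −1.0 kcal/mol per stack); loops carry flat
  penalties (hairpin +4.0, internal/bulge +3.0 plus 0.5 per unpaired
  nucleotide, multibranch +4.0).  The model is deliberately small enough that
  its minimum can be cross-checked against exhaustive enumeration of all
  pseudoknot-free structures on short sequences.

Hairpin validation applies the classical plant pre-miRNA criteria: a single
terminal loop on the mature-bearing stem, the mature confined to one arm,
2-nt 3' overhangs on the mature:star duplex, bounded internal loops/bulges
inside the duplex, and a minimum-free-energy ceiling (default −18 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._seq import to_rna

# --- simplified nearest-neighbour energy model -------------------------------

PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
STACK_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}
HAIRPIN_PENALTY = 4.0
INTERNAL_BASE = 3.0
INTERNAL_PER_NT = 0.5
MULTI_PENALTY = 4.0
MIN_HAIRPIN_LOOP = 3
MAX_INTERNAL_SPAN = 30  # per-side cap on internal-loop size in the DP

_INF = float("inf")


@dataclass(frozen=True)
class FoldResult:
    """A minimum-energy structure: sequence, dot-bracket string, energy (kcal/mol)."""

    sequence: str
    structure: str
    energy: float

    def pair_table(self) -> list[int]:
        return pair_table(self.structure)


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position; −1 for unpaired.

    Raises ``ValueError`` on unbalanced brackets.
    """
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure symbol {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt


def _check_alphabet(seq: str) -> str:
    rna = to_rna(seq)
    for i, c in enumerate(rna):
        if c not in "ACGU":
            raise ValueError(f"non-ACGTU symbol {seq[i]!r} at offset {i}")
    return rna


def _vienna_available() -> bool:
    try:
        import RNA  # noqa: F401
    except ImportError:
        return False
    return True


def fold(sequence: str, backend: str = "auto") -> FoldResult:
    """Predict the minimum-free-energy structure of ``sequence``.

    ``backend`` is ``"vienna"``, ``"simple"`` or ``"auto"`` (ViennaRNA when
    importable, otherwise the bundled simplified model).  The result is
    deterministic; in the simplified DP ties are broken toward structures
    with more pairs, preferring 5'-most pairings.
    """
    rna = _check_alphabet(sequence)
    if backend == "auto":
        backend = "vienna" if _vienna_available() else "simple"
    if backend == "vienna":
        import RNA

        structure, energy = RNA.fold(rna)
        return FoldResult(sequence, structure, round(float(energy), 2))
    if backend == "simple":
        structure, energy = _simple_fold(rna)
        return FoldResult(sequence, structure, energy)
    raise ValueError(f"unknown fold backend {backend!r}")


def _pairable(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


def _simple_fold(seq: str) -> tuple[str, float]:
    """Exact DP minimisation of the simplified nearest-neighbour model.

    Zuker-style recursions: V(i,j) = best energy of a structure closed by
    pair (i,j); WM/WM2 handle multibranch interiors (unpaired bases free,
    flat +4.0 per multiloop); W is the exterior loop.
    """
    n = len(seq)
    if n == 0:
        return "", 0.0
    V = [[_INF] * n for _ in range(n)]
    WM = [[_INF] * n for _ in range(n)]   # >= 1 branch
    WM2 = [[_INF] * n for _ in range(n)]  # >= 2 branches

    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if _pairable(seq[i], seq[j]):
                best = HAIRPIN_PENALTY
                # stack
                if j - i - 2 > MIN_HAIRPIN_LOOP and _pairable(seq[i + 1], seq[j - 1]):
                    e = STACK_ENERGY[(seq[i], seq[j])] + V[i + 1][j - 1]
                    if e < best:
                        best = e
                # internal loop / bulge
                for k in range(i + 1, min(i + 2 + MAX_INTERNAL_SPAN, j)):
                    l1 = k - i - 1
                    if l1 == 0:
                        lo = j - 1 - MAX_INTERNAL_SPAN
                    else:
                        lo = j - 1 - MAX_INTERNAL_SPAN + l1
                    for l in range(j - 1, max(k + MIN_HAIRPIN_LOOP, lo - 1, i), -1):
                        l2 = j - l - 1
                        if l1 + l2 == 0:
                            continue
                        if V[k][l] == _INF:
                            continue
                        e = INTERNAL_BASE + INTERNAL_PER_NT * (l1 + l2) + V[k][l]
                        if e < best:
                            best = e
                # multibranch
                if WM2[i + 1][j - 1] != _INF:
                    e = MULTI_PENALTY + WM2[i + 1][j - 1]
                    if e < best:
                        best = e
                V[i][j] = best
            # WM / WM2
            wm = min(WM[i + 1][j] if i + 1 <= j else _INF,
                     WM[i][j - 1] if j - 1 >= i else _INF,
                     V[i][j])
            wm2 = WM2[i][j - 1] if j - 1 >= i else _INF
            for k in range(i + 1, j):
                if V[k][j] == _INF:
                    continue
                if WM[i][k - 1] != _INF:
                    e = WM[i][k - 1] + V[k][j]
                    if e < wm:
                        wm = e
                    if e < wm2:
                        wm2 = e
            WM[i][j] = wm
            WM2[i][j] = wm2

    # exterior loop
    W = [0.0] * (n + 1)  # W[j+1] = best energy of prefix 0..j
    for j in range(n):
        best = W[j]
        for i in range(0, j):
            if V[i][j] != _INF:
                e = W[i] + V[i][j]
                if e < best:
                    best = e
        if V[0][j] != _INF and V[0][j] < best:
            best = V[0][j]
        W[j + 1] = min(best, W[j])

    energy = W[n]
    structure = ["."] * n
    _traceback(seq, V, WM, WM2, W, structure, n)
    return "".join(structure), round(energy, 2)


def _traceback(seq, V, WM, WM2, W, structure, n):
    eps = 1e-9

    def trace_v(i, j):
        structure[i], structure[j] = "(", ")"
        e = V[i][j]
        # preference order favours extending helices (more pairs, 5'-most)
        if (j - i - 2 > MIN_HAIRPIN_LOOP and _pairable(seq[i + 1], seq[j - 1])
                and abs(STACK_ENERGY[(seq[i], seq[j])] + V[i + 1][j - 1] - e) < eps):
            trace_v(i + 1, j - 1)
            return
        for k in range(i + 1, min(i + 2 + MAX_INTERNAL_SPAN, j)):
            l1 = k - i - 1
            for l in range(j - 1, max(k + MIN_HAIRPIN_LOOP, i), -1):
                l2 = j - l - 1
                if l1 + l2 == 0 or l1 > MAX_INTERNAL_SPAN or l2 > MAX_INTERNAL_SPAN:
                    continue
                if V[k][l] == _INF:
                    continue
                if abs(INTERNAL_BASE + INTERNAL_PER_NT * (l1 + l2) + V[k][l] - e) < eps:
                    trace_v(k, l)
                    return
        if abs(HAIRPIN_PENALTY - e) < eps:
            return
        if WM2[i + 1][j - 1] != _INF and abs(MULTI_PENALTY + WM2[i + 1][j - 1] - e) < eps:
            trace_wm2(i + 1, j - 1)
            return

    def trace_wm(i, j):
        e = WM[i][j]
        if e == _INF:
            return
        if V[i][j] != _INF and abs(V[i][j] - e) < eps:
            trace_v(i, j)
            return
        for k in range(i + 1, j):
            if V[k][j] != _INF and WM[i][k - 1] != _INF and abs(WM[i][k - 1] + V[k][j] - e) < eps:
                trace_wm(i, k - 1)
                trace_v(k, j)
                return
        if i + 1 <= j and abs(WM[i + 1][j] - e) < eps:
            trace_wm(i + 1, j)
            return
        if j - 1 >= i and abs(WM[i][j - 1] - e) < eps:
            trace_wm(i, j - 1)

    def trace_wm2(i, j):
        e = WM2[i][j]
        if e == _INF:
            return
        for k in range(i + 1, j):
            if V[k][j] != _INF and WM[i][k - 1] != _INF and abs(WM[i][k - 1] + V[k][j] - e) < eps:
                trace_wm(i, k - 1)
                trace_v(k, j)
                return
        if j - 1 >= i and abs(WM2[i][j - 1] - e) < eps:
            trace_wm2(i, j - 1)

    def trace_w(j):
        # j is exclusive prefix length
        while j > 0:
            e = W[j]
            if abs(W[j - 1] - e) < eps and e == W[j - 1]:
                # prefer a pairing explanation when one exists at equal energy
                paired = False
                for i in range(0, j):
                    if V[i][j - 1] != _INF and abs(W[i] + V[i][j - 1] - e) < eps:
                        trace_v(i, j - 1)
                        j = i
                        paired = True
                        break
                if paired:
                    continue
                j -= 1
                continue
            for i in range(0, j):
                if V[i][j - 1] != _INF and abs(W[i] + V[i][j - 1] - e) < eps:
                    trace_v(i, j - 1)
                    j = i
                    break
            else:
                j -= 1

    trace_w(n)


# --- hairpin validation ------------------------------------------------------


@dataclass
class HairpinCriteria:
    """Thresholds for pre-miRNA acceptance.

    ``max_energy`` is the free-energy ceiling in kcal/mol (candidates must
    fold at or below it).  ``max_bulge`` / ``max_internal`` bound asymmetric
    bulges and total internal-loop size inside the mature:star duplex.
    """

    max_energy: float = -18.0
    max_bulge: int = 4
    max_internal: int = 6
    min_length: int = 40
    max_length: int = 400
    min_mature_paired_frac: float = 0.55
    overhang_tol: int = 1


@dataclass
class HairpinCandidate:
    """A candidate precursor: a (sub)sequence with its fold and mature placement.

    Spans are 0-based inclusive within ``sequence``.  ``locus`` optionally
    records the genomic origin as ``(chrom, start, end, strand)`` with 1-based
    inclusive coordinates.
    """

    sequence: str
    fold: FoldResult
    mature_span: tuple[int, int]
    star_span: Optional[tuple[int, int]] = None
    arm: Optional[str] = None
    locus: Optional[tuple[str, int, int, str]] = None


@dataclass
class HairpinDecision:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    star_span: Optional[tuple[int, int]] = None
    arm: Optional[str] = None

    def __bool__(self) -> bool:
        return self.passed


def validate_hairpin(candidate: HairpinCandidate,
                     criteria: HairpinCriteria | None = None) -> HairpinDecision:
    """Apply the hairpin acceptance criteria; reason codes name every failure.

    Reason codes: ``length``, ``arm`` (mature straddles the loop or is mostly
    unpaired), ``loop`` (no single terminal loop on the mature stem),
    ``overhang`` (mature:star duplex ends inconsistent with 2-nt 3'
    overhangs), ``bulge`` (oversized internal loop/bulge in the duplex) and
    ``energy``.
    """
    crit = criteria or HairpinCriteria()
    seq = candidate.sequence
    n = len(seq)
    ms, me = candidate.mature_span
    if not (0 <= ms <= me < n):
        raise ValueError(f"mature span {candidate.mature_span} outside sequence of length {n}")
    reasons: list[str] = []
    if not (crit.min_length <= n <= crit.max_length):
        reasons.append("length")
    pt = pair_table(candidate.fold.structure)

    mature_partners = [pt[k] for k in range(ms, me + 1) if pt[k] >= 0]
    arm: Optional[str] = None
    if len(mature_partners) < crit.min_mature_paired_frac * (me - ms + 1):
        reasons.append("arm")
    elif all(p > me for p in mature_partners):
        arm = "5p"
    elif all(p < ms for p in mature_partners):
        arm = "3p"
    else:
        reasons.append("arm")  # mature straddles the terminal loop

    if arm is not None:
        if not _single_terminal_loop(pt, ms, me, arm):
            reasons.append("loop")
        star = _derive_star(pt, ms, me, n)
        if star is None:
            reasons.append("overhang")
        else:
            if candidate.star_span is not None:
                ss, se = candidate.star_span
                if abs(ss - star[0]) > crit.overhang_tol or abs(se - star[1]) > crit.overhang_tol:
                    reasons.append("overhang")
            if "overhang" not in reasons and not _duplex_bulges_ok(pt, ms, me, crit):
                reasons.append("bulge")
        star_span = star
    else:
        star_span = None

    if not (candidate.fold.energy <= crit.max_energy):
        reasons.append("energy")

    return HairpinDecision(passed=not reasons, reasons=reasons,
                           star_span=star_span, arm=arm)


def _single_terminal_loop(pt: list[int], ms: int, me: int, arm: str) -> bool:
    """Walk inward from the mature's innermost pair; require exactly one
    terminal loop (no multibranch) between the mature and its star arm."""
    if arm == "5p":
        inner = max((k for k in range(ms, me + 1) if pt[k] >= 0), default=None)
    else:
        inner = min((k for k in range(ms, me + 1) if pt[k] >= 0), default=None)
    if inner is None:
        return False
    i, j = (inner, pt[inner]) if arm == "5p" else (pt[inner], inner)
    # descend through the nested helix; fail on branching (multiloop)
    while True:
        branches = []
        k = i + 1
        while k < j:
            if pt[k] > k:
                branches.append(k)
                k = pt[k] + 1
            else:
                k += 1
        if not branches:
            return True  # terminal loop reached
        if len(branches) > 1:
            return False
        i, j = branches[0], pt[branches[0]]


def _derive_star(pt: list[int], ms: int, me: int, n: int) -> Optional[tuple[int, int]]:
    """Star span implied by the fold and the canonical 2-nt 3' overhang rule.

    The mature 5' end and the base two in from its 3' end must both be paired
    (they anchor the duplex ends); the star then runs between their partners,
    extended by the 2-nt overhang.
    """
    if pt[ms] < 0 or me - 2 < ms or pt[me - 2] < 0:
        return None
    a, b = pt[me - 2], pt[ms] + 2
    if a > b or b >= n or a < 0:
        return None
    return (a, b)


def _duplex_bulges_ok(pt: list[int], ms: int, me: int, crit: HairpinCriteria) -> bool:
    paired = [k for k in range(ms, me + 1) if pt[k] >= 0]
    for k1, k2 in zip(paired, paired[1:]):
        gap_m = k2 - k1 - 1
        gap_s = abs(pt[k1] - pt[k2]) - 1
        if abs(gap_m - gap_s) > crit.max_bulge:
            return False
        if gap_m + gap_s > crit.max_internal:
            return False
    return True
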