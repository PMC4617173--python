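"""Degradome (PARE) mapping and miRNA target validation.

The degradome captures uncapped 5' ends of cleaved mRNAs.  A genuine
miRNA-guided cleavage leaves a tag whose 5' end sits on the transcript base
paired to miRNA position 10 (canonically) or 11.  Target validation therefore
combines three pieces of evidence: a plant-style complementarity score of at
most 4, the positional coincidence of a degradome 5' end with the predicted
cleavage site, and a shuffled-miRNA permutation p-value below 0.05.

Scoring follows the Allen rule: each mismatch costs 1.0, each G:U wobble 0.5
and each gap/bulge 1.0, with every penalty doubled inside the seed-proximal
core (miRNA positions 2-13, 1-based from the 5' end).  At most one gap is
allowed on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEGRADOME_TAG_LENGTHS = (20, 21)
CORE_START, CORE_END = 2, 13  # doubled-penalty region, 1-based miRNA positions
MISMATCH, WOBBLE, GAP = 1.0, 0.5, 1.0
MAX_SCORE = 4.0
CLEAVAGE_INDICES = (10, 11)

_COMPLEMENT = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA G:target U / miRNA U:target G


@dataclass
class TargetHit:
    """One validated miRNA:transcript interaction."""

    mirna_name: str
    transcript_id: str
    align_score: float
    cleavage_pos: int          # 1-based transcript coordinate of the tag 5' end
    mirna_cleavage_index: int  # 10 or 11
    tag_count_at_site: int
    category: int = -1
    p_value: float = float("nan")


def build_profiles(tags: pd.DataFrame, transcripts: dict[str, str],
                   lengths: tuple[int, ...] = DEGRADOME_TAG_LENGTHS
                   ) -> dict[str, np.ndarray]:
    """Accumulate degradome 5'-end counts per transcript position.

    ``tags`` needs columns ``sequence`` and ``count``.  Only tags whose
    length is in ``lengths`` (20-21 nt by default) are used; every exact
    sense-strand match adds the tag count at its 5'-end position (index 0 =
    transcript position 1).  Antisense matches are ignored.
    """
    profiles = {tid: np.zeros(len(seq), dtype=np.int64) for tid, seq in transcripts.items()}
    kmin = min(lengths)
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in transcripts.items():
        for i in range(len(seq) - kmin + 1):
            index.setdefault(seq[i:i + kmin], []).append((tid, i))
    for seq, count in zip(tags["sequence"], tags["count"]):
        if len(seq) not in lengths:
            continue
        for tid, pos in index.get(seq[:kmin], ()):
            full = transcripts[tid]
            if full[pos:pos + len(seq)] == seq:
                profiles[tid][pos] += count
    return profiles


def _pair_penalty(mi: str, tc: str) -> float:
    if (mi, tc) in _COMPLEMENT:
        return 0.0
    if (mi, tc) in _WOBBLE:
        return WOBBLE
    return MISMATCH


def _weight(mir_pos: int) -> float:
    return 2.0 if CORE_START <= mir_pos <= CORE_END else 1.0


def score_alignment(mirna: str, site: str,
                    cutoff: float = float("inf")) -> tuple[float, str]:
    """Minimal Allen-rule score of a miRNA against a candidate target site.

    ``site`` is the transcript window 5'->3' on the sense strand, antiparallel
    to the miRNA: miRNA position i pairs site position ``len(site) - i + 1``.
    The site may be one base shorter or longer than the miRNA (a single bulge
    on either strand); larger length differences score infinity.  Returns the
    score and a pairing string over miRNA positions 5'->3' ('|' paired,
    'o' wobble, '.' mismatch, '-' opposite a gap).

    Penalties are non-negative, so a finite ``cutoff`` lets the scorer abort
    as soon as the partial sum exceeds it (the result is then reported as
    infinity); scores at or below the cutoff are exact.
    """
    m = mirna.upper().replace("U", "T")
    s = site.upper().replace("U", "T")[::-1]  # s[i-1] now faces miRNA pos i
    M, S = len(m), len(s)
    if abs(M - S) > 1 or M == 0 or S == 0:
        return float("inf"), ""

    def gapless(mseq, sseq, base=0.0):
        score, pat = base, []
        for i, (a, b) in enumerate(zip(mseq, sseq), start=1):
            pen = _pair_penalty(a, b)
            score += pen * _weight(i)
            if score > cutoff:
                return float("inf"), ""
            pat.append("|" if pen == 0 else ("o" if pen == WOBBLE else "."))
        return score, "".join(pat)

    if M == S:
        return gapless(m, s)

    best, best_pat = float("inf"), ""
    if S == M + 1:
        # one bulged target base: skip one position of s
        for skip in range(S):
            trimmed = s[:skip] + s[skip + 1:]
            sc, pat = gapless(m, trimmed, base=GAP * _weight(min(skip + 1, M)))
            if sc < best:
                best, best_pat = sc, pat
    else:  # S == M - 1: one unpaired miRNA base
        for skip in range(M):
            trimmed = m[:skip] + m[skip + 1:]
            sc, pat = gapless(trimmed, s, base=GAP * _weight(skip + 1))
            if sc < best:
                best, best_pat = sc, pat[:skip] + "-" + pat[skip:]
    return best, best_pat


def _best_site_score(mirna: str, transcript: str, site_end: int,
                     cutoff: float = float("inf")) -> float:
    """Best score over the gapless and single-gap windows ending at
    ``site_end`` (0-based inclusive index of the base paired to miRNA
    position 1)."""
    M = len(mirna)
    best = float("inf")
    for span in (M, M - 1, M + 1):
        start = site_end - span + 1
        if start < 0 or site_end >= len(transcript):
            continue
        sc, _ = score_alignment(mirna, transcript[start:site_end + 1],
                                cutoff=min(cutoff, best))
        if sc < best:
            best = sc
    return best


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PEN_MATRIX = np.ones((5, 5))
for _a, _b in _COMPLEMENT:
    _PEN_MATRIX[_CODE[_a], _CODE[_b]] = 0.0
for _a, _b in _WOBBLE:
    _PEN_MATRIX[_CODE[_a], _CODE[_b]] = WOBBLE


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _screen_lower_bound(m_codes: np.ndarray, t_codes: np.ndarray,
                        site_ends: np.ndarray) -> np.ndarray:
    """Lower bound on the score of any <=1-gap alignment ending at each
    ``site_end``.

    In any such alignment miRNA position i pairs the target base at offset
    ``site_end - i + 1`` shifted by at most one, so the weighted sum of the
    per-position minimum penalty over the three phases never exceeds the true
    score (a gap column costs at least its position weight).
    """
    M = m_codes.size
    pad = M + 2  # keeps padded indices in range even at the transcript 5' end
    t_pad = np.concatenate([np.full(pad, 4, dtype=np.int8), t_codes,
                            np.full(2, 4, dtype=np.int8)])
    lb = np.zeros(site_ends.size)
    for i in range(M):  # miRNA position i+1 pairs target index site_end - i
        idx = site_ends - i + pad  # padded coordinates
        row = _PEN_MATRIX[m_codes[i]]
        pen = np.minimum.reduce([row[t_pad[idx - 1]], row[t_pad[idx]],
                                 row[t_pad[idx + 1]]])
        lb += pen * _weight(i + 1)
    return lb


def find_targets(mirnas: dict[str, str], transcripts: dict[str, str],
                 profiles: dict[str, np.ndarray], max_score: float = MAX_SCORE,
                 cleavage_indices: tuple[int, ...] = CLEAVAGE_INDICES
                 ) -> list[TargetHit]:
    """Emit every miRNA x transcript site with score <= ``max_score`` whose
    predicted cleavage position carries degradome signal.

    Candidate sites are anchored at degradome 5' ends: for each position with
    nonzero profile count, the windows implied by cleavage at miRNA position
    10 or 11 are scored.  A vectorised lower-bound screen discards candidate
    sites that cannot reach ``max_score`` before the exact scorer runs.
    Duplicates are reduced to one hit per (miRNA, transcript, cleavage
    position), keeping the best score.
    """
    hits: dict[tuple[str, str, int], TargetHit] = {}
    clean = {name: s.upper().replace("U", "T") for name, s in mirnas.items()}
    for tid, profile in profiles.items():
        seq = transcripts[tid]
        t_codes = _encode(seq)
        nz = np.nonzero(profile)[0]
        if nz.size == 0:
            continue
        cand = []
        for ci in cleavage_indices:
            ends = nz + ci - 1
            ok = ends < len(seq)
            cand.append(np.stack([nz[ok], ends[ok],
                                  np.full(int(ok.sum()), ci)], axis=1))
        cand = np.concatenate(cand, axis=0)
        for name in sorted(clean):
            mseq = clean[name]
            m_codes = _encode(mseq)
            lb = _screen_lower_bound(m_codes, t_codes, cand[:, 1])
            for p0, site_end, ci in cand[lb <= max_score]:
                sc = _best_site_score(mseq, seq, int(site_end), cutoff=max_score)
                if sc <= max_score:
                    key = (name, tid, int(p0) + 1)
                    prev = hits.get(key)
                    if prev is None or sc < prev.align_score:
                        hits[key] = TargetHit(
                            mirna_name=name, transcript_id=tid,
                            align_score=sc, cleavage_pos=int(p0) + 1,
                            mirna_cleavage_index=int(ci),
                            tag_count_at_site=int(profile[p0]))
    return [hits[k] for k in sorted(hits)]


def categorize(hit: TargetHit, profile: np.ndarray) -> int:
    """CleaveLand-style t-plot category of the cleavage signal.

    0: unique transcript maximum with more than one read; 1: tied maximum,
    more than one read; 2: above the median of nonzero positions but below
    the maximum; 3: at or below that median, more than one read; 4: exactly
    one read.
    """
    c = int(profile[hit.cleavage_pos - 1])
    if c <= 0:
        raise ValueError("no degradome signal at the cleavage position")
    if c == 1:
        return 4
    peak = int(profile.max())
    if c == peak:
        return 0 if int((profile == peak).sum()) == 1 else 1
    med = float(np.median(profile[profile > 0]))
    return 2 if c > med else 3


def target_pvalue(hit: TargetHit, mirna: str, transcript: str,
                  n_shuffles: int = 100, seed: int = 0) -> float:
    """Permutation p-value: fraction of shuffled miRNAs scoring at least as
    well at the same cleavage-coincident site (add-one smoothed).

    Shuffles are seeded Fisher-Yates permutations of the miRNA sequence, so
    the null preserves length and base composition.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be at least 20")
    m = mirna.upper().replace("U", "T")
    site_end = hit.cleavage_pos - 1 + hit.mirna_cleavage_index - 1
    observed = _best_site_score(m, transcript, site_end)
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(m.encode(), dtype="S1")
    k = 0
    for _ in range(n_shuffles):
        shuffled = b"".join(rng.permutation(letters)).decode()
        if _best_site_score(shuffled, transcript, site_end, cutoff=observed) <= observed:
            k += 1
    return (1 + k) / (1 + n_shuffles)


def validate_targets(mirnas: dict[str, str], transcripts: dict[str, str],
                     profiles: dict[str, np.ndarray], n_shuffles: int = 100,
                     seed: int = 0, max_score: float = MAX_SCORE,
                     max_p: float = 0.05) -> pd.DataFrame:
    """Full retained-hit table: score, coincidence, category and p-value.

    Hits with p >= ``max_p`` are dropped; the returned frame satisfies the
    retained-set rule (score <= 4, positional coincidence, p < 0.05) by
    construction.
    """
    rows = []
    for hit in find_targets(mirnas, transcripts, profiles, max_score=max_score):
        profile = profiles[hit.transcript_id]
        hit.category = categorize(hit, profile)
        hit.p_value = target_pvalue(hit, mirnas[hit.mirna_name],
                                    transcripts[hit.transcript_id],
                                    n_shuffles=n_shuffles, seed=seed)
        if hit.p_value < max_p:
            rows.append(vars(hit).copy())
    cols = ["mirna_name", "transcript_id", "align_score", "cleavage_pos",
            "mirna_cleavage_index", "tag_count_at_site", "category", "p_value"]
    return pd.DataFrame(rows, columns=cols)


def tplot_table(hit: TargetHit, profile: np.ndarray) -> pd.DataFrame:
    """Per-position table for a t-plot: position, count, cleavage marker."""
    return pd.DataFrame({
        "position": np.arange(1, len(profile) + 1),
        "count": profile,
        "is_cleavage_site": np.arange(1, len(profile) + 1) == hit.cleavage_pos,
    })
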