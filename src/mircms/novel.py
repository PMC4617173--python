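"""Novel miRNA discovery from genome-mapped small-RNA tags.

Forwarded tags (introns, exon antisense, unannotated) are mapped exactly to
the genome; around each locus, candidate precursor windows are folded and
subjected to the hairpin criteria.  A call additionally requires the mature
tag's copy number to exceed five.  Identical matures arising from several
loci are merged into a single record.

Window folding dominates runtime, so each window is first screened with a
fast semi-global alignment (edlib): a valid mature:star duplex implies a
near-reverse-complement of the tag elsewhere in the window, and windows
without one cannot pass the duplex criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import edlib

from ._seq import revcomp
from .fold import (FoldResult, HairpinCandidate, HairpinCriteria,
                   HairpinDecision, fold, validate_hairpin)

log = logging.getLogger(__name__)

COPY_NUMBER_MIN = 5          # calls require copy number strictly greater
MAX_LOCI = 20                # tags mapping to more loci are repetitive
WINDOWS = ((150, 150), (20, 200), (200, 20))  # (upstream, downstream) of the tag
PRESCREEN_MAX_DIST = 6       # edlib distance ceiling for the duplex screen
END_EDIT_WIDTH = 3           # editable terminal region for expression counting
MAX_END_EDITS = 3


class GenomeIndex:
    """Exact-occurrence index of a (single-chromosome) genome.

    An 18-mer prefix dictionary seeds candidate positions which are verified
    by direct comparison, so arbitrary tag lengths >= 18 nt are supported.
    Minus-strand occurrences are found through the reverse complement.
    """

    K = 18

    def __init__(self, genome: str, name: str = "chr1"):
        self.genome = genome.upper()
        self.name = name
        self._index: dict[str, list[int]] = {}
        g = self.genome
        for i in range(len(g) - self.K + 1):
            self._index.setdefault(g[i:i + self.K], []).append(i)

    def _find_forward(self, seq: str) -> list[int]:
        out = []
        g = self.genome
        for p in self._index.get(seq[: self.K], ()):
            if g[p:p + len(seq)] == seq:
                out.append(p)
        return out

    def find(self, tag: str) -> list[tuple[int, str]]:
        """All exact occurrences as ``(0-based start, strand)`` pairs."""
        tag = tag.upper()
        if len(tag) < self.K:
            raise ValueError(f"tag shorter than index k-mer size {self.K}")
        hits = [(p, "+") for p in self._find_forward(tag)]
        hits += [(p, "-") for p in self._find_forward(revcomp(tag))]
        return hits


def map_tags_to_genome(tags, genome: str | GenomeIndex,
                       max_loci: int = MAX_LOCI) -> dict[str, list[tuple[int, str]]]:
    """Exact loci for each tag; tags with more than ``max_loci`` occurrences
    are flagged repetitive and dropped."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    out: dict[str, list[tuple[int, str]]] = {}
    n_rep = 0
    for tag in tags:
        loci = index.find(tag)
        if len(loci) > max_loci:
            n_rep += 1
            continue
        if loci:
            out[tag] = loci
    if n_rep:
        log.info("dropped %d repetitive tags (> %d loci)", n_rep, max_loci)
    return out


@dataclass
class NovelCall:
    """A merged novel-miRNA call."""

    name: str
    mature_sequence: str
    candidate: HairpinCandidate
    copy_number: int
    arm: Optional[str]
    has_star: bool = False
    n_precursors: int = 1
    loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    count_control: int = 0
    count_cms: int = 0


def _window_candidate(index: GenomeIndex, pos: int, strand: str, tag: str,
                      up: int, down: int, backend: str,
                      criteria: HairpinCriteria,
                      prescreen: int = PRESCREEN_MAX_DIST
                      ) -> Optional[tuple[HairpinCandidate, HairpinDecision]]:
    """Fold one genomic window around a tag locus and validate it.

    Windows running over a chromosome end are truncated.  Returns ``None``
    when the window fails the duplex pre-screen or the hairpin criteria.
    """
    g = index.genome
    L = len(tag)
    if strand == "+":
        start = max(0, pos - up)
        end = min(len(g), pos + L + down)
        window = g[start:end]
        m0 = pos - start
    else:
        start = max(0, pos - down)
        end = min(len(g), pos + L + up)
        window = revcomp(g[start:end])
        m0 = end - (pos + L)
    mature_span = (m0, m0 + L - 1)

    # duplex pre-screen: a near revcomp of the tag must exist in the window
    masked = window[:m0] + "N" * L + window[m0 + L:]
    res = edlib.align(revcomp(tag), masked, mode="HW", task="distance",
                      k=prescreen)
    if res["editDistance"] == -1:
        return None

    fr = fold(window, backend=backend)
    cand = HairpinCandidate(sequence=window, fold=fr, mature_span=mature_span,
                            locus=(index.name, start + 1, end, strand))
    decision = validate_hairpin(cand, criteria)
    if not decision:
        return None
    cand.arm = decision.arm
    cand.star_span = decision.star_span
    return cand, decision


def call_novel(loci: dict[str, list[tuple[int, str]]], genome: str | GenomeIndex,
               counts: dict[str, tuple[int, int]],
               backend: str = "auto", criteria: HairpinCriteria | None = None,
               copy_min: int = COPY_NUMBER_MIN,
               windows: tuple[tuple[int, int], ...] = WINDOWS,
               all_tag_set: Optional[set[str]] = None) -> list[NovelCall]:
    """Mireap-style novel-miRNA calling.

    ``loci`` maps tag sequence to its genomic occurrences, ``counts`` maps
    tag sequence to per-sample counts ``(control, cms)``.  For each locus of
    each sufficiently abundant tag, three windows are folded and the best
    valid hairpin (lowest energy) retained.  Identical matures from multiple
    loci merge into one call with ``n_precursors`` incremented.  ``has_star``
    is set when a sequenced tag matches the predicted star arm (within a
    2-nt shift).

    Calls are named ``novel-miR-N`` in order of decreasing total copy number
    (ties broken by sequence), making the numbering deterministic.
    """
    criteria = criteria or HairpinCriteria()
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    tag_set = all_tag_set if all_tag_set is not None else set(counts)

    merged: dict[str, NovelCall] = {}
    for tag in sorted(loci):
        c_ctrl, c_cms = counts.get(tag, (0, 0))
        copy = c_ctrl + c_cms
        if not copy > copy_min:
            continue
        for pos, strand in sorted(loci[tag]):
            best: Optional[HairpinCandidate] = None
            for up, down in windows:
                got = _window_candidate(index, pos, strand, tag, up, down,
                                        backend, criteria)
                if got is None:
                    continue
                cand, _ = got
                if best is None or cand.fold.energy < best.fold.energy:
                    best = cand
            if best is None:
                continue
            call = merged.get(tag)
            if call is None:
                call = NovelCall(name="", mature_sequence=tag, candidate=best,
                                 copy_number=copy, arm=best.arm,
                                 loci=[best.locus],
                                 count_control=c_ctrl, count_cms=c_cms)
                call.has_star = _star_observed(best, tag_set)
                merged[tag] = call
            else:
                call.n_precursors += 1
                call.loci.append(best.locus)
                if best.fold.energy < call.candidate.fold.energy:
                    call.candidate = best
                    call.arm = best.arm
                call.has_star = call.has_star or _star_observed(best, tag_set)

    calls = sorted(merged.values(),
                   key=lambda c: (-c.copy_number, c.mature_sequence))
    for i, call in enumerate(calls, start=1):
        call.name = f"novel-miR-{i}"
    return calls


def _star_observed(cand: HairpinCandidate, tag_set: set[str]) -> bool:
    if cand.star_span is None:
        return False
    a, b = cand.star_span
    seq = cand.sequence
    for da in (-2, -1, 0, 1, 2):
        s = seq[max(0, a + da): b + 1 + da]
        if len(s) >= 18 and s in tag_set:
            return True
    return False


def tag_matches_mature(tag: str, mature: str, end_width: int = END_EDIT_WIDTH,
                       max_end_edits: int = MAX_END_EDITS) -> bool:
    """Expression-counting rule: edits confined to the terminal regions.

    A tag contributes to a mature's count when some end-offset alignment has
    an exactly matching core (mature positions ``end_width+1`` ..
    ``len-end_width``) and at most ``max_end_edits`` total edited columns
    (substitutions, trims or overhangs), all within ``end_width`` nt of the
    respective ends.
    """
    M = len(mature)
    core_lo, core_hi = end_width, M - end_width  # 0-based half-open core
    for shift in range(-max_end_edits, max_end_edits + 1):
        # tag index i aligns mature index i + shift
        edits = 0
        ok = True
        for mi in range(M):
            ti = mi - shift
            covered = 0 <= ti < len(tag)
            if core_lo <= mi < core_hi:
                if not covered or tag[ti] != mature[mi]:
                    ok = False
                    break
            else:
                if not covered or tag[ti] != mature[mi]:
                    edits += 1
        if not ok:
            continue
        # tag overhangs beyond the mature ends
        for ti in range(len(tag)):
            mi = ti + shift
            if not (0 <= mi < M):
                edits += 1
                near5 = ti < end_width or mi < 0
                near3 = ti >= len(tag) - end_width or mi >= M
                if not (near5 or near3):
                    ok = False
                    break
        if ok and edits <= max_end_edits:
            return True
    return False


def count_novel_expression(calls: list[NovelCall],
                           counts: dict[str, tuple[int, int]],
                           candidates: Optional[dict[str, list[str]]] = None
                           ) -> dict[str, tuple[int, int]]:
    """Per-sample expression of each call under the end-tolerant rule.

    ``candidates`` optionally restricts, per call name, which tag sequences
    are tested (e.g. tags whose genomic locus overlaps the mature locus);
    without it every tag is compared, which is only sensible for small tables.
    """
    out: dict[str, tuple[int, int]] = {}
    for call in calls:
        pool = candidates.get(call.name, []) if candidates is not None else list(counts)
        ctrl = cms = 0
        for tag in pool:
            if tag not in counts:
                continue
            if tag_matches_mature(tag, call.mature_sequence):
                a, b = counts[tag]
                ctrl += a
                cms += b
        out[call.name] = (ctrl, cms)
        call.count_control, call.count_cms = ctrl, cms
    return out
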