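"""Small-RNA read cleaning, tag collapsing, known-miRNA identification,
family expansion and hierarchical annotation.

Known-miRNA identification follows the two-rule scheme used for miRBase
references: a tag must match a reference precursor exactly (no mismatches)
and overlap a reference mature miRNA by at least 16 nt in precursor
coordinates, which tolerates processing offsets.  Family expansion relaxes
matching to two edits against mature miRNAs of other plant species and then
demands a valid hairpin at the tag's genomic locus — candidates whose locus
does not fold are pseudo-miRNAs and are discarded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import edlib
import numpy as np
import pandas as pd

from ._seq import iter_fastq
from .fold import HairpinCriteria
from .novel import GenomeIndex, _window_candidate

log = logging.getLogger(__name__)

MIN_TAG_LEN, MAX_TAG_LEN = 18, 30
POLYA_FRACTION = 0.8
MIN_MEAN_QUALITY = 20.0
KNOWN_MIN_OVERLAP = 16
FAMILY_MAX_EDITS = 2
FAMILY_WINDOW = 150

#: annotation categories in priority order (highest first); a tag receives
#: exactly one category.
ANNOTATION_PRIORITY = [
    "known_miRNA", "rRNA", "scRNA", "snRNA", "snoRNA", "tRNA", "repeat",
    "exon_sense", "exon_antisense", "intron_sense", "intron_antisense",
    "unannotated",
]
#: categories whose tags are forwarded to novel-miRNA prediction
FORWARDED_CATEGORIES = {"exon_antisense", "intron_sense", "intron_antisense",
                        "unannotated"}


@dataclass
class Adapters:
    three_prime: Optional[str] = None
    five_prime: Optional[str] = None


@dataclass
class CleaningReport:
    """Bookkeeping for read cleaning; removals plus survivors balance to
    the raw total."""

    n_raw: int = 0
    n_malformed: int = 0
    n_low_quality: int = 0
    n_3adapter_null: int = 0
    n_insert_null: int = 0
    n_5adapter_contaminant: int = 0
    n_shorter_than_18: int = 0
    n_polyA: int = 0
    n_longer_than_30: int = 0
    n_clean: int = 0

    def balances(self) -> bool:
        removed = (self.n_malformed + self.n_low_quality + self.n_3adapter_null
                   + self.n_insert_null + self.n_5adapter_contaminant
                   + self.n_shorter_than_18 + self.n_polyA + self.n_longer_than_30)
        return self.n_raw == self.n_clean + removed


def clean_reads(reads, adapters: Adapters | None = None,
                min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN,
                polya_fraction: float = POLYA_FRACTION,
                min_mean_quality: float = MIN_MEAN_QUALITY
                ) -> tuple[list[str], CleaningReport]:
    """Filter and adapter-trim raw reads into clean 18-30 nt inserts.

    ``reads`` is a FASTQ path or an iterable of ``(id, sequence, qualities)``
    triples (``qualities`` may be ``None``).  Filters are applied in report
    order: malformed records are skipped with a logged count, then low
    quality (mean phred below threshold or any N), missing 3' adapter, empty
    insert, 5'-adapter contamination, length below 18 nt, poly-A (>= 80%
    adenine over the insert) and length above 30 nt.  An empty input is not
    an error and yields an empty output with a zeroed report.
    """
    if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
        reads = iter_fastq(reads)
    adapters = adapters or Adapters()
    a3 = adapters.three_prime[:8] if adapters.three_prime else None
    a5 = adapters.five_prime[-8:] if adapters.five_prime else None
    report = CleaningReport()
    clean: list[str] = []
    for item in reads:
        report.n_raw += 1
        try:
            _rid, seq, qual = item
            seq = seq.upper()
            if not seq or (qual is not None and len(qual) != len(seq)):
                raise ValueError("empty sequence or quality length mismatch")
        except (TypeError, ValueError):
            report.n_malformed += 1
            continue
        if "N" in seq or (qual is not None and np.mean(qual) < min_mean_quality):
            report.n_low_quality += 1
            continue
        insert = seq
        if a3 is not None:
            idx = seq.find(a3)
            if idx < 0:
                report.n_3adapter_null += 1
                continue
            insert = seq[:idx]
            if not insert:
                report.n_insert_null += 1
                continue
        if a5 is not None and a5 in insert:
            report.n_5adapter_contaminant += 1
            continue
        if len(insert) < min_len:
            report.n_shorter_than_18 += 1
            continue
        if insert.count("A") / len(insert) >= polya_fraction:
            report.n_polyA += 1
            continue
        if len(insert) > max_len:
            report.n_longer_than_30 += 1
            continue
        report.n_clean += 1
        clean.append(insert)
    if report.n_malformed:
        log.warning("skipped %d malformed records", report.n_malformed)
    return clean, report


def collapse_tags(sample_streams: dict[str, Iterable[str]]
                  ) -> tuple[pd.DataFrame, dict]:
    """Collapse per-sample clean reads into a unique-tag count table.

    Returns a frame with one row per distinct sequence and a ``count_<sample>``
    column per sample, plus sharing statistics over total and unique tags
    (sample-specific vs shared).
    """
    samples = list(sample_streams)
    tallies = {s: pd.Series(list(sample_streams[s]), dtype=object).value_counts()
               for s in samples}
    df = pd.DataFrame({f"count_{s}": tallies[s] for s in samples}).fillna(0).astype(np.int64)
    df.index.name = "sequence"
    df = df.sort_index().reset_index()

    stats: dict = {"samples": samples}
    counts = df[[f"count_{s}" for s in samples]].to_numpy()
    present = counts > 0
    stats["total_tags"] = int(counts.sum())
    stats["unique_tags"] = int(len(df))
    if len(samples) == 2:
        shared = present.all(axis=1)
        stats["unique_shared"] = int(shared.sum())
        stats["total_shared"] = int(counts[shared].sum())
        stats["shared_total_fraction"] = (stats["total_shared"] / stats["total_tags"]
                                          if stats["total_tags"] else 0.0)
        for i, s in enumerate(samples):
            specific = present[:, i] & ~shared
            stats[f"unique_specific_{s}"] = int(specific.sum())
            stats[f"total_specific_{s}"] = int(counts[specific, i].sum())
    return df, stats


def shared_fraction(total_tags: float, shared_tags: float) -> float:
    """Fraction of all sequenced tags present in both samples."""
    if total_tags <= 0:
        raise ValueError("total_tags must be positive")
    return shared_tags / total_tags


_ARM_RE = re.compile(r"-(5p|3p)$")
_FAMILY_RE = re.compile(r"^(?:[a-z]{2,4}-)?(mir[0-9]+|miR[0-9]+|let[0-9]+)",
                        re.IGNORECASE)


def mirna_family(name: str) -> str:
    """Family label from a mature-miRNA name (species prefix, arm and
    letter/number variant suffixes stripped): ``bra-miR157a-5p`` -> ``miR157``."""
    m = _FAMILY_RE.match(name)
    if m:
        fam = m.group(1)
        return "miR" + re.sub(r"[^0-9]", "", fam)
    return _ARM_RE.sub("", name)


def _mature_arm(name: str) -> str:
    m = _ARM_RE.search(name)
    return m.group(1) if m else "unknown"


def match_known(tags: pd.DataFrame, precursors: dict[str, str],
                matures: dict[str, str], min_overlap: int = KNOWN_MIN_OVERLAP
                ) -> tuple[pd.DataFrame, pd.Series]:
    """Identify known miRNAs among collapsed tags.

    A tag qualifies iff it occurs exactly within a reference precursor and
    overlaps a reference mature by >= ``min_overlap`` nt in precursor
    coordinates.  Expression of a mature is the sum of counts of all
    qualifying tags; matures sharing an identical sequence across precursors
    collapse into one record.

    Returns the record table and a boolean mask (aligned with ``tags``)
    flagging matched rows.
    """
    if not precursors or not matures:
        raise ValueError("empty reference")
    # locate each mature inside each precursor
    mature_sites: dict[str, list[tuple[str, int, int]]] = {}  # pid -> (name, s, e)
    for mname, mseq in matures.items():
        mseq = mseq.upper().replace("U", "T")
        for pid, pseq in precursors.items():
            start = pseq.find(mseq)
            while start >= 0:
                mature_sites.setdefault(pid, []).append((mname, start, start + len(mseq) - 1))
                start = pseq.find(mseq, start + 1)

    # substring index over precursors for exact tag placement
    sub_index: dict[str, list[tuple[str, int]]] = {}
    for pid, pseq in precursors.items():
        for L in range(MIN_TAG_LEN, MAX_TAG_LEN + 1):
            for i in range(len(pseq) - L + 1):
                sub_index.setdefault(pseq[i:i + L], []).append((pid, i))

    count_cols = [c for c in tags.columns if c.startswith("count_")]
    per_mature: dict[str, dict] = {}
    matched = np.zeros(len(tags), dtype=bool)
    for row_i, (tag, *cnts) in enumerate(zip(tags["sequence"],
                                             *[tags[c] for c in count_cols])):
        placements = sub_index.get(tag)
        if not placements:
            continue
        assigned: set[str] = set()
        pids: dict[str, set[str]] = {}
        for pid, pos in placements:
            te = pos + len(tag) - 1
            for mname, ms, me in mature_sites.get(pid, ()):
                if min(te, me) - max(pos, ms) + 1 >= min_overlap:
                    assigned.add(mname)
                    pids.setdefault(mname, set()).add(pid)
        if not assigned:
            continue
        matched[row_i] = True
        for mname in assigned:
            rec = per_mature.setdefault(mname, {
                "name": mname,
                "mature_sequence": matures[mname].upper().replace("U", "T"),
                "arm": _mature_arm(mname), "family": mirna_family(mname),
                "source": "brapa_known", "precursor_ids": set(),
                **{c: 0 for c in count_cols},
            })
            rec["precursor_ids"] |= pids[mname]
            for c, v in zip(count_cols, cnts):
                rec[c] += int(v)

    # collapse matures with identical sequence (multi-precursor matures)
    by_seq: dict[str, dict] = {}
    for mname in sorted(per_mature):
        rec = per_mature[mname]
        seq = rec["mature_sequence"]
        if seq in by_seq:
            keep = by_seq[seq]
            keep["precursor_ids"] |= rec["precursor_ids"]
        else:
            by_seq[seq] = rec
    records = pd.DataFrame([
        {**r, "precursor_ids": ",".join(sorted(r["precursor_ids"]))}
        for r in by_seq.values()
    ])
    if not records.empty:
        records = records.sort_values("name").reset_index(drop=True)
    return records, pd.Series(matched, index=tags.index)


def expand_families(tags: pd.DataFrame, foreign_matures: dict[str, str],
                    genome: str | GenomeIndex | None,
                    backend: str = "auto",
                    criteria: HairpinCriteria | None = None,
                    max_edits: int = FAMILY_MAX_EDITS,
                    window: int = FAMILY_WINDOW) -> pd.DataFrame:
    """Expand miRNA families with tags matching other species' matures.

    For each tag the closest foreign mature within ``max_edits`` edits
    (substitutions and gap columns, end offsets free) is found with a
    semi-global alignment.  Per family, the highest-expressed matching tag is
    taken as the temporary family representative; its genomic loci are folded
    (+/- ``window`` nt) and only loci passing the hairpin criteria survive.
    Candidates without a valid hairpin are pseudo-miRNAs and are dropped.
    """
    if genome is None:
        log.warning("no genome supplied; family-expansion stage skipped")
        return pd.DataFrame(columns=["name", "mature_sequence", "family",
                                     "source", "locus", "energy"])
    criteria = criteria or HairpinCriteria()
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    count_cols = [c for c in tags.columns if c.startswith("count_")]

    foreign = {n: s.upper().replace("U", "T") for n, s in foreign_matures.items()}
    best_per_family: dict[str, tuple[int, str]] = {}
    for tag, *cnts in zip(tags["sequence"], *[tags[c] for c in count_cols]):
        total = int(sum(cnts))
        for fname, fseq in foreign.items():
            short, long_ = (tag, fseq) if len(tag) <= len(fseq) else (fseq, tag)
            res = edlib.align(short, long_, mode="HW", task="distance", k=max_edits)
            if res["editDistance"] == -1:
                continue
            fam = mirna_family(fname)
            cur = best_per_family.get(fam)
            if cur is None or total > cur[0]:
                best_per_family[fam] = (total, tag)

    rows = []
    for fam in sorted(best_per_family):
        total, tag = best_per_family[fam]
        try:
            loci = index.find(tag)
        except ValueError:
            continue
        for pos, strand in sorted(loci):
            got = _window_candidate(index, pos, strand, tag, window, window,
                                    backend, criteria)
            if got is None:
                continue
            cand, _decision = got
            rows.append({"name": f"{fam}-like", "mature_sequence": tag,
                         "family": fam, "source": "family_expansion",
                         "locus": cand.locus, "energy": cand.fold.energy})
            break  # one validated locus is enough to accept the member
    return pd.DataFrame(rows, columns=["name", "mature_sequence", "family",
                                       "source", "locus", "energy"])


def _paint(length: int, intervals: list[tuple[int, int]], code: int,
           arr: np.ndarray) -> None:
    for s, e in intervals:
        s0 = max(0, s - 1)
        arr[s0:e] = np.minimum(arr[s0:e], code)


def annotate_hierarchy(tags: pd.DataFrame, genome_index: GenomeIndex | None,
                       intervals: pd.DataFrame | None,
                       decoys: dict[str, list[str]] | None,
                       known_mask: pd.Series | None = None,
                       loci: dict[str, list[tuple[int, str]]] | None = None
                       ) -> pd.DataFrame:
    """Assign exactly one annotation category per tag by the priority order.

    ``intervals`` holds 1-based inclusive genomic features with columns
    ``start``, ``end``, ``strand`` and ``category`` (``exon``, ``intron`` or
    ``repeat``); ``decoys`` maps structural-RNA categories (rRNA, tRNA, ...)
    to reference sequences matched by exact substring.  Exon and intron
    become sense/antisense according to the tag's mapping strand.  Tags in
    forwarded categories feed novel-miRNA prediction.
    """
    n = len(tags)
    rank = np.full(n, ANNOTATION_PRIORITY.index("unannotated"), dtype=np.int16)

    if known_mask is not None:
        rank[known_mask.to_numpy()] = ANNOTATION_PRIORITY.index("known_miRNA")

    # structural-RNA decoys: exact substring containment
    if decoys:
        decoy_subs: dict[str, int] = {}
        for cat in ("rRNA", "scRNA", "snRNA", "snoRNA", "tRNA"):
            code = ANNOTATION_PRIORITY.index(cat)
            for seq in decoys.get(cat, ()):
                seq = seq.upper()
                for L in range(MIN_TAG_LEN, MAX_TAG_LEN + 1):
                    for i in range(len(seq) - L + 1):
                        sub = seq[i:i + L]
                        if decoy_subs.get(sub, 99) > code:
                            decoy_subs[sub] = code
        for i, tag in enumerate(tags["sequence"]):
            code = decoy_subs.get(tag)
            if code is not None and code < rank[i]:
                rank[i] = code

    # genomic intervals: per-base priority arrays per annotation strand
    if genome_index is not None and intervals is not None and len(intervals):
        G = len(genome_index.genome)
        unann = ANNOTATION_PRIORITY.index("unannotated")
        arr = {"+": np.full(G, 99, dtype=np.int16),
               "-": np.full(G, 99, dtype=np.int16)}
        cat_base = {"repeat": ("repeat", "repeat"),
                    "exon": ("exon_sense", "exon_antisense"),
                    "intron": ("intron_sense", "intron_antisense")}
        for _, row in intervals.iterrows():
            if row["category"] not in cat_base:
                continue
            _paint(G, [(int(row["start"]), int(row["end"]))],
                   ANNOTATION_PRIORITY.index(cat_base[row["category"]][0]),
                   arr[row["strand"]])
        for i, tag in enumerate(tags["sequence"]):
            if rank[i] < ANNOTATION_PRIORITY.index("repeat"):
                continue  # already annotated at higher priority
            if loci is not None:
                tag_loci = loci.get(tag, ())
            else:
                try:
                    tag_loci = genome_index.find(tag)
                except ValueError:
                    tag_loci = ()
            best = unann
            for pos, strand in tag_loci:
                if pos + len(tag) > G:
                    continue
                span = slice(pos, pos + len(tag))
                same = int(arr[strand][span].min())
                opp = int(arr["-" if strand == "+" else "+"][span].min())
                cand = min(same if same < 99 else unann,
                           _antisense_code(opp) if opp < 99 else unann)
                if cand < best:
                    best = cand
            if best < rank[i]:
                rank[i] = best

    out = tags.copy()
    out["annotation"] = [ANNOTATION_PRIORITY[r] for r in rank]
    out["forwarded"] = out["annotation"].isin(FORWARDED_CATEGORIES)
    return out


def _antisense_code(sense_code: int) -> int:
    cat = ANNOTATION_PRIORITY[sense_code]
    if cat == "exon_sense":
        return ANNOTATION_PRIORITY.index("exon_antisense")
    if cat == "intron_sense":
        return ANNOTATION_PRIORITY.index("intron_antisense")
    return sense_code


def map_tags_to_genome_lazy(sequences, genome_index: GenomeIndex
                            ) -> dict[str, list[tuple[int, str]]]:
    out = {}
    for tag in sequences:
        try:
            hits = genome_index.find(tag)
        except ValueError:
            continue
        if hits:
            out[tag] = hits
    return out
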