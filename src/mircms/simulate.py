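"""Synthetic two-condition study generator.

Emulates the three sequencing layers of a CMS-versus-maintainer bud
experiment: a small genome with planted miRNA precursors, a transcriptome
with planted cleavage-target sites, and tag-count tables for small-RNA,
degradome and RNA-seq libraries with planted fold changes.  Every planted
feature is recorded in a truth table so each pipeline stage can be scored
against known ground truth.

All randomness flows from one root seed through named substreams (genome,
transcriptome, srna, degradome, rnaseq), so stages regenerate independently
and identical configurations give byte-identical outputs.

Planted precursors are built as perfect inverted repeats: a 30-nt arm
carrying the 21-nt mature, an 8-nt A/C loop (which cannot base-pair), and
the arm's reverse complement.  With a mildly GC-biased composition the stem
folds 10+ kcal/mol below the -18 kcal/mol acceptance ceiling under both the
thermodynamic and the simplified energy model, and the mature:star duplex
carries the canonical 2-nt 3' overhangs by construction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import revcomp, write_fasta
from .degradome import CORE_START, CORE_END, score_alignment
from .fold import HairpinCandidate, HairpinCriteria, fold, validate_hairpin

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_GC_BIAS = np.array([0.22, 0.28, 0.28, 0.22])
MATURE_LEN = 21
ARM_LEN = 30
LOOP_LEN = 8
PRECURSOR_LEN = 2 * ARM_LEN + LOOP_LEN
MATURE_OFFSET = 5  # 0-based mature start within the 5' arm
ENERGY_MARGIN = 10.0  # precursors fold at least this far below the ceiling


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror a desk-scale version of a bud small-RNA study: one
    million small-RNA tags per sample, ten planted novel miRNAs, five
    planted cleavage targets whose miRNAs carry two-fold (|log2fc| = 1)
    expression changes, and half of each library drawn from background
    degradation products.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_known_mirnas: int = 10
    n_novel_mirnas: int = 10
    n_transcripts: int = 50
    transcript_length_range: tuple[int, int] = (500, 1500)
    n_planted_targets: int = 5
    planted_log2fc: tuple[float, ...] = (-1.0, -1.0, -1.0, 1.0, 1.0)
    planted_target_scores: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    srna_depth: int = 1_000_000
    degradome_depth: int = 200_000
    rnaseq_depth: int = 2_000_000
    background_fraction: float = 0.5
    noise_model: str = "poisson"
    nb_dispersion: float = 0.1
    star_fraction: float = 0.02       # star-strand abundance relative to mature
    decoy_fraction: float = 0.1       # share of sRNA background from rRNA/tRNA decoys
    n_degradome_background: int = 10_000
    fold_backend: str = "auto"

    def validate(self) -> None:
        if self.genome_length < 10 * (self.n_known_mirnas + self.n_novel_mirnas) * PRECURSOR_LEN:
            raise ValueError("genome too short for the requested precursors "
                             "(need >= 10x total precursor length)")
        if not (0.0 <= self.background_fraction <= 1.0):
            raise ValueError("background_fraction must be in [0, 1]")
        if self.noise_model not in {"poisson", "nbinom"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.n_planted_targets > self.n_transcripts:
            raise ValueError("more planted targets than transcripts")
        for depth in (self.srna_depth, self.degradome_depth, self.rnaseq_depth):
            if depth <= 0:
                raise ValueError("depths must be positive")

    def substream(self, name: str) -> np.random.Generator:
        order = ("genome", "transcriptome", "srna", "degradome", "rnaseq")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(order))[order.index(name)])


@dataclass
class PlantedMiRNA:
    name: str
    mature: str
    star: str
    precursor: str
    locus: tuple[str, int, int, str]  # 1-based inclusive
    arm: str
    kind: str  # "known" | "novel"


@dataclass
class TruthTable:
    """Ground truth of every planted feature."""

    planted_mirnas: list[PlantedMiRNA] = field(default_factory=list)
    planted_targets: list[dict] = field(default_factory=list)
    mirna_fc: dict[str, float] = field(default_factory=dict)
    gene_fc: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    genome: str
    truth: TruthTable
    known_precursors: dict[str, str]
    known_matures: dict[str, str]
    intervals: pd.DataFrame
    decoys: dict[str, list[str]]
    transcripts: dict[str, str] = field(default_factory=dict)
    srna_counts: Optional[pd.DataFrame] = None
    degradome: Optional[dict[str, pd.DataFrame]] = None
    rnaseq_counts: Optional[pd.DataFrame] = None


def load_decoys() -> dict[str, list[str]]:
    """Bundled synthetic rRNA/tRNA fragment set used as annotation decoys."""
    text = (importlib.resources.files("mircms") / "data" / "decoys.tsv").read_text()
    out: dict[str, list[str]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("category"):
            continue
        cat, _name, seq = line.split("\t")
        out.setdefault(cat, []).append(seq)
    return out


def _random_seq(rng: np.random.Generator, n: int, p=None) -> str:
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _build_precursor(rng: np.random.Generator, backend: str) -> tuple[str, str, str]:
    """One planted precursor; returns (precursor, mature, star).

    Resamples until the whole precursor folds at least ``ENERGY_MARGIN``
    below the acceptance ceiling, so both energy backends agree on every
    decision.
    """
    crit = HairpinCriteria()
    for _ in range(40):
        mature = _random_seq(rng, MATURE_LEN, _GC_BIAS)
        ext5 = _random_seq(rng, MATURE_OFFSET, _GC_BIAS)
        ext3 = _random_seq(rng, ARM_LEN - MATURE_OFFSET - MATURE_LEN, _GC_BIAS)
        arm5 = ext5 + mature + ext3
        loop = rng.choice(np.frombuffer(b"AC", dtype="S1"),
                          size=LOOP_LEN).tobytes().decode()
        precursor = list(arm5 + loop + revcomp(arm5))
        # two isolated star-side mismatches (1x1 internal loops) keep the
        # stem realistic and prevent the mature's exact reverse complement
        # from appearing in the genome
        last = PRECURSOR_LEN - 1
        for k in (MATURE_OFFSET + 5, MATURE_OFFSET + 13):
            partner = last - k
            wc = {"A": "T", "C": "G", "G": "C", "T": "A"}[precursor[k]]
            bad = {wc, precursor[partner]}
            if precursor[k] in "GT":  # avoid creating a G:U wobble pair
                bad.add({"G": "T", "T": "G"}[precursor[k]])
            precursor[partner] = next(b for b in "ACGT" if b not in bad)
        precursor = "".join(precursor)
        fr = fold(precursor, backend=backend)
        if fr.energy > crit.max_energy - ENERGY_MARGIN:
            continue
        ms = MATURE_OFFSET
        me = ms + MATURE_LEN - 1
        cand = HairpinCandidate(sequence=precursor, fold=fr, mature_span=(ms, me))
        decision = validate_hairpin(cand, crit)
        if not decision:
            continue
        ss, se = decision.star_span
        return precursor, mature, precursor[ss:se + 1]
    raise RuntimeError("failed to construct a valid precursor; widen the margin")


def make_genome(cfg: SimulationConfig) -> SyntheticStudy:
    """Genome with embedded precursors, reference set, annotation and decoys."""
    cfg.validate()
    rng = cfg.substream("genome")
    n_total = cfg.n_known_mirnas + cfg.n_novel_mirnas

    genome = np.array(list(_random_seq(rng, cfg.genome_length)), dtype="U1")
    truth = TruthTable()
    known_precursors: dict[str, str] = {}
    known_matures: dict[str, str] = {}

    # non-overlapping insertion slots, well separated
    gap = 400
    slots = np.sort(rng.choice(
        np.arange(gap, cfg.genome_length - gap - PRECURSOR_LEN,
                  PRECURSOR_LEN + gap), size=n_total, replace=False))
    occupied: list[tuple[int, int]] = []
    for i, start in enumerate(slots):
        precursor, mature, star = _build_precursor(rng, cfg.fold_backend)
        strand = "+" if rng.random() < 0.5 else "-"
        ins = precursor if strand == "+" else revcomp(precursor)
        genome[start:start + PRECURSOR_LEN] = list(ins)
        locus = ("chr1", int(start) + 1, int(start) + PRECURSOR_LEN, strand)
        occupied.append((int(start), int(start) + PRECURSOR_LEN))
        kind = "known" if i < cfg.n_known_mirnas else "novel"
        if kind == "known":
            name = f"syn-miR{i + 1:03d}-5p"
            known_precursors[f"syn-MIR{i + 1:03d}"] = precursor
            known_matures[name] = mature
        else:
            name = f"planted-novel-{i - cfg.n_known_mirnas + 1}"
        truth.planted_mirnas.append(PlantedMiRNA(
            name=name, mature=mature, star=star, precursor=precursor,
            locus=locus, arm="5p", kind=kind))

    genome_str = "".join(genome)
    intervals = _make_intervals(cfg, rng, occupied)
    return SyntheticStudy(config=cfg, genome=genome_str, truth=truth,
                          known_precursors=known_precursors,
                          known_matures=known_matures,
                          intervals=intervals, decoys=load_decoys())


def _make_intervals(cfg: SimulationConfig, rng: np.random.Generator,
                    occupied: list[tuple[int, int]]) -> pd.DataFrame:
    """Gene models (exon/intron) and repeats avoiding precursor loci."""
    margin = 250
    forbidden = [(max(0, s - margin), e + margin) for s, e in occupied]

    def clashes(s, e):
        return any(s < fe and fs < e for fs, fe in forbidden)

    rows = []
    n_genes, n_repeats = 25, 10
    for _ in range(n_genes * 4):
        if n_genes == 0:
            break
        glen = int(rng.integers(1500, 2500))
        s = int(rng.integers(0, cfg.genome_length - glen))
        if clashes(s, s + glen):
            continue
        n_genes -= 1
        strand = "+" if rng.random() < 0.5 else "-"
        forbidden.append((s, s + glen))
        # exon/intron/exon/intron/exon partition
        cuts = np.sort(rng.integers(100, glen - 100, size=4))
        bounds = [0, *cuts.tolist(), glen]
        kinds = ["exon", "intron", "exon", "intron", "exon"]
        for (a, b), kind in zip(zip(bounds, bounds[1:]), kinds):
            rows.append({"start": s + a + 1, "end": s + b, "strand": strand,
                         "category": kind})
    for _ in range(n_repeats * 4):
        if n_repeats == 0:
            break
        rlen = int(rng.integers(200, 500))
        s = int(rng.integers(0, cfg.genome_length - rlen))
        if clashes(s, s + rlen):
            continue
        n_repeats -= 1
        forbidden.append((s, s + rlen))
        rows.append({"start": s + 1, "end": s + rlen,
                     "strand": "+" if rng.random() < 0.5 else "-",
                     "category": "repeat"})
    return pd.DataFrame(rows, columns=["start", "end", "strand", "category"])


def _site_with_score(mature: str, score: float, rng: np.random.Generator) -> str:
    """A 21-nt target site whose Allen-rule score against ``mature`` equals
    ``score`` (mutations placed outside the cleavage-critical positions).

    Raises ``ValueError`` when the requested score cannot be hit exactly.
    """
    site = list(revcomp(mature))  # perfect complement, score 0
    M = len(mature)
    # site index paired to miRNA position i (1-based): M - i
    edge = [i for i in range(CORE_END + 3, M + 1)]        # cheap positions (weight 1)
    core = [i for i in range(CORE_START, CORE_END + 1) if i not in (10, 11)]
    remaining = score
    rng.shuffle(edge)
    rng.shuffle(core)

    def mutate(pos, wobble=False):
        si = M - pos
        mb = mature[pos - 1]
        if wobble:
            if mb == "G":
                site[si] = "T"
            elif mb == "T":
                site[si] = "G"
            else:
                return False
        else:
            # a true mismatch: neither the Watson-Crick partner nor a wobble
            wc = {"A": "T", "C": "G", "G": "C", "T": "A"}[mb]
            choices = [b for b in "ACGT" if b != wc and
                       not ((mb == "G" and b == "T") or (mb == "T" and b == "G"))]
            site[si] = choices[int(rng.integers(len(choices)))]
        return True

    while remaining >= 2.0 - 1e-9 and core:
        if mutate(core.pop()):
            remaining -= 2.0
    while remaining >= 1.0 - 1e-9 and edge:
        if mutate(edge.pop()):
            remaining -= 1.0
    while remaining >= 0.5 - 1e-9 and edge:
        if mutate(edge.pop(), wobble=True):
            remaining -= 0.5
    if abs(remaining) > 1e-9:
        raise ValueError(f"requested alignment score {score} unreachable for a "
                         f"{M}-mer site")
    out = "".join(site)
    got, _ = score_alignment(mature, out)
    if abs(got - score) > 1e-9:
        raise ValueError(f"site construction reached score {got}, wanted {score}")
    return out


def make_transcriptome(cfg: SimulationConfig, study: SyntheticStudy) -> None:
    """Transcripts with planted target sites; fills the truth site table.

    Planted sites alternate between known and novel miRNAs.  The target
    gene of each planted miRNA receives the opposite fold change, emulating
    cleavage-driven anticorrelation.
    """
    rng = cfg.substream("transcriptome")
    lo, hi = cfg.transcript_length_range
    transcripts = {}
    for i in range(cfg.n_transcripts):
        L = int(rng.integers(lo, hi + 1))
        transcripts[f"gene{i + 1:04d}"] = _random_seq(rng, L)

    planted = study.truth.planted_mirnas
    # alternate known / novel target miRNAs
    known = [m for m in planted if m.kind == "known"]
    novel = [m for m in planted if m.kind == "novel"]
    order = []
    while len(order) < cfg.n_planted_targets and (known or novel):
        if novel:
            order.append(novel.pop(0))
        if known and len(order) < cfg.n_planted_targets:
            order.append(known.pop(0))
    if len(order) < cfg.n_planted_targets:
        raise ValueError("not enough planted miRNAs for the requested targets")

    fcs = list(cfg.planted_log2fc)
    if len(fcs) < cfg.n_planted_targets:
        raise ValueError("planted_log2fc shorter than n_planted_targets")
    scores = list(cfg.planted_target_scores)
    for i, mir in enumerate(order):
        tid = f"gene{i + 1:04d}"
        seq = transcripts[tid]
        M = len(mir.mature)
        site = _site_with_score(mir.mature, scores[i], rng)
        # keep >= 15 nt downstream so a 21-nt degradome tag fits after cleavage
        start = int(rng.integers(50, len(seq) - M - 40))
        transcripts[tid] = seq[:start] + site + seq[start + M:]
        site_start = start + 1  # 1-based
        cleavage_pos = site_start + M - 10  # tag 5' end paired to miRNA pos 10
        study.truth.planted_targets.append({
            "mirna_name": mir.name, "mirna_sequence": mir.mature,
            "transcript_id": tid, "site_start": site_start,
            "expected_score": scores[i], "cleavage_pos": cleavage_pos,
        })
        study.truth.mirna_fc[mir.name] = fcs[i]
        study.truth.gene_fc[tid] = -fcs[i]
    study.transcripts = transcripts


def _noise(rng: np.random.Generator, expected: np.ndarray,
           cfg: SimulationConfig) -> np.ndarray:
    expected = np.asarray(expected, dtype=float)
    if cfg.noise_model == "poisson":
        return rng.poisson(expected)
    r = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape=r, scale=np.maximum(expected, 1e-12) / r)
    return rng.poisson(lam)


def simulate_srna(cfg: SimulationConfig, study: SyntheticStudy) -> pd.DataFrame:
    """Two-sample small-RNA tag-count table (sequence, count_control, count_cms).

    Planted miRNA (and low-abundance star) counts are drawn around
    depth-scaled expected abundances honouring the planted fold changes.
    Background tags come from a large pool of genome-derived degradation
    fragments (18-30 nt, both strands, sizes peaked at 21/24 nt) plus the
    bundled rRNA/tRNA decoy set.
    """
    rng = cfg.substream("srna")
    planted = study.truth.planted_mirnas
    rows_seq: list[str] = []
    ctrl_exp: list[float] = []
    cms_exp: list[float] = []

    if planted:
        w = rng.lognormal(0.0, 1.0, len(planted))
        mass = cfg.srna_depth * (1.0 - cfg.background_fraction)
        base = mass * w / w.sum()
        for mir, b in zip(planted, base):
            fc = study.truth.mirna_fc.get(mir.name, 0.0)
            rows_seq += [mir.mature, mir.star]
            ctrl_exp += [b, b * cfg.star_fraction]
            cms_exp += [b * 2 ** fc, b * cfg.star_fraction * 2 ** fc]

    # background pool: distinct fragment species, ~1 expected read per
    # species across both samples, so the unique-tag tail is count-1 heavy
    bg_mass = cfg.srna_depth * cfg.background_fraction
    if bg_mass > 0:
        n_species = max(1, int(2 * bg_mass))
        n_dec = int(n_species * cfg.decoy_fraction)
        n_gen = n_species - n_dec
        g = study.genome
        seqs = []
        probs = _length_distribution()
        for L, pL in zip(range(18, 31), probs):
            n_max = cfg.genome_length - L
            for minus in (False, True):
                k = min(int(round(n_gen * pL / 2)), n_max)
                starts = rng.choice(n_max, size=k, replace=False)
                starts.sort()
                for s in starts:
                    frag = g[s:s + L]
                    seqs.append(revcomp(frag) if minus else frag)
        decoy_seqs = [s for group in study.decoys.values() for s in group]
        if n_dec and decoy_seqs:
            didx = rng.integers(0, len(decoy_seqs), size=n_dec)
            dlens = rng.choice(np.arange(18, 31), size=n_dec,
                               p=_length_distribution())
            for di, L in zip(didx, dlens):
                src = decoy_seqs[di]
                p = int(rng.integers(0, max(1, len(src) - L)))
                seqs.append(src[p:p + int(L)])
        per_species = bg_mass / len(seqs)
        rows_seq += seqs
        ctrl_exp += [per_species] * len(seqs)
        cms_exp += [per_species] * len(seqs)

    ctrl = _noise(rng, np.array(ctrl_exp), cfg)
    cms = _noise(rng, np.array(cms_exp), cfg)
    df = pd.DataFrame({"sequence": rows_seq, "count_control": ctrl,
                       "count_cms": cms})
    df = (df.groupby("sequence", as_index=False).sum()
            .sort_values("sequence", kind="mergesort").reset_index(drop=True))
    df = df[(df.count_control > 0) | (df.count_cms > 0)].reset_index(drop=True)
    study.srna_counts = df
    return df


def _length_distribution() -> np.ndarray:
    """Tag-length distribution 18-30 nt, peaked at 24 then 21 nt."""
    p = np.array([2, 3, 5, 14, 6, 5, 22, 4, 3, 2, 1.5, 1, 0.5])
    return p / p.sum()


def simulate_degradome(cfg: SimulationConfig, study: SyntheticStudy
                       ) -> dict[str, pd.DataFrame]:
    """Per-sample degradome tag tables (sequence, count).

    Each planted target emits 20-21 nt tags whose 5' ends sit exactly at the
    cleavage position (paired to miRNA position 10), far above the uniform
    per-position background drawn along all transcripts.
    """
    rng = cfg.substream("degradome")
    if not study.transcripts:
        raise ValueError("transcriptome not generated")
    out: dict[str, pd.DataFrame] = {}
    targets = study.truth.planted_targets
    tids = sorted(study.transcripts)

    # background species shared between samples (degradation hotspots)
    n_bg = cfg.n_degradome_background if cfg.background_fraction > 0 else 0
    bg_rows = []
    for _ in range(n_bg):
        tid = tids[int(rng.integers(len(tids)))]
        seq = study.transcripts[tid]
        L = int(rng.choice([19, 20, 20, 20, 21, 21, 21, 22]))
        p = int(rng.integers(0, len(seq) - L))
        bg_rows.append(seq[p:p + L])
    bg_mass = cfg.degradome_depth * cfg.background_fraction
    bg_exp = bg_mass / max(1, n_bg)

    planted_mass = cfg.degradome_depth * (1 - cfg.background_fraction)
    site_exp = planted_mass / max(1, len(targets)) / 2.0  # per tag length

    for sample in ("control", "cms"):
        seqs: list[str] = []
        exps: list[float] = []
        for t in targets:
            seq = study.transcripts[t["transcript_id"]]
            c0 = t["cleavage_pos"] - 1
            for L in (20, 21):
                if c0 + L > len(seq):
                    raise ValueError(
                        f"planted site in {t['transcript_id']} too close to the "
                        f"3' end to emit a {L}-nt tag")
                seqs.append(seq[c0:c0 + L])
                exps.append(site_exp)
        seqs += bg_rows
        exps += [bg_exp] * len(bg_rows)
        counts = _noise(rng, np.array(exps), cfg)
        df = pd.DataFrame({"sequence": seqs, "count": counts})
        df = (df.groupby("sequence", as_index=False).sum()
                .sort_values("sequence", kind="mergesort").reset_index(drop=True))
        out[sample] = df[df["count"] > 0].reset_index(drop=True)
    study.degradome = out
    return out


def simulate_rnaseq(cfg: SimulationConfig, study: SyntheticStudy
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene RNA-seq count table; planted target genes carry the
    anticorrelated fold changes."""
    rng = cfg.substream("rnaseq")
    if not study.transcripts:
        raise ValueError("transcriptome not generated")
    tids = sorted(study.transcripts)
    w = rng.lognormal(0.0, 1.0, len(tids))
    base = cfg.rnaseq_depth * w / w.sum()
    fc = np.array([study.truth.gene_fc.get(t, 0.0) for t in tids])
    ctrl = _noise(rng, base, cfg)
    cms = _noise(rng, base * 2.0 ** fc, cfg)
    df = pd.DataFrame({"feature_id": tids, "count_control": ctrl,
                       "count_cms": cms})
    lengths = {t: len(study.transcripts[t]) for t in tids}
    study.rnaseq_counts = df
    return df, lengths


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Run every generator stage and return the complete in-memory study."""
    study = make_genome(cfg)
    make_transcriptome(cfg, study)
    simulate_srna(cfg, study)
    simulate_degradome(cfg, study)
    simulate_rnaseq(cfg, study)
    return study


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the study to disk (FASTA/GFF3/TSV; TSVs have one header line)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    write_fasta(outdir / "genome.fasta", {"chr1": study.genome})
    write_fasta(outdir / "mature.fasta", study.known_matures)
    write_fasta(outdir / "precursor.fasta", study.known_precursors)
    if study.transcripts:
        write_fasta(outdir / "transcripts.fasta", study.transcripts)
    with open(outdir / "precursors.gff", "w") as fh:
        fh.write("##gff-version 3\n")
        for m in study.truth.planted_mirnas:
            chrom, s, e, strand = m.locus
            fh.write(f"{chrom}\tmircms_sim\tmiRNA_primary_transcript\t{s}\t{e}"
                     f"\t.\t{strand}\t.\tID={m.name}\n")
    study.intervals.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    if study.srna_counts is not None:
        study.srna_counts.to_csv(outdir / "srna_counts.tsv", sep="\t", index=False)
    if study.degradome:
        for sample, df in study.degradome.items():
            df.to_csv(outdir / f"degradome_{sample}.tsv", sep="\t", index=False)
    if study.rnaseq_counts is not None:
        lengths = pd.DataFrame({"feature_id": sorted(study.transcripts),
                                "length": [len(study.transcripts[t])
                                           for t in sorted(study.transcripts)]})
        study.rnaseq_counts.merge(lengths).to_csv(
            outdir / "rnaseq_counts.tsv", sep="\t", index=False)
    pd.DataFrame([vars(m) for m in study.truth.planted_mirnas]).to_csv(
        outdir / "truth" / "planted_mirnas.tsv", sep="\t", index=False)
    pd.DataFrame(study.truth.planted_targets).to_csv(
        outdir / "truth" / "planted_targets.tsv", sep="\t", index=False)
    fc_rows = ([{"feature": k, "log2fc": v, "layer": "mirna"}
                for k, v in sorted(study.truth.mirna_fc.items())]
               + [{"feature": k, "log2fc": v, "layer": "gene"}
                  for k, v in sorted(study.truth.gene_fc.items())])
    pd.DataFrame(fc_rows, columns=["feature", "log2fc", "layer"]).to_csv(
        outdir / "truth" / "planted_fc.tsv", sep="\t", index=False)
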