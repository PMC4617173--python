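"""Join the miRNA and target expression layers into the final pair report.

Validated miRNA:target pairs are classified into the four joint-regulation
clusters: I (miRNA down, target up — the expected signature of relieved
cleavage), II (both down), III (both up) and IV (miRNA up, target down).
Tier labels mark pairs where *both* members change by at least 1.5-fold or
2-fold; the tier sets are nested (2fold within 1.5fold within any).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

log = logging.getLogger(__name__)

CLUSTERS = ("I", "II", "III", "IV")
TIER_THRESHOLDS = {"any": 0.0, "1.5fold": math.log2(1.5), "2fold": 1.0}


@dataclass
class PairRecord:
    mirna_name: str
    target_gene: str
    mirna_log2fc: float
    target_log2fc: float
    cluster: str
    tier: str
    zero_fold: bool = False
    annotation: str = ""


def classify_cluster(mirna_fc: float, target_fc: float) -> tuple[str, bool]:
    """Cluster of one pair; zero fold changes resolve to the smaller cluster
    index and are flagged."""
    zero = mirna_fc == 0 or target_fc == 0
    m_signs = (-1, 1) if mirna_fc == 0 else ((-1,) if mirna_fc < 0 else (1,))
    t_signs = (-1, 1) if target_fc == 0 else ((-1,) if target_fc < 0 else (1,))
    table = {(-1, 1): "I", (-1, -1): "II", (1, 1): "III", (1, -1): "IV"}
    options = sorted(table[(m, t)] for m in m_signs for t in t_signs)
    return min(options, key=CLUSTERS.index), zero


def pair_tier(mirna_fc: float, target_fc: float) -> str:
    both = min(abs(mirna_fc), abs(target_fc))
    if both >= TIER_THRESHOLDS["2fold"]:
        return "2fold"
    if both >= TIER_THRESHOLDS["1.5fold"]:
        return "1.5fold"
    return "any"


def pair_and_classify(mirna_de: pd.DataFrame, gene_de: pd.DataFrame,
                      hits: pd.DataFrame,
                      annotation: Optional[pd.DataFrame] = None
                      ) -> tuple[pd.DataFrame, dict]:
    """One PairRecord per validated hit whose miRNA and target both carry a
    defined fold change; returns the pair table and per-tier cluster
    proportions.

    ``mirna_de``/``gene_de`` are :func:`mircms.stats.diff_table` outputs;
    ``hits`` is a retained-target table with ``mirna_name`` and
    ``transcript_id`` columns.  ``annotation`` optionally joins a gene
    description column (``feature_id``, ``description``).
    """
    m_fc = dict(zip(mirna_de["feature_id"], mirna_de["log2fc"]))
    g_fc = dict(zip(gene_de["feature_id"], gene_de["log2fc"]))
    desc = {}
    if annotation is not None:
        desc = dict(zip(annotation["feature_id"], annotation["description"]))

    records: list[PairRecord] = []
    n_skipped = 0
    seen = set()
    for _, hit in hits.iterrows():
        key = (hit["mirna_name"], hit["transcript_id"])
        if key in seen:
            continue
        seen.add(key)
        if key[0] not in m_fc or key[1] not in g_fc:
            n_skipped += 1
            log.info("pair %s -> %s skipped: no defined fold change", *key)
            continue
        mfc, tfc = m_fc[key[0]], g_fc[key[1]]
        cluster, zero = classify_cluster(mfc, tfc)
        records.append(PairRecord(
            mirna_name=key[0], target_gene=key[1], mirna_log2fc=mfc,
            target_log2fc=tfc, cluster=cluster, tier=pair_tier(mfc, tfc),
            zero_fold=zero, annotation=desc.get(key[1], "")))

    pairs = pd.DataFrame([vars(r) for r in records], columns=[
        "mirna_name", "target_gene", "mirna_log2fc", "target_log2fc",
        "cluster", "tier", "zero_fold", "annotation"])
    proportions = cluster_proportions(pairs)
    proportions["n_skipped_no_expression"] = n_skipped
    return pairs, proportions


def cluster_proportions(pairs: pd.DataFrame) -> dict:
    """Cluster proportions per tier; tier sets are nested by construction."""
    out: dict = {}
    rank = {"any": 0, "1.5fold": 1, "2fold": 2}
    for tier, level in rank.items():
        sub = pairs[[rank[t] >= level for t in pairs["tier"]]] if len(pairs) else pairs
        counts = {c: int((sub["cluster"] == c).sum()) if len(sub) else 0
                  for c in CLUSTERS}
        total = sum(counts.values())
        out[tier] = {
            "n_pairs": total,
            "counts": counts,
            "proportions": {c: (counts[c] / total if total else 0.0)
                            for c in CLUSTERS},
        }
    return out


def report(pairs: pd.DataFrame, mirna_de: pd.DataFrame, gene_de: pd.DataFrame,
           hits: pd.DataFrame, novel_calls=None, config: Optional[dict] = None,
           outdir: Optional[str | Path] = None) -> dict:
    """Structured end-of-run summary (JSON-serialisable, deterministic).

    Counts per stage, cluster/tier proportions and a provenance block with
    the effective configuration.  When ``outdir`` is given, writes
    ``pairs.tsv`` and ``summary.json``.
    """
    def de_counts(df):
        return {"n": int(len(df)),
                "up": int((df["call"] == "up").sum()) if len(df) else 0,
                "down": int((df["call"] == "down").sum()) if len(df) else 0}

    summary = {
        "mirna_de": de_counts(mirna_de),
        "gene_de": de_counts(gene_de),
        "n_novel_calls": len(novel_calls) if novel_calls is not None else 0,
        "n_target_hits": int(len(hits)),
        "n_target_genes": int(hits["transcript_id"].nunique()) if len(hits) else 0,
        "pairs": cluster_proportions(pairs),
        "provenance": dict(sorted((config or {}).items())),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
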