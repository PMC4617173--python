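"""Normalisation and differential-expression statistics for tag-count data.

Two layers share this module: small-RNA tags (TPM normalisation, an
Audic-Claverie exact test for unreplicated tag counts) and gene-level RNA-seq
(RPKM normalisation, a Pearson chi-squared test on the 2x2 count table, with
Benjamini-Hochberg control of the false-discovery rate).  The design has one
library per condition, so no dispersion estimation is attempted: the tests
model pure counting noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

#: floor applied to a zero normalised value when computing a fold change
ZERO_FLOOR = 0.01


@dataclass
class LibrarySizes:
    """Per-sample totals used for normalisation.

    ``total_clean_*`` divide the TPM formula; ``total_mapped_*`` are the N of
    RPKM; ``gene_lengths`` maps gene id to length in bases.
    """

    total_clean_control: int = 0
    total_clean_cms: int = 0
    total_mapped_control: int = 0
    total_mapped_cms: int = 0
    gene_lengths: dict[str, int] = field(default_factory=dict)


@dataclass
class DEThresholds:
    """Regulation-call thresholds; every value is configuration-driven."""

    min_abs_log2fc: float = 1.0
    max_p: float | None = 1e-3   # used for the miRNA layer
    max_q: float | None = None   # used for the mRNA layer (FDR)


MIRNA_THRESHOLDS = DEThresholds(min_abs_log2fc=1.0, max_p=1e-3, max_q=None)
MRNA_THRESHOLDS = DEThresholds(min_abs_log2fc=1.0, max_p=None, max_q=1e-2)
MRNA_TARGET_THRESHOLDS = DEThresholds(min_abs_log2fc=1.0, max_p=None, max_q=1e-3)


def tpm(count: float, total_clean: float) -> float:
    """Tags per million: ``count / total_clean * 1e6``."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    return count / total_clean * 1e6


def rpkm(c: float, n: float, length: float) -> float:
    """Reads per kilobase per million mapped reads: ``1e9 * C / (N * L)``."""
    if length <= 0:
        raise ValueError("gene length must be positive")
    if n <= 0:
        raise ValueError("total mapped reads must be positive")
    return 1e9 * c / (n * length)


def log2fc(norm_control: float, norm_cms: float, floor: float = ZERO_FLOOR) -> float:
    """log2(cms / control); a one-sided zero is floored at ``floor``.

    Features with zero in both samples are undefined and must be excluded
    upstream.
    """
    if norm_control < 0 or norm_cms < 0:
        raise ValueError("normalised expression must be non-negative")
    if norm_control == 0 and norm_cms == 0:
        raise ValueError("log2 fold change undefined when both samples are zero")
    a = norm_control if norm_control > 0 else floor
    b = norm_cms if norm_cms > 0 else floor
    return float(np.log2(b / a))


def tag_count_test(x: int, y: int, n1: float, n2: float) -> float:
    """Audic-Claverie two-sided p-value for tag counts (x, y) in libraries
    of sizes (n1, n2).

    Under equal underlying rates the second count given the first follows a
    negative-binomial posterior predictive, ``Y | x ~ NB(x + 1, n1/(n1+n2))``;
    the two-sided p-value doubles the smaller tail (capped at 1).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p_succ = n1 / (n1 + n2)
    lower = sps.nbinom.cdf(y, x + 1, p_succ)
    upper = sps.nbinom.sf(y - 1, x + 1, p_succ)
    p = min(1.0, 2.0 * min(lower, upper))
    return float(max(p, 1e-300))  # keep p in (0, 1] despite tail underflow


def chi2_test(c1: int, c2: int, n1: float, n2: float) -> float:
    """Pearson chi-squared (1 df) on the 2x2 table [[c1, N1-c1], [c2, N2-c2]].

    When any expected cell drops below 1 the approximation is unreliable and
    the Audic-Claverie exact test is used instead (logged).
    """
    table = np.array([[c1, n1 - c1], [c2, n2 - c2]], dtype=float)
    if table.min() < 0:
        raise ValueError("counts exceed library sizes")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / table.sum()
    if expected.min() < 1.0:
        log.debug("chi2 expected cell < 1 for counts (%s, %s); falling back to "
                  "the exact tag-count test", c1, c2)
        return tag_count_test(int(c1), int(c2), n1, n2)
    stat = ((table - expected) ** 2 / expected).sum()
    return float(sps.chi2.sf(stat, df=1))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone in p rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def call_de(fc: float, p: float, q: float, thresholds: DEThresholds) -> str:
    """Classify one feature as ``up``, ``down`` or ``ns``."""
    if abs(fc) < thresholds.min_abs_log2fc:
        return "ns"
    if thresholds.max_p is not None and not (p < thresholds.max_p):
        return "ns"
    if thresholds.max_q is not None and not (q < thresholds.max_q):
        return "ns"
    return "up" if fc > 0 else "down"


def diff_table(counts: pd.DataFrame, sizes: LibrarySizes, layer: str,
               thresholds: DEThresholds | None = None) -> pd.DataFrame:
    """Full differential-expression table for one layer.

    ``counts`` must have columns ``feature_id``, ``count_control`` and
    ``count_cms``.  The miRNA layer normalises by TPM and tests with the
    Audic-Claverie statistic; the mRNA layer normalises by RPKM (gene lengths
    from ``sizes``) and tests with the chi-squared statistic.  Features with
    zero counts in both samples are excluded with a logged count.  Columns:
    feature_id, norm_control, norm_cms, log2fc, p_value, q_value, call.
    """
    if layer not in {"mirna", "mrna"}:
        raise ValueError(f"unknown layer {layer!r}")
    if thresholds is None:
        thresholds = MIRNA_THRESHOLDS if layer == "mirna" else MRNA_THRESHOLDS

    df = counts.copy()
    both_zero = (df["count_control"] == 0) & (df["count_cms"] == 0)
    if both_zero.any():
        log.info("excluding %d features with zero counts in both samples",
                 int(both_zero.sum()))
    df = df.loc[~both_zero].reset_index(drop=True)

    if layer == "mirna":
        n1, n2 = sizes.total_clean_control, sizes.total_clean_cms
        df["norm_control"] = [tpm(c, n1) for c in df["count_control"]]
        df["norm_cms"] = [tpm(c, n2) for c in df["count_cms"]]
        df["p_value"] = [tag_count_test(int(x), int(y), n1, n2)
                         for x, y in zip(df["count_control"], df["count_cms"])]
    else:
        n1, n2 = sizes.total_mapped_control, sizes.total_mapped_cms
        lengths = [sizes.gene_lengths[g] for g in df["feature_id"]]
        df["norm_control"] = [rpkm(c, n1, L) for c, L in zip(df["count_control"], lengths)]
        df["norm_cms"] = [rpkm(c, n2, L) for c, L in zip(df["count_cms"], lengths)]
        df["p_value"] = [chi2_test(int(x), int(y), n1, n2)
                         for x, y in zip(df["count_control"], df["count_cms"])]

    df["log2fc"] = [log2fc(a, b) for a, b in zip(df["norm_control"], df["norm_cms"])]
    df["q_value"] = bh_fdr(np.clip(df["p_value"].to_numpy(), 1e-300, 1.0))
    df["call"] = [call_de(fc, p, q, thresholds)
                  for fc, p, q in zip(df["log2fc"], df["p_value"], df["q_value"])]
    cols = ["feature_id", "count_control", "count_cms", "norm_control",
            "norm_cms", "log2fc", "p_value", "q_value", "call"]
    return df[cols]
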