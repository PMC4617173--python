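"""Bundled reference tables from the Ogura-CMS (Tyms) versus maintainer
(231-330) Chinese cabbage bud comparison.

These small published summary tables — the most highly expressed known
miRNAs, the differentially expressed known miRNAs with their TPM-normalised
expression, the up/down-regulated degradome-validated target genes with
their RPKM values, and overall library statistics — serve as worked examples
and as fixed inputs for validating the normalisation and regulation-call
arithmetic of :mod:`mircms.stats` against independently computed values.
"""

from __future__ import annotations

import importlib.resources
from io import StringIO

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    text = (importlib.resources.files("mircms") / "data" / name).read_text()
    return pd.read_csv(StringIO(text), sep="\t", comment="#")


def known_mirna_de() -> pd.DataFrame:
    """Differentially expressed known miRNAs (TPM pairs, printed log2
    fold change, p-value and regulation call)."""
    return _read("known_mirna_de.tsv")


def top_known_mirnas() -> pd.DataFrame:
    """The 20 most highly expressed known miRNAs with raw tag counts."""
    return _read("top_known_mirnas.tsv")


def targets_up() -> pd.DataFrame:
    """Up-regulated validated target genes (RPKM pairs, log2fc, FDR)."""
    return _read("target_up.tsv")


def targets_down() -> pd.DataFrame:
    """Down-regulated validated target genes (RPKM pairs, log2fc, FDR)."""
    return _read("target_down.tsv")


def library_stats() -> dict[str, float]:
    """Headline library statistics (tag totals in millions, discovery counts)."""
    df = _read("library_stats.tsv")
    return dict(zip(df["key"], df["value"].astype(float)))
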