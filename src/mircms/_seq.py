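"""Small sequence helpers shared across the pipeline.

All sequences are stored in the DNA alphabet (ACGT); folding converts to RNA
internally.  FASTA input/output goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RC = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def revcomp(seq: str) -> str:
    """Reverse complement (U treated as T)."""
    return seq.translate(_RC)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict.

    Raises ``ValueError`` on duplicate record ids, which commonly indicates a
    corrupt or concatenated reference file.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    SeqIO.write(records, str(path), "fasta")


def iter_fastq(path: str | Path) -> Iterable[tuple[str, str, list[int]]]:
    """Yield ``(id, sequence, phred_qualities)`` triples from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]
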