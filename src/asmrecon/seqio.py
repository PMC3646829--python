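"""Thin FASTA helpers (Biopython-backed) and reverse complement."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into an ordered {name: uppercase sequence} dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
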