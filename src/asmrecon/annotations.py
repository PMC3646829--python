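"""Gene annotations: GFF3 gene rows and ordered cluster gene lists.

Coordinates are 0-based half-open in memory and converted to GFF3's
1-based closed convention on write/read.  Only ``gene`` feature rows are
consumed; everything else in a GFF3 is passed over.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml


@dataclass
class GeneRecord:
    """One annotated gene (sequence span includes introns)."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"
    product: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must be > start")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, chromosomes: dict[str, str]) -> str:
        """Gene nucleotide sequence on the forward strand of its chromosome."""
        return chromosomes[self.chrom][self.start : self.end]


def write_gff3(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.chrom}\tasmrecon\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[GeneRecord]:
    """Read gene rows from a GFF3 file (1-based closed -> half-open)."""
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(cols)}")
            if cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            genes.append(
                GeneRecord(
                    gene_id=attrs.get("ID", f"gene_at_{cols[0]}_{cols[3]}"),
                    chrom=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "+",
                    product=attrs.get("product", ""),
                )
            )
    return genes


def write_clusters(clusters: dict[str, list[str]], path: str | Path) -> None:
    """Write ordered cluster gene lists as a YAML mapping."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            {name: list(ids) for name, ids in clusters.items()},
            fh,
            sort_keys=False,
        )


def read_clusters(path: str | Path) -> dict[str, list[str]]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: cluster config must map cluster name -> gene list")
    return {str(k): [str(g) for g in v] for k, v in data.items()}
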