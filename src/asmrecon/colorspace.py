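"""SOLiD di-base color-space codec and csfasta/.qual I/O.

SOLiD instruments report reads in "color space": each symbol 0-3 encodes
the transition between two adjacent bases rather than a base itself, and
the record starts with a known primer base so the sequence can be decoded
by walking the transitions.  The transition code is the XOR of the 2-bit
base codes (A=0, C=1, G=2, T=3), which reproduces the standard SOLiD
di-base matrix: color 0 means the two bases are equal, color 3 means they
are complementary, etc.  An undetermined color call is written as ``.``.

Files come in pairs: a ``.csfasta`` with '>'-headed records whose single
sequence line is the primer base followed by the color string, and a
``.qual`` with the same headers and one Phred-scaled integer per color.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"
_COLOR_ALPHABET = frozenset("0123.")


class ColorSpaceError(ValueError):
    """Raised for malformed color-space data or files."""


@dataclass
class ColorRead:
    """One SOLiD color-space read: primer base + colors + per-color QVs.

    ``tag`` distinguishes the two mates of a mate-pair (F3/R3); reads are
    paired by the shared id prefix before the ``_F3``/``_R3`` suffix.
    """

    read_id: str
    tag: str  # "F3" or "R3"
    primer_base: str
    colors: str
    qvs: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.primer_base not in _BASE_CODE:
            raise ColorSpaceError(
                f"{self.read_id}: primer base {self.primer_base!r} is not a nucleotide"
            )
        if not set(self.colors) <= _COLOR_ALPHABET:
            bad = sorted(set(self.colors) - _COLOR_ALPHABET)
            raise ColorSpaceError(f"{self.read_id}: invalid color symbols {bad}")
        if len(self.qvs) != len(self.colors):
            raise ColorSpaceError(
                f"{self.read_id}: {len(self.qvs)} quality values for "
                f"{len(self.colors)} colors"
            )

    @property
    def pair_id(self) -> str:
        """Read id with the _F3/_R3 tag suffix stripped."""
        return re.sub(r"_(F3|R3)$", "", self.read_id)

    @property
    def undetermined(self) -> tuple[int, ...]:
        """Positions of '.' (undetermined) color calls."""
        return tuple(i for i, c in enumerate(self.colors) if c == ".")

    def __len__(self) -> int:
        return len(self.colors)


def encode_colorspace(sequence: str) -> tuple[str, str]:
    """Encode a nucleotide string into (primer_base, color string).

    color[i] = code(base[i]) XOR code(base[i+1]) with A=0, C=1, G=2, T=3;
    the first base is returned unchanged as the primer.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ColorSpaceError("sequence must have length >= 2 to encode")
    for i, b in enumerate(seq, 1):
        if b not in _BASE_CODE:
            raise ColorSpaceError(f"non-ACGT character {b!r} at position {i}")
    codes = [_BASE_CODE[b] for b in seq]
    colors = "".join(str(a ^ b) for a, b in itertools.pairwise(codes))
    return seq[0], colors


def decode_colorspace(primer_base: str, colors: str) -> str:
    """Decode (primer_base, colors) back to nucleotides.

    Exact inverse of :func:`encode_colorspace`.  A '.' color cannot be
    decoded; the error names the first undetermined position.
    """
    if primer_base not in _BASE_CODE:
        raise ColorSpaceError(f"primer base {primer_base!r} is not a nucleotide")
    dot = colors.find(".")
    if dot >= 0:
        # positions are 1-based in messages
        raise ColorSpaceError(f"undecodable: undetermined color at position {dot + 1}")
    state = _BASE_CODE[primer_base]
    out = [primer_base]
    for i, c in enumerate(colors):
        if c not in "0123":
            raise ColorSpaceError(f"invalid color {c!r} at position {i}")
        state ^= int(c)
        out.append(_CODE_BASE[state])
    return "".join(out)


def _tag_of(read_id: str) -> str:
    m = re.search(r"_(F3|R3)$", read_id)
    return m.group(1) if m else "F3"


def _iter_fasta_records(path: Path) -> Iterator[tuple[str, str]]:
    """Yield (header, joined body) from a '>'-headed file, skipping '#' comments."""
    header: str | None = None
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, " ".join(body)
                header = line[1:].strip()
                body = []
            else:
                if header is None:
                    raise ColorSpaceError(f"{path}: data before first '>' header")
                body.append(line)
        if header is not None:
            yield header, " ".join(body)


def read_csfasta(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, primer_base, colors) records from a csfasta file."""
    for header, body in _iter_fasta_records(Path(path)):
        seq = body.replace(" ", "")
        if len(seq) < 1 or seq[0] not in _BASE_CODE:
            raise ColorSpaceError(
                f"{path}: record {header}: color line must start with a primer base"
            )
        yield header, seq[0], seq[1:]


def read_qual(path: str | Path) -> Iterator[tuple[str, list[int]]]:
    """Yield (read_id, qvs) records from a .qual file."""
    for header, body in _iter_fasta_records(Path(path)):
        try:
            qvs = [int(tok) for tok in body.split()]
        except ValueError as exc:
            raise ColorSpaceError(f"{path}: record {header}: {exc}") from None
        yield header, qvs


def read_color_reads(
    csfasta_path: str | Path, qual_path: str | Path
) -> Iterator[ColorRead]:
    """Stream paired csfasta + .qual records as :class:`ColorRead`.

    Records are paired by order and must agree on id and length.  A '.'
    color always gets QV 0, whatever the .qual file says (this makes every
    QV filter at least as strict as the no-dot filter).
    """
    quals = read_qual(qual_path)
    for (rid, primer, colors), qrec in itertools.zip_longest(
        read_csfasta(csfasta_path), quals, fillvalue=None
    ):
        if qrec is None:
            raise ColorSpaceError(f"missing .qual record for read {rid}")
        if rid is None:
            raise ColorSpaceError(f"extra .qual record {qrec[0]} with no csfasta mate")
        qid, qvs = qrec
        if qid != rid:
            raise ColorSpaceError(f"id mismatch: csfasta {rid!r} vs .qual {qid!r}")
        if len(qvs) != len(colors):
            raise ColorSpaceError(
                f"{rid}: {len(qvs)} quality values for {len(colors)} colors"
            )
        qvs = [0 if c == "." else q for c, q in zip(colors, qvs)]
        yield ColorRead(read_id=rid, tag=_tag_of(rid), primer_base=primer,
                        colors=colors, qvs=qvs)


def write_csfasta(reads: Iterable[ColorRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.primer_base}{r.colors}\n")


def write_qual(reads: Iterable[ColorRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{' '.join(str(q) for q in r.qvs)}\n")


def write_color_reads(
    reads: Iterable[ColorRead], csfasta_path: str | Path, qual_path: str | Path
) -> None:
    """Write reads to a csfasta/.qual pair (single pass over the stream)."""
    reads = list(reads)
    write_csfasta(reads, csfasta_path)
    write_qual(reads, qual_path)


def pair_reads(
    reads: Iterable[ColorRead],
) -> tuple[list[tuple[ColorRead, ColorRead]], list[ColorRead]]:
    """Group a read stream into (F3, R3) pairs by shared id prefix.

    Returns (pairs, orphans); orphans are reads whose mate never appeared.
    """
    pending: dict[str, ColorRead] = {}
    pairs: list[tuple[ColorRead, ColorRead]] = []
    for r in reads:
        key = r.pair_id
        mate = pending.pop(key, None)
        if mate is None:
            pending[key] = r
        else:
            f3, r3 = (r, mate) if r.tag == "F3" else (mate, r)
            pairs.append((f3, r3))
    return pairs, list(pending.values())
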