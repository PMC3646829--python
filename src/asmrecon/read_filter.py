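"""Quality filtering of mate-paired color-space reads.

Three regimes are supported, mirroring how SOLiD read sets are commonly
prepared for assembly:

* ``nofilter`` — keep everything;
* ``nodot``    — drop any read containing an undetermined ('.') color;
* ``qv``       — drop any read whose minimum quality value is not strictly
  above a threshold (the study regime is qv10: every color QV > 10, i.e.
  > 90% per-base accuracy under Phred scaling).

Because an undetermined color always carries QV 0, the survivor sets nest:
qv-filtered reads are a subset of no-dot reads, which are a subset of all
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .colorspace import ColorRead


@dataclass(frozen=True)
class FilterPolicy:
    """A read-filtering regime.

    mode: "nofilter", "nodot" or "qv".
    qv_threshold: used only in qv mode; a read passes iff min(QV) is
        strictly greater than this (strict ">", so qv_threshold=10 rejects
        a read containing a QV of exactly 10).
    pair_rule: "both_pass" drops the whole pair when either mate fails
        (a pair with one bad mate contributes no mate-pair linkage);
        "independent" keeps passing mates individually.
    """

    mode: str = "nofilter"
    qv_threshold: int = 10
    pair_rule: str = "both_pass"

    def __post_init__(self) -> None:
        if self.mode not in ("nofilter", "nodot", "qv"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.pair_rule not in ("both_pass", "independent"):
            raise ValueError(f"unknown pair rule {self.pair_rule!r}")
        if self.qv_threshold < 0:
            raise ValueError("qv_threshold must be >= 0")


@dataclass
class FilterStats:
    """Bookkeeping for one filtering run."""

    pairs_in: int = 0
    pairs_out: int = 0
    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0
    orphans: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def passes(read: ColorRead, policy: FilterPolicy) -> bool:
    """Does a single read survive the policy?"""
    if policy.mode == "nofilter":
        return True
    if policy.mode == "nodot":
        return "." not in read.colors
    # qv mode: every color strictly above threshold ('.' carries QV 0)
    return all(q > policy.qv_threshold for q in read.qvs)


def filter_pairs(
    pairs: Iterable[tuple[ColorRead, ColorRead]],
    policy: FilterPolicy,
    stats: FilterStats | None = None,
) -> Iterator[tuple[ColorRead, ColorRead]]:
    """Filter a stream of (F3, R3) pairs under a policy.

    Under ``both_pass`` a pair survives iff both mates pass; under
    ``independent`` it survives iff at least one mate passes (the failing
    mate is still dropped from the base tally but the surviving mate keeps
    its pair slot).  Pass a :class:`FilterStats` to collect counts.
    """
    if stats is None:
        stats = FilterStats()
    for f3, r3 in pairs:
        stats.pairs_in += 1
        stats.reads_in += 2
        stats.bases_in += len(f3) + len(r3)
        ok_f, ok_r = passes(f3, policy), passes(r3, policy)
        if policy.pair_rule == "both_pass":
            keep = ok_f and ok_r
            if keep:
                stats.pairs_out += 1
                stats.reads_out += 2
                stats.bases_out += len(f3) + len(r3)
                yield f3, r3
        else:
            if ok_f or ok_r:
                stats.pairs_out += 1
                stats.reads_out += int(ok_f) + int(ok_r)
                stats.bases_out += (len(f3) if ok_f else 0) + (len(r3) if ok_r else 0)
                yield f3, r3


def qv_to_accuracy(qv: int | float) -> float:
    """Phred-scaled QV to per-base accuracy: 1 - 10^(-qv/10).

    QV 10 maps to 0.90, QV 20 to 0.99.
    """
    if qv < 0:
        raise ValueError("QV must be >= 0")
    return 1.0 - 10.0 ** (-qv / 10.0)


def depth_of_coverage(n_reads: int, read_len: int, genome_size: int) -> float:
    """Fold coverage of a genome by a read set: n_reads * read_len / genome_size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    return n_reads * read_len / genome_size


def subsample_fraction(n_reads: int, fraction: float, seed: int = 0) -> int:
    """Reads retained by a seeded binomial subsampling at the given fraction.

    De-duplication/subsampling of the vendor toolchain is out of scope; this
    helper lets depth be reported after a user-supplied retention fraction.
    """
    import numpy as np

    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return int(rng.binomial(n_reads, fraction))
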