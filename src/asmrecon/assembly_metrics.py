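"""Assembly-level statistics and misarrangement classification.

Covers the size statistics (N50/NG50, counts above size floors), the
reference-based statistics (coverage, fragment-length-class coverage, and
R50 — the NG50 of reference spans covered by significantly aligned
scaffold fragments, with the reference size as the total), misarrangement
classification from fragment adjacency (misjoin / inversion / deletion /
insertion above a 500 bp threshold), small-indel accounting, and the
contig/scaffold bookkeeping behind the scaffolding ratio.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .fragment_align import AlignmentFragment

MISARRANGEMENT_MIN_SIZE = 500
MISJOIN_DISTANCE_BOUND = 100_000
SCAFFOLD_SIZE_FLOOR = 95
CLASS_BOUNDS = (10_000, 50_000)


# ---------------------------------------------------------------------------
# Size statistics
# ---------------------------------------------------------------------------


def n50(lengths: Iterable[int]) -> int:
    """Largest L such that sequences of length >= L hold >= half of all bases."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length set is undefined")
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, cum[-1] / 2.0, side="left"))
    return int(arr[idx])


def ng50(lengths: Iterable[int], genome_size: int) -> int:
    """N50 with the half-threshold taken against the genome size.

    Returns 0 when the summed lengths never reach half the genome.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        return 0
    cum = np.cumsum(arr)
    half = genome_size / 2.0
    if cum[-1] < half:
        return 0
    return int(arr[int(np.searchsorted(cum, half, side="left"))])


def r50(
    fragments: Sequence[AlignmentFragment],
    genome_size: int,
    merge: bool = False,
) -> int:
    """NG50 over reference spans of aligned fragments, total = genome size.

    By default each fragment's reference span counts on its own (matching
    per-fragment reporting); ``merge=True`` first unions overlapping
    reference intervals, as a sensitivity variant.
    """
    if merge:
        lengths = [b - a for _, a, b in _merged_ref_intervals(fragments)]
    else:
        lengths = [f.ref_span for f in fragments]
    return ng50(lengths, genome_size)


def _merged_ref_intervals(
    fragments: Sequence[AlignmentFragment],
) -> list[tuple[str, int, int]]:
    ivs = sorted((f.ref_chrom, f.ref_start, f.ref_end) for f in fragments)
    merged: list[list] = []
    for chrom, a, b in ivs:
        if merged and merged[-1][0] == chrom and a <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], b)
        else:
            merged.append([chrom, a, b])
    return [tuple(m) for m in merged]


def _ref_lengths(reference: dict) -> dict[str, int]:
    return {k: (len(v) if isinstance(v, str) else int(v)) for k, v in reference.items()}


def genome_coverage(
    fragments: Sequence[AlignmentFragment], reference: dict
) -> float:
    """Percent of reference bases inside the union of fragment ref intervals."""
    lens = _ref_lengths(reference)
    total = sum(lens.values())
    covered = sum(b - a for _, a, b in _merged_ref_intervals(fragments))
    return 100.0 * covered / total


def coverage_by_class(
    fragments: Sequence[AlignmentFragment],
    reference: dict,
    bounds: tuple[int, int] = CLASS_BOUNDS,
) -> dict[str, float]:
    """Reference fraction covered per fragment-length class.

    Each reference base is attributed to the longest fragment covering it;
    classes split at the bounds (default: <=10 kb, >10 kb, >50 kb, plus the
    uncovered remainder).  Fractions sum to 1.
    """
    if list(bounds) != sorted(bounds):
        raise ValueError("bounds must be ascending")
    lens = _ref_lengths(reference)
    paint = {c: np.zeros(n, dtype=np.int8) for c, n in lens.items()}
    for f in sorted(fragments, key=lambda f: f.ref_span):
        rank = 1 + int(np.searchsorted(np.asarray(bounds), f.ref_span, side="left"))
        paint[f.ref_chrom][f.ref_start : f.ref_end] = rank
    total = sum(lens.values())
    counts = np.zeros(len(bounds) + 2, dtype=np.int64)
    for arr in paint.values():
        counts += np.bincount(arr, minlength=len(bounds) + 2)
    lo, hi = bounds
    return {
        "uncovered": counts[0] / total,
        f"le_{lo // 1000}kb": counts[1] / total,
        f"gt_{lo // 1000}kb": counts[2] / total,
        f"gt_{hi // 1000}kb": counts[3] / total,
    }


# ---------------------------------------------------------------------------
# Misarrangement classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MisarrangementEvent:
    """A classified assembly error.

    size is the event extent in reference bp for deletion/insertion (and
    the flipped span for inversion); 0 for misjoin.  ref_pos locates the
    event on the reference (for a misjoin: the leading coordinate of the
    discordant right-hand fragment).
    """

    kind: str  # misjoin | inversion | deletion | insertion
    scaffold_id: str
    ref_chrom: str
    ref_pos: int
    size: int = 0
    scaffold_pos: int = 0


def _leading_ref(f: AlignmentFragment) -> int:
    return f.ref_start if f.strand == "+" else f.ref_end


def _trailing_ref(f: AlignmentFragment) -> int:
    return f.ref_end if f.strand == "+" else f.ref_start


def classify_misarrangements(
    fragments: Sequence[AlignmentFragment],
    min_size: int = MISARRANGEMENT_MIN_SIZE,
    misjoin_bound: int = MISJOIN_DISTANCE_BOUND,
    primary_only: bool = True,
) -> list[MisarrangementEvent]:
    """Classify misjoins, inversions, deletions and insertions (> min_size).

    Works on consecutive retained fragments of each scaffold, which must
    arrive sorted by (scaffold, scaffold_start):

    * different reference chromosomes, or same-chromosome displacement
      whose ref-vs-scaffold discrepancy exceeds ``misjoin_bound`` -> misjoin;
    * an interior fragment strand-flipped relative to both neighbours ->
      one inversion (not two misjoins); a pair-level strand flip at a
      scaffold end counts as an inversion of the flipped span;
    * otherwise a ref-gap minus scaffold-gap difference > min_size is a
      deletion, and the converse an insertion, of that difference.

    Events of extent <= min_size are never reported.  With
    ``primary_only`` (default) the maximum-score non-overlapping fragment
    subset per scaffold is classified, so secondary repeat placements do
    not manufacture junctions.
    """
    seen_order: dict[str, int] = {}
    for f in fragments:
        if f.scaffold_start < seen_order.get(f.scaffold_id, -1):
            raise ValueError(
                f"fragments of {f.scaffold_id} are not sorted by scaffold_start"
            )
        seen_order[f.scaffold_id] = f.scaffold_start
    if primary_only:
        from .fragment_align import select_primary_fragments

        fragments = select_primary_fragments(fragments)
    by_scaffold: dict[str, list[AlignmentFragment]] = {}
    for f in fragments:
        by_scaffold.setdefault(f.scaffold_id, []).append(f)

    events: list[MisarrangementEvent] = []
    for sid, frs in by_scaffold.items():
        starts = [f.scaffold_start for f in frs]
        if starts != sorted(starts):
            raise ValueError(f"fragments of {sid} are not sorted by scaffold_start")
        n = len(frs)
        consumed: set[int] = set()  # junction index i == pair (i, i+1)

        # dominant orientation of the scaffold (strandness of a scaffold is
        # arbitrary, so "inverted" means against the majority by aligned bp)
        plus_bp = sum(f.ref_span for f in frs if f.strand == "+")
        minus_bp = sum(f.ref_span for f in frs if f.strand == "-")
        dom = "+" if plus_bp >= minus_bp else "-"

        # interior fragments flipped against both (dominant-strand)
        # neighbours: one inversion each, not two misjoins
        for i in range(1, n - 1):
            a, b, c = frs[i - 1], frs[i], frs[i + 1]
            if (
                b.strand != dom
                and a.strand == c.strand == dom
                and a.ref_chrom == b.ref_chrom == c.ref_chrom
                and abs(b.ref_start - a.ref_end) <= misjoin_bound
                and abs(c.ref_start - b.ref_end) <= misjoin_bound
            ):
                consumed.update({i - 1, i})
                if b.ref_span > min_size:
                    events.append(
                        MisarrangementEvent(
                            "inversion", sid, b.ref_chrom, b.ref_start,
                            b.ref_span, b.scaffold_start,
                        )
                    )

        for i in range(n - 1):
            if i in consumed:
                continue
            a, b = frs[i], frs[i + 1]
            junction = MisarrangementEvent(
                "misjoin", sid, b.ref_chrom, _leading_ref(b), 0, b.scaffold_start
            )
            if a.ref_chrom != b.ref_chrom:
                events.append(junction)
                continue
            if a.strand != b.strand:
                # terminal flip: inversion if local, else misjoin
                if abs(_leading_ref(b) - _trailing_ref(a)) <= misjoin_bound:
                    flip = a if a.strand != dom else b
                    if flip.ref_span > min_size:
                        events.append(
                            MisarrangementEvent(
                                "inversion", sid, flip.ref_chrom, flip.ref_start,
                                flip.ref_span, flip.scaffold_start,
                            )
                        )
                else:
                    events.append(junction)
                continue
            ref_gap = (
                b.ref_start - a.ref_end if a.strand == "+" else a.ref_start - b.ref_end
            )
            scaf_gap = b.scaffold_start - a.scaffold_end
            diff = ref_gap - scaf_gap
            if abs(diff) > misjoin_bound:
                events.append(junction)
            elif diff > min_size:
                pos = a.ref_end if a.strand == "+" else b.ref_end
                events.append(
                    MisarrangementEvent(
                        "deletion", sid, a.ref_chrom, pos, diff, a.scaffold_end
                    )
                )
            elif -diff > min_size:
                pos = a.ref_end if a.strand == "+" else a.ref_start
                events.append(
                    MisarrangementEvent(
                        "insertion", sid, a.ref_chrom, pos, -diff, a.scaffold_end
                    )
                )
    events.sort(key=lambda e: (e.scaffold_id, e.scaffold_pos))
    return events


def misjoin_scaffold_count(events: Sequence[MisarrangementEvent]) -> int:
    """Number of scaffolds containing at least one misjoin (per-scaffold view)."""
    return len({e.scaffold_id for e in events if e.kind == "misjoin"})


def score_event_recovery(
    predicted: Sequence[MisarrangementEvent],
    truth,
    min_size: int = MISARRANGEMENT_MIN_SIZE,
    pos_tol: int = 1_000,
    size_tol: int = 50,
) -> dict[str, float]:
    """Precision/recall of classified events against a simulation truth table.

    ``truth`` is the DataFrame produced by the scaffold simulator (columns
    kind, scaffold, chrom, ref_start, ref_end, size).  Truth rows at or
    below min_size are expected NOT to be reported and are excluded from
    the recall denominator.  Matching is greedy within a kind: positions
    must agree within pos_tol and sizes within size_tol.
    """
    truth_rows = [
        row
        for row in truth.to_dict("records")
        if row["kind"] == "misjoin" or row["size"] > min_size
    ]
    matched_truth: set[int] = set()
    n_pred_matched = 0
    for ev in predicted:
        best = None
        for ti, row in enumerate(truth_rows):
            if ti in matched_truth or row["kind"] != ev.kind:
                continue
            if row["chrom"] != ev.ref_chrom:
                continue
            t_pos = row["ref_start"]
            if ev.kind == "inversion":
                ok = (
                    abs(ev.ref_pos - t_pos) <= pos_tol
                    and abs(ev.size - row["size"]) <= max(size_tol, 0.1 * row["size"])
                )
            elif ev.kind == "misjoin":
                ok = min(abs(ev.ref_pos - row["ref_start"]),
                         abs(ev.ref_pos - row["ref_end"])) <= pos_tol
            else:
                ok = (
                    abs(ev.ref_pos - t_pos) <= pos_tol
                    and abs(ev.size - row["size"]) <= size_tol
                )
            if ok:
                best = ti
                break
        if best is not None:
            matched_truth.add(best)
            n_pred_matched += 1
    n_pred = len(predicted)
    n_truth = len(truth_rows)
    return {
        "precision": n_pred_matched / n_pred if n_pred else 1.0,
        "recall": len(matched_truth) / n_truth if n_truth else 1.0,
        "n_predicted": float(n_pred),
        "n_truth": float(n_truth),
    }


# ---------------------------------------------------------------------------
# Small indels
# ---------------------------------------------------------------------------


def count_small_indels(
    fragments: Sequence[AlignmentFragment],
    gene_intervals: dict[str, Sequence[tuple[int, int]]] | None = None,
) -> tuple[int, int]:
    """(inserted bases, deleted bases) summed over fragment alignment detail.

    With ``gene_intervals`` (per-chromosome half-open intervals) only gaps
    whose reference coordinate falls inside a gene are counted.
    """
    if gene_intervals is None:
        return (
            sum(f.n_ins for f in fragments),
            sum(f.n_del for f in fragments),
        )
    starts = {}
    ends = {}
    for chrom, ivs in gene_intervals.items():
        ivs = sorted(ivs)
        starts[chrom] = np.array([a for a, _ in ivs])
        ends[chrom] = np.array([b for _, b in ivs])
    n_ins = n_del = 0
    for f in fragments:
        if f.ref_chrom not in starts:
            continue
        s, e = starts[f.ref_chrom], ends[f.ref_chrom]
        for pos, kind, length in f.indels:
            i = int(np.searchsorted(s, pos, side="right")) - 1
            if i >= 0 and pos < e[i]:
                if kind == "ins":
                    n_ins += length
                else:
                    n_del += length
    return n_ins, n_del


# ---------------------------------------------------------------------------
# Contigs and scaffolding ratio
# ---------------------------------------------------------------------------


def split_to_contigs(scaffolds: dict[str, str]) -> dict[str, str]:
    """Break scaffolds at N runs into maximal N-free contigs."""
    contigs: dict[str, str] = {}
    for sid, seq in scaffolds.items():
        pieces = [p for p in re.split(r"[Nn]+", seq) if p]
        if len(pieces) == 1:
            contigs[sid] = pieces[0]
        else:
            for i, p in enumerate(pieces, 1):
                contigs[f"{sid}_ctg{i}"] = p
    return contigs


def scaffolding_ratio(n_contigs: int, n_scaffolds: int) -> float:
    """Contig count over scaffold count, rounded half-up to 2 decimals."""
    if n_scaffolds <= 0:
        raise ValueError("n_scaffolds must be > 0")
    d = Decimal(n_contigs) / Decimal(n_scaffolds)
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------


@dataclass
class SizeStats:
    n_scaffolds_95: int
    n_scaffolds_500: int
    n50: int
    max: int
    total: int


def size_stats(lengths: Iterable[int], floor: int = SCAFFOLD_SIZE_FLOOR) -> SizeStats:
    """Size statistics over sequences longer than the reporting floor."""
    kept = [x for x in lengths if x > floor]
    if not kept:
        raise ValueError(f"no sequences above the {floor} bp floor")
    return SizeStats(
        n_scaffolds_95=len(kept),
        n_scaffolds_500=sum(1 for x in kept if x > 500),
        n50=n50(kept),
        max=max(kept),
        total=sum(kept),
    )


@dataclass
class AssemblyReport:
    """All per-assembly metrics in one record (one row of each report table)."""

    name: str
    scaffold_stats: SizeStats
    coverage_pct: float
    r50: int
    class_coverage: dict[str, float]
    misarrangements: dict[str, int] = field(default_factory=dict)
    deletion_total_bp: int = 0
    insertion_total_bp: int = 0
    small_indels_genome: tuple[int, int] = (0, 0)
    small_indels_gene: tuple[int, int] = (0, 0)
    n_contigs: int = 0
    contig_n50: int = 0
    scaffolding_ratio: float = 0.0
    n_misjoin_scaffolds: int = 0
    depth: float = 0.0


def evaluate_assembly(
    name: str,
    scaffolds: dict[str, str],
    reference: dict[str, str],
    fragments: Sequence[AlignmentFragment],
    gene_intervals: dict[str, Sequence[tuple[int, int]]] | None = None,
    min_size: int = MISARRANGEMENT_MIN_SIZE,
    misjoin_bound: int = MISJOIN_DISTANCE_BOUND,
    depth: float = 0.0,
) -> AssemblyReport:
    """Compute the full metrics report for one assembly."""
    genome_size = sum(len(s) for s in reference.values())
    events = classify_misarrangements(fragments, min_size, misjoin_bound)
    counts = {k: 0 for k in ("misjoin", "inversion", "deletion", "insertion")}
    del_bp = ins_bp = 0
    for e in events:
        counts[e.kind] += 1
        if e.kind == "deletion":
            del_bp += e.size
        elif e.kind == "insertion":
            ins_bp += e.size
    contigs = split_to_contigs(scaffolds)
    contig_lengths = [len(s) for s in contigs.values() if len(s) > SCAFFOLD_SIZE_FLOOR]
    return AssemblyReport(
        name=name,
        scaffold_stats=size_stats(len(s) for s in scaffolds.values()),
        coverage_pct=genome_coverage(fragments, reference),
        r50=r50(fragments, genome_size),
        class_coverage=coverage_by_class(fragments, reference),
        misarrangements=counts,
        deletion_total_bp=del_bp,
        insertion_total_bp=ins_bp,
        small_indels_genome=count_small_indels(fragments),
        small_indels_gene=(
            count_small_indels(fragments, gene_intervals)
            if gene_intervals
            else (0, 0)
        ),
        n_contigs=len(contig_lengths),
        contig_n50=n50(contig_lengths) if contig_lengths else 0,
        scaffolding_ratio=scaffolding_ratio(len(contig_lengths), len(scaffolds)),
        n_misjoin_scaffolds=misjoin_scaffold_count(events),
        depth=depth,
    )
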