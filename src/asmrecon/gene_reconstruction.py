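"""Per-gene reconstruction scoring and gene-cluster continuity.

Each annotated gene (intron-inclusive nucleotide sequence) is searched
against the assembled scaffolds.  Local alignments are turned into
high-scoring segment pairs (HSPs) by a Karlin-Altschul E-value cutoff
(E < 1e-100 by default); for each gene only the single best-scoring
scaffold is used.  Reported per gene: the fraction of gene bases inside
qualifying HSPs, the fraction identical within them, and whether the gene
is lost entirely.  Cluster continuity asks whether an ordered run of
genes (a secondary-metabolite cluster) lands on one scaffold, in order
(global reversal allowed), with no foreign gene placed in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotations import GeneRecord
from .fragment_align import AlignmentFragment, ReferenceAligner

# Ungapped Karlin-Altschul parameters for unit match/mismatch scoring at
# uniform base composition: lambda solves (1/4)e^l + (3/4)e^-l = 1.
KA_LAMBDA = math.log(3.0)
KA_K = 0.621
EVALUE_MAX = 1e-100


def log10_evalue(score: float, m: int, n: int,
                 lam: float = KA_LAMBDA, K: float = KA_K) -> float:
    """log10 of E = K*m*n*exp(-lambda*S); computed in log space."""
    if m <= 0 or n <= 0:
        raise ValueError("search space sizes must be positive")
    return math.log10(K * m * n) - lam * score / math.log(10.0)


@dataclass
class GeneReconResult:
    """Reconstruction score of one gene against the scaffold set."""

    gene_id: str
    gene_length: int
    best_scaffold: str | None
    hsp_fraction: float
    identity_fraction: float
    lost: bool
    # qualifying HSP footprint on the best scaffold, for continuity checks
    scaffold_span: tuple[int, int] | None = None
    hsps: tuple[AlignmentFragment, ...] = ()


def build_scaffold_aligner(
    scaffolds: Mapping[str, str], size_floor: int = 95, **kwargs
) -> ReferenceAligner:
    """Index scaffolds above the size floor for gene searches."""
    kept = {k: v for k, v in scaffolds.items() if len(v) > size_floor}
    if not kept:
        raise ValueError(f"no scaffolds above the {size_floor} bp floor")
    return ReferenceAligner(kept, **kwargs)


def evaluate_gene(
    gene_id: str,
    gene_seq: str,
    aligner: ReferenceAligner,
    evalue_max: float = EVALUE_MAX,
    min_score: int = 40,
) -> GeneReconResult:
    """Score one gene's reconstruction in the scaffolds.

    All qualifying HSPs (E < evalue_max) from the single best-scoring
    scaffold contribute; overlapping HSPs are counted once, and identity
    never exceeds HSP coverage.
    """
    if not gene_seq:
        raise ValueError(f"{gene_id}: empty gene sequence")
    glen = len(gene_seq)
    log10_cut = math.log10(evalue_max)
    frags = aligner.map(gene_id, gene_seq, min_score=min_score)
    qualifying = [
        f
        for f in frags
        if log10_evalue(f.score, glen, aligner.total) < log10_cut
    ]
    if not qualifying:
        return GeneReconResult(gene_id, glen, None, 0.0, 0.0, True)

    # scaffold holding the single highest-scoring HSP
    best = max(qualifying, key=lambda f: f.score).ref_chrom
    chosen = sorted(
        (f for f in qualifying if f.ref_chrom == best),
        key=lambda f: f.scaffold_start,  # gene coordinates
    )
    covered = 0
    matched = 0
    cursor = 0
    for f in chosen:
        eff_start = max(f.scaffold_start, cursor)
        eff = max(0, f.scaffold_end - eff_start)
        covered += eff
        n_match = f.scaffold_span - f.n_ins - f.n_mismatch
        matched += min(n_match, eff)
        cursor = max(cursor, f.scaffold_end)
    span = (min(f.ref_start for f in chosen), max(f.ref_end for f in chosen))
    return GeneReconResult(
        gene_id,
        glen,
        best,
        hsp_fraction=covered / glen,
        identity_fraction=matched / glen,
        lost=False,
        scaffold_span=span,
        hsps=tuple(chosen),
    )


def evaluate_genes(
    genes: Sequence[GeneRecord],
    chromosomes: Mapping[str, str],
    scaffolds: Mapping[str, str],
    evalue_max: float = EVALUE_MAX,
    size_floor: int = 95,
    **aligner_kwargs,
) -> dict[str, GeneReconResult]:
    """Evaluate every annotated gene against the scaffold set."""
    aligner = build_scaffold_aligner(scaffolds, size_floor, **aligner_kwargs)
    return {
        g.gene_id: evaluate_gene(
            g.gene_id, g.sequence(chromosomes), aligner, evalue_max
        )
        for g in genes
    }


def summarize_genes(
    results: Mapping[str, GeneReconResult],
    subset: Iterable[str] | None = None,
) -> dict[str, float]:
    """Base-weighted aggregate HSP%/identity% and the lost-gene count.

    ``subset`` restricts the aggregate to a named gene list (e.g. the
    PKS/NRPS genes) — the genome-wide lost count is still over all genes
    passed in.
    """
    chosen = (
        [results[g] for g in subset] if subset is not None else list(results.values())
    )
    if subset is not None:
        missing = [g for g in subset if g not in results]
        if missing:
            raise KeyError(f"unknown gene ids in subset: {missing[:5]}")
    total = sum(r.gene_length for r in chosen)
    if total == 0:
        raise ValueError("no genes to summarize")
    return {
        "hsp_pct": 100.0 * sum(r.hsp_fraction * r.gene_length for r in chosen) / total,
        "identity_pct": 100.0
        * sum(r.identity_fraction * r.gene_length for r in chosen)
        / total,
        "n_genes": float(len(chosen)),
        "n_lost": float(sum(r.lost for r in chosen)),
    }


def cluster_continuity(
    cluster: Sequence[str],
    results: Mapping[str, GeneReconResult],
) -> bool:
    """Is an ordered gene cluster reproduced contiguously in the scaffolds?

    True iff every cluster gene has qualifying HSPs on one and the same
    scaffold, their order along that scaffold matches the cluster order
    (or its exact reversal), and no other evaluated gene's placement falls
    between them on that scaffold.
    """
    missing = [g for g in cluster if g not in results]
    if missing:
        raise KeyError(f"unknown gene ids in cluster: {missing[:5]}")
    rs = [results[g] for g in cluster]
    if any(r.lost or r.scaffold_span is None for r in rs):
        return False
    scaffolds = {r.best_scaffold for r in rs}
    if len(scaffolds) != 1:
        return False
    (scaffold,) = scaffolds
    mids = [sum(r.scaffold_span) / 2 for r in rs]
    increasing = all(a < b for a, b in zip(mids, mids[1:]))
    decreasing = all(a > b for a, b in zip(mids, mids[1:]))
    if not (increasing or decreasing):
        return False
    lo, hi = min(mids), max(mids)
    member = set(cluster)
    for gid, r in results.items():
        if gid in member or r.lost or r.best_scaffold != scaffold:
            continue
        mid = sum(r.scaffold_span) / 2
        if lo < mid < hi:
            return False
    return True
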