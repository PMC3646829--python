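"""Gene reconstruction scoring (HSP/identity fractions) and cluster continuity."""

import dataclasses

import pytest

from asmrecon.gene_reconstruction import (
    GeneReconResult,
    build_scaffold_aligner,
    cluster_continuity,
    evaluate_gene,
    evaluate_genes,
    log10_evalue,
    summarize_genes,
)
from asmrecon.seqio import revcomp


@pytest.fixture(scope="module")
def identity_results(genome):
    """All genes evaluated against error-free scaffolds (= the chromosomes)."""
    return evaluate_genes(genome.genes, genome.chromosomes, dict(genome.chromosomes))


def test_evalue_threshold_behaviour():
    # a perfect ~250 bp match is overwhelmingly significant...
    assert log10_evalue(250, 1_000, 1_000_000) < -100
    # ...a 40-score alignment is not
    assert log10_evalue(40, 1_000, 1_000_000) > -100


def test_gene_present_verbatim_scores_perfect(genome, identity_results):
    for r in identity_results.values():
        assert not r.lost
        assert r.hsp_fraction == 1.0
        assert r.identity_fraction == 1.0


def test_gene_absent_from_scaffolds_is_lost(genome):
    import numpy as np

    rng = np.random.default_rng(5)
    decoy = {"s1": "".join(rng.choice(list("ACGT"), 20_000))}
    aligner = build_scaffold_aligner(decoy)
    gene = genome.genes[0]
    res = evaluate_gene(gene.gene_id, gene.sequence(genome.chromosomes), aligner)
    assert res.lost
    assert res.hsp_fraction == res.identity_fraction == 0.0


def test_split_gene_uses_best_scaffold_only(genome):
    # a non-repeat gene, so no secondary repeat HSPs blur the split
    gene = max(
        (g for g in genome.genes if g.product == "hypothetical protein"),
        key=lambda g: g.length,
    )
    seq = gene.sequence(genome.chromosomes)
    half = len(seq) // 2
    pad_a = genome.chromosomes[gene.chrom][:3_000]
    scaffolds = {
        "sA": seq[: half + 200] + pad_a,  # larger piece -> best scaffold
        "sB": seq[half:],
    }
    aligner = build_scaffold_aligner(scaffolds)
    res = evaluate_gene(gene.gene_id, seq, aligner)
    assert res.best_scaffold == "sA"
    assert res.hsp_fraction < 1.0  # only the best scaffold's HSPs count
    assert res.hsp_fraction == pytest.approx((half + 200) / len(seq), abs=0.02)


def test_identity_never_exceeds_hsp_fraction(genome, identity_results):
    for r in identity_results.values():
        assert r.identity_fraction <= r.hsp_fraction <= 1.0


def test_lost_implies_zero_fractions():
    r = GeneReconResult("g", 100, None, 0.0, 0.0, True)
    assert r.lost and r.hsp_fraction == 0.0 and r.identity_fraction == 0.0


def test_summary_base_weighting():
    results = {
        f"g{i}": GeneReconResult(f"g{i}", 1_000, "s1", 1.0, 1.0, False,
                                 scaffold_span=(0, 1_000))
        for i in range(3)
    }
    results["g3"] = GeneReconResult("g3", 1_000, None, 0.0, 0.0, True)
    s = summarize_genes(results)
    assert s["hsp_pct"] == pytest.approx(75.0)
    assert s["n_lost"] == 1


def test_summary_all_perfect(identity_results):
    s = summarize_genes(identity_results)
    assert s["hsp_pct"] == 100.0
    assert s["identity_pct"] == 100.0
    assert s["n_lost"] == 0


def test_summary_subset_bounded(genome, identity_results):
    smb = [g.gene_id for g in genome.genes if "polyketide" in g.product]
    assert smb
    s = summarize_genes(identity_results, subset=smb)
    assert s["hsp_pct"] <= 100.0
    assert s["n_genes"] == len(smb)


def test_clusters_continuous_on_identity_scaffolds(genome, identity_results):
    for ids in genome.clusters.values():
        assert cluster_continuity(ids, identity_results)


def test_cluster_continuity_allows_global_reversal(genome):
    by_id = {g.gene_id: g for g in genome.genes}
    ids = genome.clusters["cluster_3"]
    chrom = by_id[ids[0]].chrom
    scaffolds = dict(genome.chromosomes)
    scaffolds[chrom] = revcomp(scaffolds[chrom])
    res = evaluate_genes(genome.genes, genome.chromosomes, scaffolds)
    assert cluster_continuity(ids, res)


def test_cluster_split_across_scaffolds_not_continuous(genome):
    by_id = {g.gene_id: g for g in genome.genes}
    ids = genome.clusters["cluster_3"]
    chrom = by_id[ids[0]].chrom
    lo = min(by_id[i].start for i in ids)
    hi = max(by_id[i].end for i in ids)
    mid = (lo + hi) // 2
    scaffolds = dict(genome.chromosomes)
    seq = scaffolds.pop(chrom)
    scaffolds["left"] = seq[:mid]
    scaffolds["right"] = seq[mid:]
    res = evaluate_genes(genome.genes, genome.chromosomes, scaffolds)
    assert not cluster_continuity(ids, res)


def test_deleting_middle_gene_flips_exactly_that_cluster(genome):
    by_id = {g.gene_id: g for g in genome.genes}
    ids = genome.clusters["cluster_3"]
    mid_gene = by_id[ids[1]]
    scaffolds = dict(genome.chromosomes)
    seq = scaffolds[mid_gene.chrom]
    scaffolds[mid_gene.chrom] = seq[: mid_gene.start - 50] + seq[mid_gene.end + 50 :]
    res = evaluate_genes(genome.genes, genome.chromosomes, scaffolds)
    continuity = {
        name: cluster_continuity(cids, res) for name, cids in genome.clusters.items()
    }
    assert continuity == {"cluster_1": True, "cluster_2": True, "cluster_3": False}
    assert res[ids[1]].lost


def test_permuted_cluster_order_not_continuous():
    results = {
        "a": GeneReconResult("a", 1_000, "s1", 1.0, 1.0, False, (0, 1_000)),
        "b": GeneReconResult("b", 1_000, "s1", 1.0, 1.0, False, (4_000, 5_000)),
        "c": GeneReconResult("c", 1_000, "s1", 1.0, 1.0, False, (2_000, 3_000)),
    }
    assert not cluster_continuity(["a", "b", "c"], results)
    assert cluster_continuity(["a", "c", "b"], results)


def test_foreign_gene_interleaved_breaks_continuity():
    results = {
        "a": GeneReconResult("a", 1_000, "s1", 1.0, 1.0, False, (0, 1_000)),
        "b": GeneReconResult("b", 1_000, "s1", 1.0, 1.0, False, (4_000, 5_000)),
        "x": GeneReconResult("x", 1_000, "s1", 1.0, 1.0, False, (2_000, 3_000)),
    }
    assert not cluster_continuity(["a", "b"], results)
    # same foreign gene on another scaffold does not interfere
    results["x"] = dataclasses.replace(results["x"], best_scaffold="s2")
    assert cluster_continuity(["a", "b"], results)


def test_unknown_cluster_gene_id_rejected(identity_results):
    with pytest.raises(KeyError, match="unknown gene ids"):
        cluster_continuity(["nope_1"], identity_results)
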