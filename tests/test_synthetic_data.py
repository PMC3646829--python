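"""Synthetic genome, scaffold-error and read generators."""

import numpy as np
import pytest

from asmrecon.colorspace import decode_colorspace
from asmrecon.seqio import revcomp
from asmrecon.synthetic_data import (
    ClusterSpec,
    GenomeConfig,
    LibraryConfig,
    RefBlock,
    ScaffoldErrorConfig,
    simulate_genome,
    simulate_mate_pairs,
    simulate_scaffolds,
)

SMALL = GenomeConfig(
    n_chromosomes=2, chrom_length=60_000, n_genes=20,
    cluster_specs=(ClusterSpec(5, 10_000),), seed=3,
)


def test_empty_genome_has_requested_length_and_no_genes():
    g = simulate_genome(
        GenomeConfig(n_chromosomes=1, chrom_length=30_000, n_genes=0,
                     cluster_specs=(), seed=1)
    )
    assert set(g.chromosomes) == {"chr1"}
    assert len(g.chromosomes["chr1"]) == 30_000
    assert g.genes == [] and g.clusters == {}


def test_same_seed_reproduces_identical_genome():
    a, b = simulate_genome(SMALL), simulate_genome(SMALL)
    assert a.chromosomes == b.chromosomes
    assert [(g.gene_id, g.start, g.end, g.strand) for g in a.genes] == [
        (g.gene_id, g.start, g.end, g.strand) for g in b.genes
    ]


def test_cluster_genes_contiguous_ordered_within_span(genome):
    by_id = {g.gene_id: g for g in genome.genes}
    for spec, ids in zip(genome.config.cluster_specs, genome.clusters.values()):
        genes = [by_id[i] for i in ids]
        assert len(genes) == spec.n_genes
        assert len({g.chrom for g in genes}) == 1
        starts = [g.start for g in genes]
        assert starts == sorted(starts)
        assert max(g.end for g in genes) - min(g.start for g in genes) <= spec.span


def test_genes_do_not_overlap(genome):
    by_chrom = {}
    for g in genome.genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for ivs in by_chrom.values():
        ivs.sort()
        assert all(a2 >= b1 for (_, b1), (a2, _) in zip(ivs, ivs[1:]))


def test_centromere_is_at_rich_background_is_not(genome):
    cfg = genome.config
    cen_start = (cfg.chrom_length - cfg.centromere_length) // 2
    for seq in genome.chromosomes.values():
        cen = seq[cen_start : cen_start + cfg.centromere_length]
        at_cen = (cen.count("A") + cen.count("T")) / len(cen)
        assert at_cen >= cfg.centromere_at_fraction - 0.03
        arm = seq[: cen_start - 1000]
        gc_arm = (arm.count("G") + arm.count("C")) / len(arm)
        # within 3 sigma of the binomial background
        sigma = (cfg.gc_background * (1 - cfg.gc_background) / len(arm)) ** 0.5
        assert abs(gc_arm - cfg.gc_background) < 3 * sigma + 0.01


def test_infeasible_packing_raises():
    with pytest.raises(ValueError, match="infeasible"):
        simulate_genome(
            GenomeConfig(n_chromosomes=1, chrom_length=30_000, n_genes=0,
                         cluster_specs=(ClusterSpec(29, 73_000),), seed=1)
        )


def test_zero_error_scaffolds_are_the_chromosomes(genome):
    sim = simulate_scaffolds(genome, ScaffoldErrorConfig())
    assert list(sim.scaffolds.values()) == list(genome.chromosomes.values())
    assert len(sim.truth) == 0


def test_truth_table_matches_event_roster(errored):
    from tests.conftest import ERROR_CONFIG as cfg

    counts = errored.truth.kind.value_counts().to_dict()
    assert counts["misjoin"] == cfg.n_misjoin
    assert counts["inversion"] == cfg.n_inversion + cfg.n_small_inversion
    assert counts["deletion"] == cfg.n_deletion + cfg.n_small_deletion
    assert counts["insertion"] == cfg.n_insertion + cfg.n_small_insertion
    big = errored.truth[errored.truth.kind != "misjoin"]
    lo, hi = cfg.small_size_range
    assert ((big["size"] > 500) | ((big["size"] >= lo) & (big["size"] <= hi))).all()


def test_scaffolds_reconstructible_from_truth_blocks(genome, errored):
    """Every scaffold renders exactly from its block decomposition.

    (Small per-bp indels are applied after rendering, so this checks the
    block model itself with the indel-free part of the config.)
    """
    from tests.conftest import ERROR_CONFIG

    import dataclasses

    cfg = dataclasses.replace(ERROR_CONFIG, small_indel_rate=0.0)
    sim = simulate_scaffolds(genome, cfg)
    for sid, blocks in sim.blocks.items():
        parts = []
        for b in blocks:
            if isinstance(b, RefBlock):
                s = genome.chromosomes[b.chrom][b.start : b.end]
                parts.append(s if b.strand == "+" else revcomp(s))
            elif hasattr(b, "seq"):
                parts.append(b.seq)
            else:
                parts.append("N" * b.length)
        assert "".join(parts) == sim.scaffolds[sid]


def test_misjoin_junctions_receive_gap_runs(errored):
    total_n = sum(seq.count("N") for seq in errored.scaffolds.values())
    assert total_n == 3 * 100  # n_misjoin * gap_run


def test_mate_pair_insert_distribution(genome):
    lib = LibraryConfig(n_pairs=2_000, seed=1)
    sim = simulate_mate_pairs(genome, lib)
    ins = sim.truth["insert"].to_numpy()
    se = lib.insert_sd / np.sqrt(lib.n_pairs)
    assert abs(ins.mean() - lib.insert_mean) < 3 * se
    assert abs(ins.std() - lib.insert_sd) < 0.1 * lib.insert_sd
    assert (ins >= 2 * lib.read_len).all()


def test_mate_pair_reads_decode_to_reference(genome):
    lib = LibraryConfig(n_pairs=50, dot_rate=0.0, seed=9)
    sim = simulate_mate_pairs(genome, lib)
    for (f3, r3), row in zip(sim.pairs, sim.truth.to_dict("records")):
        frag = genome.chromosomes[row["chrom"]][
            row["start"] : row["start"] + row["insert"]
        ]
        if row["strand"] == "-":
            frag = revcomp(frag)
        assert decode_colorspace(f3.primer_base, f3.colors)[1:] == frag[: lib.read_len]
        assert decode_colorspace(r3.primer_base, r3.colors)[1:] == frag[-lib.read_len :]


def test_dot_rate_zero_means_no_dots(genome):
    sim = simulate_mate_pairs(genome, LibraryConfig(n_pairs=100, dot_rate=0.0, seed=2))
    assert all("." not in r.colors for pair in sim.pairs for r in pair)


def test_dot_rate_realized_within_binomial_tolerance(genome):
    lib = LibraryConfig(n_pairs=2_000, dot_rate=0.01, seed=4)
    sim = simulate_mate_pairs(genome, lib)
    n_colors = 2 * lib.n_pairs * lib.read_len
    n_dots = sum(r.colors.count(".") for pair in sim.pairs for r in pair)
    rate = n_dots / n_colors
    sigma = (0.01 * 0.99 / n_colors) ** 0.5
    assert abs(rate - 0.01) < 4 * sigma


def test_no_pairs_yields_empty_output(genome):
    sim = simulate_mate_pairs(genome, LibraryConfig(n_pairs=0))
    assert sim.pairs == [] and len(sim.truth) == 0


def test_read_simulation_deterministic(genome):
    lib = LibraryConfig(n_pairs=20, seed=5)
    a, b = simulate_mate_pairs(genome, lib), simulate_mate_pairs(genome, lib)
    assert [(x.read_id, x.colors, x.qvs) for p in a.pairs for x in p] == [
        (x.read_id, x.colors, x.qvs) for p in b.pairs for x in p
    ]
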