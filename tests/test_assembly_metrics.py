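"""N50/NG50/R50, coverage, misarrangement classification, contigs, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmrecon.assembly_metrics import (
    classify_misarrangements,
    count_small_indels,
    coverage_by_class,
    evaluate_assembly,
    genome_coverage,
    n50,
    ng50,
    r50,
    scaffolding_ratio,
    score_event_recovery,
    size_stats,
    split_to_contigs,
)
from asmrecon.fragment_align import AlignmentFragment


def cumulative_oracle(lengths, half):
    """Independent oracle: walk lengths in descending order to the threshold."""
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if acc >= half:
            return x
    return 0


# ---------------------------------------------------------------------------
# N50 / NG50 / R50
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "lengths, expect",
    [([100], 100), ([50, 40, 30, 20, 10], 40), ([10, 10, 10, 10], 10)],
)
def test_n50_examples(lengths, expect):
    assert n50(lengths) == expect


def test_n50_empty_rejected():
    with pytest.raises(ValueError):
        n50([])


@given(st.lists(st.integers(1, 10_000), min_size=1, max_size=60))
@settings(max_examples=300, deadline=None)
def test_n50_matches_cumulative_oracle(lengths):
    assert n50(lengths) == cumulative_oracle(lengths, sum(lengths) / 2)


@pytest.mark.parametrize(
    "lengths, gsize, expect",
    [([60, 30], 100, 60), ([10], 1_000, 0), ([50, 50], 100, 50)],
)
def test_ng50_examples(lengths, gsize, expect):
    assert ng50(lengths, gsize) == expect


@given(st.lists(st.integers(1, 10_000), min_size=1, max_size=60),
       st.integers(1, 500_000))
@settings(max_examples=300, deadline=None)
def test_ng50_matches_cumulative_oracle(lengths, gsize):
    assert ng50(lengths, gsize) == cumulative_oracle(lengths, gsize / 2)


@given(st.lists(st.integers(1, 10_000), min_size=1, max_size=60))
@settings(max_examples=100, deadline=None)
def test_ng50_equals_n50_when_total_is_genome_size(lengths):
    assert ng50(lengths, sum(lengths)) == n50(lengths)


def _frag(ref_start, ref_end, chrom="chr1", sid="s1", s0=None, strand="+", score=None):
    span = ref_end - ref_start
    s0 = ref_start if s0 is None else s0
    return AlignmentFragment(
        sid, s0, s0 + span, chrom, ref_start, ref_end, strand,
        score if score is not None else span,
    )


def test_r50_examples():
    assert r50([_frag(0, 100_000)], 100_000) == 100_000
    assert r50([_frag(0, 60_000), _frag(60_000, 90_000)], 100_000) == 60_000
    assert r50([], 100_000) == 0


def test_r50_full_tiling_equals_ng50_of_chromosomes(genome, perfect_fragments):
    gsize = genome.genome_size
    chrom_ng50 = ng50([len(s) for s in genome.chromosomes.values()], gsize)
    assert r50(perfect_fragments, gsize) == chrom_ng50


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def test_genome_coverage_union_semantics():
    ref = {"chr1": 100_000}
    tiles = [_frag(0, 50_000), _frag(50_000, 100_000)]
    assert genome_coverage(tiles, ref) == 100.0
    dup = tiles + [_frag(10_000, 40_000, sid="s2")]
    assert genome_coverage(dup, ref) == 100.0  # overlap counted once
    assert genome_coverage([_frag(0, 50_000)], ref) == 50.0


def test_coverage_by_class_longest_wins_and_sums_to_one():
    ref = {"chr1": 100_000}
    cc = coverage_by_class([_frag(0, 60_000)], ref)
    assert cc["gt_50kb"] == pytest.approx(0.6)
    assert cc["uncovered"] == pytest.approx(0.4)

    cc = coverage_by_class([_frag(0, 9_000)], ref)  # 9 kb is <= 10 kb class
    assert cc["le_10kb"] == pytest.approx(0.09)

    # base under both a 9 kb and a 60 kb fragment goes to the longer one
    cc = coverage_by_class([_frag(0, 9_000, sid="s2"), _frag(0, 60_000)], ref)
    assert cc["le_10kb"] == 0.0
    assert cc["gt_50kb"] == pytest.approx(0.6)
    assert sum(cc.values()) == pytest.approx(1.0, abs=1e-9)


def test_boundary_10kb_fragment_is_le_class():
    ref = {"chr1": 100_000}
    cc = coverage_by_class([_frag(0, 10_000)], ref)
    assert cc["le_10kb"] == pytest.approx(0.10)
    cc = coverage_by_class([_frag(0, 10_001)], ref)
    assert cc["gt_10kb"] == pytest.approx(0.10001)


# ---------------------------------------------------------------------------
# Misarrangement classification
# ---------------------------------------------------------------------------


def test_cross_chromosome_junction_is_misjoin():
    frags = [_frag(0, 10_000), _frag(0, 10_000, chrom="chr2", s0=10_000)]
    (ev,) = classify_misarrangements(frags)
    assert ev.kind == "misjoin"


def test_ref_gap_above_threshold_is_deletion():
    frags = [_frag(0, 10_000), _frag(10_600, 20_000, s0=10_000)]
    (ev,) = classify_misarrangements(frags)
    assert (ev.kind, ev.size) == ("deletion", 600)


def test_ref_gap_below_threshold_is_no_event():
    frags = [_frag(0, 10_000), _frag(10_400, 20_000, s0=10_000)]
    assert classify_misarrangements(frags) == []


def test_scaffold_gap_above_threshold_is_insertion():
    frags = [_frag(0, 10_000), _frag(10_000, 20_000, s0=10_800)]
    (ev,) = classify_misarrangements(frags)
    assert (ev.kind, ev.size) == ("insertion", 800)


def test_interior_flip_counts_once_as_inversion():
    frags = [
        _frag(0, 10_000),
        _frag(10_000, 12_000, s0=10_000, strand="-"),
        _frag(12_000, 20_000, s0=12_000),
    ]
    events = classify_misarrangements(frags)
    assert [e.kind for e in events] == ["inversion"]
    assert events[0].size == 2_000


def test_small_interior_flip_not_reported():
    frags = [
        _frag(0, 10_000),
        _frag(10_000, 10_400, s0=10_000, strand="-"),
        _frag(10_400, 20_000, s0=10_400),
    ]
    assert classify_misarrangements(frags) == []


def test_large_same_chromosome_displacement_is_misjoin():
    frags = [_frag(0, 10_000), _frag(150_000, 160_000, s0=10_000)]
    (ev,) = classify_misarrangements(frags)
    assert ev.kind == "misjoin"


def test_unsorted_fragments_rejected():
    frags = [_frag(10_000, 20_000, s0=10_000), _frag(0, 10_000)]
    with pytest.raises(ValueError, match="not sorted"):
        classify_misarrangements(frags)


def test_planted_events_recovered_exactly(errored, errored_fragments):
    events = classify_misarrangements(errored_fragments)
    rec = score_event_recovery(events, errored.truth)
    assert rec["precision"] == 1.0
    assert rec["recall"] == 1.0


def test_sub_threshold_planted_events_never_reported(errored, errored_fragments):
    from tests.conftest import ERROR_CONFIG as cfg

    events = classify_misarrangements(errored_fragments)
    n_big = cfg.n_misjoin + cfg.n_inversion + cfg.n_deletion + cfg.n_insertion
    assert len(events) == n_big


# ---------------------------------------------------------------------------
# Small indels, contigs, ratios
# ---------------------------------------------------------------------------


def test_count_small_indels_sums_and_gene_mask():
    f1 = AlignmentFragment(
        "s1", 0, 1_003, "chr1", 0, 1_001, "+", 900, n_ins=3, n_del=1,
        indels=((100, "ins", 2), (500, "ins", 1), (800, "del", 1)),
    )
    assert count_small_indels([f1]) == (3, 1)
    # gene covering [0, 200): only the first insertion falls inside
    assert count_small_indels([f1], {"chr1": [(0, 200)]}) == (2, 0)
    g_ins, g_del = count_small_indels([f1], {"chr1": [(0, 1_001)]})
    assert (g_ins, g_del) == (3, 1)


def test_perfect_alignments_have_zero_indels(perfect_fragments):
    assert count_small_indels(perfect_fragments) == (0, 0)


@pytest.mark.parametrize(
    "seq, expect",
    [
        ("ACGTNNNNACGT", ["ACGT", "ACGT"]),
        ("ACGTACGT", ["ACGTACGT"]),
        ("NNNN", []),
        ("NACGTN", ["ACGT"]),
    ],
)
def test_split_to_contigs(seq, expect):
    assert list(split_to_contigs({"s": seq}).values()) == expect


@pytest.mark.parametrize(
    "contigs, scaffolds, ratio",
    [(5332, 1184, 4.50), (7153, 2456, 2.91), (8254, 3050, 2.71),
     (7763, 2751, 2.82), (5265, 1147, 4.59), (7, 7, 1.00)],
)
def test_scaffolding_ratio_two_decimals(contigs, scaffolds, ratio):
    assert scaffolding_ratio(contigs, scaffolds) == ratio


def test_scaffolding_ratio_zero_scaffolds_rejected():
    with pytest.raises(ValueError):
        scaffolding_ratio(10, 0)


def test_size_stats_floors_and_monotonicity():
    s = size_stats([50, 96, 400, 501, 2_000])
    assert s.n_scaffolds_95 == 4  # 50 excluded by the >95 floor
    assert s.n_scaffolds_500 == 2
    assert s.n_scaffolds_500 <= s.n_scaffolds_95
    assert s.max >= s.n50


def test_evaluate_assembly_report_consistency(genome, errored, errored_fragments):
    gene_ivs = {}
    for g in genome.genes:
        gene_ivs.setdefault(g.chrom, []).append((g.start, g.end))
    rep = evaluate_assembly(
        "errored", errored.scaffolds, genome.chromosomes, errored_fragments,
        gene_intervals=gene_ivs,
    )
    assert 0.0 <= rep.coverage_pct <= 100.0
    assert sum(rep.class_coverage.values()) == pytest.approx(1.0, abs=1e-9)
    assert rep.small_indels_gene[0] <= rep.small_indels_genome[0]
    assert rep.small_indels_gene[1] <= rep.small_indels_genome[1]
    # three misjoins each cut one N-gap junction into the target scaffold
    assert rep.n_contigs >= len(errored.scaffolds)
    assert rep.scaffolding_ratio >= 1.0
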