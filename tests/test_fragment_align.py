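"""Local alignment of scaffolds to a reference: fragments, PAF I/O, SW oracle."""

import numpy as np
import pytest

from asmrecon.fragment_align import (
    AlignmentFragment,
    align_scaffolds,
    load_fragments,
    select_primary_fragments,
    smith_waterman,
    write_paf,
)
from asmrecon.seqio import revcomp


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# ---------------------------------------------------------------------------
# Smith-Waterman vs an independent brute-force oracle
# ---------------------------------------------------------------------------


def sw_oracle_score(q, t, match=1, mismatch=1, gap_open=2, gap_extend=1):
    """Independent affine local-alignment score: two-row DP, score only."""
    NEG = -(10**9)
    m = len(t)
    h_prev = [0] * (m + 1)
    x_prev = [NEG] * (m + 1)
    best = 0
    for qi in q:
        h_cur = [0] * (m + 1)
        x_cur = [NEG] * (m + 1)
        y = NEG
        for j in range(1, m + 1):
            s = match if (qi == t[j - 1] and qi != "N") else -mismatch
            x_cur[j] = max(h_prev[j] - gap_open, x_prev[j] - gap_extend)
            y = max(h_cur[j - 1] - gap_open, y - gap_extend)
            h = max(0, h_prev[j - 1] + s, x_cur[j], y)
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, x_prev = h_cur, x_cur
    return best


def test_smith_waterman_agrees_with_oracle_on_random_pairs():
    rng = np.random.default_rng(7)
    for trial in range(40):
        q = _rand_seq(rng, int(rng.integers(10, 150)))
        t = _rand_seq(rng, int(rng.integers(10, 150)))
        if trial % 2:  # embed a shared segment half the time
            k = min(len(q), len(t)) // 2
            t = t[:5] + q[:k] + t[5:]
        res = smith_waterman(q, t)
        got = res["score"] if res else 0
        assert got == sw_oracle_score(q, t)


def test_smith_waterman_counts_consistent():
    res = smith_waterman("ACGTACGTAC", "ACGTTTACGTAC")
    assert res["n_del"] == 2  # bases present only in the target
    span_q = res["q_end"] - res["q_start"]
    span_t = res["t_end"] - res["t_start"]
    assert span_q - span_t == res["n_ins"] - res["n_del"]


def test_n_never_matches_even_itself():
    assert smith_waterman("NNNN", "NNNN") is None


# ---------------------------------------------------------------------------
# align_scaffolds
# ---------------------------------------------------------------------------


def test_exact_copy_gives_single_full_length_fragment():
    rng = np.random.default_rng(1)
    ref = {"chrA": _rand_seq(rng, 5_000)}
    frags = align_scaffolds({"s": ref["chrA"]}, ref)
    assert len(frags) == 1
    f = frags[0]
    assert (f.scaffold_start, f.scaffold_end) == (0, 5_000)
    assert (f.ref_start, f.ref_end, f.strand) == (0, 5_000, "+")
    assert f.n_ins == f.n_del == f.n_mismatch == 0


def test_reverse_complement_gives_minus_strand_fragment():
    rng = np.random.default_rng(2)
    ref = {"chrA": _rand_seq(rng, 5_000)}
    frags = align_scaffolds({"s": revcomp(ref["chrA"])}, ref)
    assert len(frags) == 1
    assert frags[0].strand == "-"
    assert (frags[0].ref_start, frags[0].ref_end) == (0, 5_000)


def test_short_random_scaffold_scores_below_threshold():
    rng = np.random.default_rng(3)
    ref = {"chrA": _rand_seq(rng, 2_000)}
    scaffold = _rand_seq(rng, 30)  # max possible score 30 < 40
    assert align_scaffolds({"s": scaffold}, ref, min_score=40) == []


def test_zero_error_scaffolds_recover_one_fragment_per_chromosome(
    genome, perfect_fragments
):
    assert len(perfect_fragments) == len(genome.chromosomes)
    for f, (chrom, seq) in zip(perfect_fragments, genome.chromosomes.items()):
        assert (f.ref_start, f.ref_end) == (0, len(seq))
        assert f.strand == "+" and f.n_mismatch == 0


def test_strand_symmetry_on_errored_scaffolds(genome, errored):
    fwd = align_scaffolds(errored.scaffolds, genome.chromosomes)
    rc = align_scaffolds(
        {k: revcomp(v) for k, v in errored.scaffolds.items()}, genome.chromosomes
    )
    flip = {"+": "-", "-": "+"}
    key_f = sorted(
        (f.scaffold_id, f.ref_chrom, f.ref_start, f.ref_end, f.strand) for f in fwd
    )
    key_r = sorted(
        (f.scaffold_id, f.ref_chrom, f.ref_start, f.ref_end, flip[f.strand])
        for f in rc
    )
    assert key_f == key_r


def test_empty_reference_rejected():
    with pytest.raises(ValueError, match="empty reference"):
        align_scaffolds({"s": "ACGT"}, {})


def test_primary_selection_is_nonoverlapping_max_score():
    mk = lambda s, e, sc: AlignmentFragment("s", s, e, "c", s, e, "+", sc)
    frags = [mk(0, 100, 100), mk(50, 200, 80), mk(150, 300, 120)]
    prim = select_primary_fragments(frags, overlap_tol=10)
    assert [(f.scaffold_start, f.scaffold_end) for f in prim] == [(0, 100), (150, 300)]


def test_fragment_invariant_rejects_inconsistent_counts():
    with pytest.raises(ValueError, match="inconsistent"):
        AlignmentFragment("s", 0, 100, "c", 0, 90, "+", 50, n_ins=0, n_del=0)


# ---------------------------------------------------------------------------
# PAF I/O
# ---------------------------------------------------------------------------


def test_paf_roundtrip(genome, errored, errored_fragments, tmp_path):
    paf = tmp_path / "a.paf"
    write_paf(
        errored_fragments,
        paf,
        {k: len(v) for k, v in errored.scaffolds.items()},
        {k: len(v) for k, v in genome.chromosomes.items()},
    )
    back = load_fragments(paf)
    orig = [
        (f.scaffold_id, f.scaffold_start, f.scaffold_end, f.ref_chrom,
         f.ref_start, f.ref_end, f.strand, f.score)
        for f in errored_fragments
    ]
    got = [
        (f.scaffold_id, f.scaffold_start, f.scaffold_end, f.ref_chrom,
         f.ref_start, f.ref_end, f.strand, f.score)
        for f in back
    ]
    assert got == orig


def test_paf_single_line_toy(tmp_path):
    p = tmp_path / "toy.paf"
    p.write_text("s1\t1000\t10\t510\t-\tchr1\t5000\t100\t600\t480\t500\t60\n")
    (f,) = load_fragments(p)
    assert (f.scaffold_start, f.scaffold_end) == (10, 510)
    assert (f.ref_chrom, f.ref_start, f.ref_end, f.strand) == ("chr1", 100, 600, "-")
    assert f.score == 480  # falls back to the match count


def test_paf_too_few_columns_rejected_with_line_number(tmp_path):
    p = tmp_path / "bad.paf"
    p.write_text("s1\t1000\t10\t510\t-\tchr1\t5000\t100\t600\t480\t500\n")
    with pytest.raises(ValueError, match=":1"):
        load_fragments(p)


def test_paf_low_score_records_dropped(tmp_path):
    p = tmp_path / "low.paf"
    p.write_text(
        "s1\t100\t0\t30\t+\tchr1\t500\t0\t30\t30\t30\t60\n"
        "s1\t100\t0\t90\t+\tchr1\t500\t0\t90\t90\t90\t60\n"
    )
    frags = load_fragments(p, min_score=40)
    assert len(frags) == 1 and frags[0].score == 90
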