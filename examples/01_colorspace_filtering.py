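"""Color-space reads and the three filtering regimes.

Simulates a small SOLiD-style mate-paired library, then filters it under
no filter / no-dot / qv10 and reports how the survivor sets nest.
"""

from asmrecon import (
    FilterPolicy,
    FilterStats,
    decode_colorspace,
    depth_of_coverage,
    encode_colorspace,
    filter_pairs,
    qv_to_accuracy,
)
from asmrecon.synthetic_data import (
    GenomeConfig,
    LibraryConfig,
    simulate_genome,
    simulate_mate_pairs,
)

# the di-base code: each color is the transition between adjacent bases
primer, colors = encode_colorspace("AACGT")
print(f"AACGT encodes as primer {primer} + colors {colors}")
print(f"decoding gives back: {decode_colorspace(primer, colors)}")
print(f"QV 10 corresponds to {100 * qv_to_accuracy(10):.0f}% per-base accuracy\n")

genome = simulate_genome(
    GenomeConfig(n_chromosomes=1, chrom_length=100_000, n_genes=0,
                 cluster_specs=(), seed=3)
)
reads = simulate_mate_pairs(
    genome, LibraryConfig(n_pairs=2_000, dot_rate=0.01, seed=31)
)
print(f"simulated {len(reads.pairs)} mate pairs of 50 bp color reads")

for mode in ("nofilter", "nodot", "qv"):
    stats = FilterStats()
    survivors = list(
        filter_pairs(reads.pairs, FilterPolicy(mode, qv_threshold=10), stats)
    )
    depth = depth_of_coverage(2 * len(survivors), 50, genome.genome_size)
    print(
        f"  {mode:>8}: {stats.pairs_out:>5}/{stats.pairs_in} pairs kept, "
        f"{stats.bases_out} bases -> {depth:.1f}x depth"
    )

# Each regime's survivors are a subset of the previous one: an undetermined
# '.' color always carries QV 0, so the qv10 filter is strictly the
# strictest.  The depth column is what an assembler would actually see.
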