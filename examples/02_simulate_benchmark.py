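"""Build a benchmark world: reference, annotations, and error-bearing scaffolds.

The generator plants a known roster of assembly errors and records every
one with exact coordinates — the truth table downstream stages are scored
against.
"""

from asmrecon.synthetic_data import (
    GenomeConfig,
    ScaffoldErrorConfig,
    simulate_genome,
    simulate_scaffolds,
)

genome = simulate_genome(GenomeConfig(seed=42))  # 8 x 200 kb, 160 genes
print(
    f"reference: {len(genome.chromosomes)} chromosomes, "
    f"{genome.genome_size / 1e6:.1f} Mb, {len(genome.genes)} genes"
)
for name, ids in genome.clusters.items():
    print(f"  {name}: {len(ids)} genes ({ids[0]} .. {ids[-1]})")

errors = ScaffoldErrorConfig(
    n_misjoin=4, n_inversion=2, n_deletion=3, n_insertion=3,
    n_small_deletion=2,          # below the 500 bp counting threshold
    small_indel_rate=1e-4,       # scattered 1-3 bp errors
    seed=7,
)
sim = simulate_scaffolds(genome, errors)
print(f"\nscaffolds: {len(sim.scaffolds)}, planted events:")
print(sim.truth.to_string(index=False))

# Rows with size <= 500 are the sub-threshold class: a correct
# misarrangement classifier must never report them.  The scaffold column
# says where each event physically ends up (misjoins move sequence between
# scaffolds).
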