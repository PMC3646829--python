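# Methods

This note documents the models, parameter choices and numerical details
behind `asmrecon`, and what its synthetic benchmarks do and do not show
about real data.

## Color-space model

SOLiD reads are modelled as a primer base plus a string of di-base
transition colors with per-color Phred-scaled quality values. The codec is
the XOR of 2-bit base codes (A=0, C=1, G=2, T=3); it is an involution in
the color domain, `decode(encode(s)) = s` for all ACGT strings, and color
0 occurs exactly where adjacent bases are equal. Undetermined calls
(`'.'`) cannot be decoded. Files pair a csfasta (primer + colors) with a
.qual (integers); records pair by order and id, and `#` comment lines are
skipped.

**Dot-QV convention.** File formats in the wild disagree on how a `'.'`
position is scored. Here it is always forced to QV 0 on read, which makes
every QV filter at least as strict as the no-dot filter and gives the
survivor-nesting invariant `qvN ⊆ nodot ⊆ all` unconditionally.

## Filtering regimes

- `nofilter`: identity.
- `nodot`: drop reads containing any `'.'`.
- `qv` with threshold *t* (default 10): drop reads whose minimum QV is not
  **strictly** above *t* — a read carrying a QV of exactly 10 fails the
  qv10 filter. This is the literal reading of "all bases above QV 10 /
  90 % accuracy"; accuracy is `1 − 10^(−QV/10)`.
- Pair rule: `both_pass` (default) drops a pair when either mate fails,
  since a pair with one bad mate contributes no usable mate-pair linkage
  to scaffolding; `independent` is available for ablation. Depth of
  coverage is `reads × read length / genome size`; any read subsampling is
  the caller's responsibility (a seeded binomial helper is provided).

## Alignment ("fragments")

Fragments are maximal local alignments of scaffold intervals to the
reference, scored with unit parameters (match +1, mismatch −1, gap open
−2, gap extend −1) and retained when score > 40. The threshold is the
package's significance floor for every downstream statistic.

Two implementations share the fragment contract:

- **Full affine Smith–Waterman** (Gotoh, with traceback) for problems up
  to ~0.26 Mcell (`dp_limit`). `N` never matches anything, itself
  included.
- **Anchor/chain/extend** for genome-scale inputs: exact 15-mers sampled
  every 10 bp against a sorted index (k-mers occurring > 32 times are
  skipped — this masks AT-rich centromeres, which chaining then bridges,
  the gap limit of 10 kb exceeding the 5 kb centromere), merged into
  exact segments on shared diagonals, greedily chained per chromosome and
  strand with ≤ 100 bp diagonal drift per join. Joins are filled with an
  edlib (edit-distance) alignment whose CIGAR supplies mismatch/indel
  detail; chain ends are extended while bases match exactly.

**Chain breaking.** A double-gapped join is a fragment boundary when its
score contribution is below −100 *or* its identity (matches over the
longer gap) is below 0.8 on gaps ≥ 200 bp. The identity test matters: an
edit-distance alignment across an inverted or foreign segment manufactures
enough spurious matches to hover near zero score while its identity sits
near random (~60 % for reverse-complemented sequence under edlib), so a
pure score test would absorb inversions into flanking fragments.

Diagonal drift (100 bp) is deliberately far below the 500 bp event
threshold: structural events break chains, scattered 1–3 bp indels do not.

**Primary fragments.** Repeats give a scaffold interval several reference
placements. For structure-sensitive analyses the maximum-score
non-overlapping subset per scaffold (weighted interval scheduling, 100 bp
overlap tolerance) is used; coverage and R50 use all retained fragments,
since interval union and per-fragment spans are insensitive to secondary
placements in the ways that matter.

Ties between equal-scoring placements resolve to the lowest chromosome
name, then lowest start; output order is deterministic.

## Statistics

`n50` is the largest `L` such that sequences of length ≥ `L` contain at
least half of all bases. (The common verbal definition "50 % of bases are
in scaffolds of length < N" is internally inconsistent at face value; the
standard cumulative convention is used and tested against a brute-force
oracle.) `ng50` thresholds against half the genome size and returns 0
when unreachable. `r50` is `ng50` over per-fragment reference spans with
the reference size as total; spans are **not** union-merged by default
(each fragment reports its own span), with a `merge=True` variant for
sensitivity analysis.

Coverage is the interval union of fragment reference spans. Length-class
coverage attributes each reference base to the longest fragment covering
it; classes split at 10 kb and 50 kb (a 10 000 bp fragment is in the
≤ 10 kb class), fractions plus uncovered sum to 1.

## Misarrangement classification

Events are detected between consecutive primary fragments of a scaffold
(per-junction counting; a per-scaffold misjoin count is also reported):

1. different reference chromosomes → misjoin;
2. strand flip: a fragment inverted against the scaffold's *dominant*
   orientation (majority by aligned bp — scaffold strandness is
   arbitrary) with locus-consistent neighbours counts once as an
   inversion of its span; junctions it participates in are consumed, so a
   flipped interior fragment is one inversion, not two misjoins, and a
   run of inversions does not make the sequence between them an event;
3. otherwise, with `d = ref_gap − scaffold_gap`: `|d| > 100 kb` →
   misjoin (the distance bound for same-chromosome rearrangements; no
   principled value exists, 100 kb is configurable and documented);
   `d > 500` → deletion of `d`; `−d > 500` → insertion of `−d`.

Events of extent ≤ 500 bp are never reported. Small indels are summed
from per-fragment alignment detail (inserted and deleted bases); the
gene-restricted variant masks indel positions by reference coordinate
against gene intervals, rather than re-aligning genes to scaffolds.

## Gene reconstruction and clusters

Genes (intron-inclusive nucleotide sequences) are searched against
scaffolds > 95 bp with the same aligner. Significance uses the ungapped
Karlin–Altschul form `E = K·m·n·e^(−λS)` with `λ = ln 3 ≈ 1.0986` and
`K = 0.621` for unit scoring at uniform composition (both configurable;
threshold behaviour at `E < 1e-100`, not absolute E-values, is what the
pipeline consumes — a qualifying HSP needs roughly 235 matched bases at
these sizes). For each gene, all qualifying HSPs from the single
best-scoring scaffold contribute; overlapping HSPs count once, and the
identity fraction is capped so `identity ≤ hsp ≤ 1` holds structurally.
Aggregates are base-weighted, not gene-weighted.

A cluster is continuous when all its genes have qualifying HSPs on one
shared scaffold, their midpoints are strictly monotone in cluster order
(global reversal allowed — scaffold orientation is arbitrary), and no
other evaluated gene's placement falls between them.

## Synthetic data

The generator reproduces the statistical structure the assessment assumes,
at roughly 1/23 linear scale (default 8 × 200 kb vs a 37 Mb fungal
genome) while keeping **all thresholds at their real values** (500 bp
events, 10/50 kb classes, 95 bp floor, E < 1e-100), so classification
logic runs unscaled:

- i.i.d. background at 48 % GC; a mid-chromosome 5 kb centromere at 85 %
  AT;
- genes of 0.8–1.8 kb packed without overlap; three default clusters
  mirroring real secondary-metabolite geometries (29 genes/73 kb,
  38 genes/75 kb, 3 genes/6 kb), in which every fifth gene is a
  PKS/NRPS-style member built from three ~2 %-mutated copies of a
  cluster-specific 900 bp unit (no repeat-family statistics exist for the
  reference organism; these defaults are the package's own choice);
- scaffolds derived from the chromosomes by planting an explicit event
  roster (counts per kind with a >500 bp size range, a sub-threshold
  class, per-bp 1–3 bp indels, N gap runs at misjoin junctions). Events
  are recorded by scanning the final block structure, so the truth table
  is exact by construction even when a misjoin relocates earlier events
  to another scaffold. Placement keeps events ≥ 2 kb apart and outside
  clusters and centromeres: planted events sit in unique flanking
  sequence (repeats and centromeres stress the aligner separately), which
  is the regime in which exact recovery is a fair contract;
- mate pairs: both mates from the same strand of a Gaussian-insert
  fragment (defaults 2764 ± 500 bp; an 1875 ± 400 bp companion library
  is predefined), truncated at twice the 50 bp read length; colors
  behind a T primer; per-color QV declining linearly along the read
  (30 → 22, σ 6, clipped to [0, 40]) — chosen to make the qv10 filter
  reject a substantial-but-not-degenerate fraction of reads; dot dropout
  at 1 % per color.

Everything is driven by one seeded generator per call; identical configs
give byte-identical outputs.

**What passing these benchmarks does not show.** The generator's genome
is i.i.d. apart from its planted structure: no transposon families, no
compositional heterogeneity beyond the centromere, no sequencing-error
model in color space beyond dot/QV dropout, and no assembler in the loop
— scaffolds are reference transformations, not de Bruijn graph output.
Exact event recovery here demonstrates the classifier and aligner are
correct, not that real assemblies would classify this cleanly; on real
data, repeat-mediated ambiguity and assembler-specific artifacts will
blur event boundaries.

## Problem sizes and runtime

The acceptance checks run the misarrangement benchmark on a 1 Mb genome
with 30 countable events (plus 6 sub-threshold), the identity pipeline on
a 500 kb genome, oracle comparisons on 1 000 random length multisets and
200 random sequence pairs ≤ 200 bp, and filter nesting on 10 000 reads —
sizes at which the whole script completes in well under a minute while
exercising every code path at real thresholds.

## Known limitations

- The built-in aligner is heuristic at genome scale: fragments shorter
  than ~40 bp of anchor support can be missed, and fragment boundaries
  are exact only up to the exact-extension rule. The Smith–Waterman
  route is exact but quadratic.
- E-values use ungapped Karlin–Altschul constants with gapped scoring; a
  calibrated gapped λ would shift absolute E-values (not the threshold
  behaviour the pipeline relies on).
- Misjoin counting is per junction; a single translocated block bounded
  by two junctions counts twice, which is the honest reading of
  junction-level evidence.
- `independent` pair filtering keeps the surviving mate but downstream
  consumers treat the pair as intact; orphan handling is bookkeeping
  only.
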