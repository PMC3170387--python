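# Methods

This note documents the models, conventions and numerical choices behind
`plastokit`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the simulation-based tests do and do not
demonstrate about real data.

## Genome model

A plastome is modelled as a circular quadripartite molecule
LSC + IRa + SSC + IRb with IRb *defined* as the reverse complement of IRa;
only LSC, IRa and SSC are stored, so the two repeats cannot drift apart.
Default segment proportions are 90 : 31 : 10 kb (LSC : IR : SSC), scaled
by a single `size_factor`; most tests and the acceptance script run at
`size_factor = 0.1` (16.2 kb total) so that a full pipeline run completes
in seconds while preserving the architecture (two identical repeats
flanking two single-copy regions, the feature that makes plastome assembly
non-trivial). A `size_factor` that would push any segment below 4× the
largest anchor k-mer (31) is rejected. Gene features are placed one per
evenly spaced slot with jittered start and codon-multiple length, giving a
deterministic, non-overlapping annotation.

## Divergence simulator

Evolution is applied to the single-copy molecule (LSC+IRa+SSC); the
derived IRb is rebuilt from the derived IRa, mirroring mutations between
repeats. Per ancestral site:

- **substitutions** are Bernoulli draws at `substitution_rate`; a
  substituted base becomes its transition partner with probability
  `R/(1+R)`, otherwise one of its two transversion partners uniformly, so
  the expected si/sv ratio equals `r_target`. This two-parameter scheme
  reproduces the summary statistics of interest (rate and R) without a
  full rate-matrix model; it does not model among-site rate variation or
  base-composition drift.
- **INDEL events** start per site at `indel_rate` with geometric lengths
  (`indel_mean_length`, default 40 nt); insertions and deletions are
  equally likely and events never overlap. For a target alignment INDEL
  ratio *t*, `EvolutionParams.with_indel_ratio_target` solves
  d·m = t/(1 − t/2) for the event rate, since each event of length ℓ
  contributes ℓ gap characters while only insertions add columns.
- `coding_rate_multiplier` (default 1.0) scales both rates inside gene
  features, reproducing the empirical pattern that coding regions diverge
  more slowly than intergenic ones.

Every realized mutation is logged on ancestor coordinates; replaying the
log reproduces the derived sequence exactly, and the log implies a
reference alignment against which the comparative module's estimates are
validated. Two presets bundle observed divergence levels between duckweed
plastomes: `intra-tribe` (5% substitutions, R 0.7, INDEL ratio 0.073) and
`inter-tribe` (7%, R 0.6, 0.089).

## Read simulator

Mate pairs emulate long-insert libraries from early short-read platforms:
~1.5 kb inserts (Normal, sd 150), two 50 nt tags per fragment,
outward-facing by default (the forward tag stored as the reverse
complement of the fragment prefix), configurable to inward. Reads are
plain base space with Phred-style QVs — colorspace encoding is platform
plumbing, not method content, and is deliberately not modelled. Fragments
are drawn from three compartments with probability proportional to copy
number × length (default 100 chloroplast and 10 mitochondrial copies per
nuclear copy; the nuclear compartment is a 100 kb random stand-in, far
smaller than a real plant nucleus but sufficient to contribute realistic
low-coverage contamination). Per-base QVs follow
clamp(Normal(28, 6), 2, 40) with an 8% fraction of low-quality reads
(mean 12) so the QV-20 filter has genuine work to do; sequencing errors
are uniform substitutions at `error_rate` (default 0.2%), independent of
QV. Hidden origin labels (compartment, fragment coordinates, strand) ride
along as ground truth for recall/precision and depth-ratio tests.

What the simulator does **not** emulate: colorspace error propagation,
GC-coverage bias, chimeric fragments, duplicated reads, heteroplasmy, and
real nuclear genomes' plastid-derived insertions (NUPTs). Tests passing on
this generator therefore demonstrate algorithmic correctness under clean
library statistics, not robustness to every artefact of a real run.

## Quality filter

Tags are truncated to a 40 nt prefix first, and the mean QV is computed on
that prefix; the threshold is strict (mean > 20). Prefix truncation was
chosen over best-window selection for determinism. A pair survives only if
both mates pass (`require_both_mates`), since downstream scaffolding needs
intact pairs. QV means are not rounded.

## Read mapper

Seed-and-extend, ungapped, end-to-end, both strands, mismatch budget
`max_mismatch_frac` × tag length (default 10% → 4 mismatches on a 40 nt
tag). Seeding uses the pigeonhole principle: the tag is cut into
(budget + 1) disjoint chunks — chunk length min(`seed_k`, ⌊L/(budget+1)⌋),
i.e. 8 nt at the defaults — so any qualifying placement has at least one
exact chunk and the mapper provably finds every hit a brute-force scan of
all offsets and strands would find (property-tested against exactly that
oracle). Ungapped extension means INDEL-containing reads are simply lost
to mapping, matching the behaviour of a default-parameter short-read
aligner on 40 nt tags; the reiteration pass recovers their information.
References are treated as linear. For coverage profiles, a read with
several equally valid placements (the two IRs) is assigned to one uniformly
at random under a fixed seed, so total placements are conserved while
repeat coverage splits between copies.

## Assembler

Contigs are maximal non-branching paths of a de Bruijn graph over
canonical k-mers (k odd, default 19, so no k-mer is its own reverse
complement). k-mers with multiplicity below `coverage_cutoff` (default 11)
are dropped before graph construction; dead-end paths shorter than 2k are
trimmed as tips and simple bubbles (two unitigs sharing both
neighbourhoods) collapse to the higher-coverage branch, for two rounds.
Contig mean k-mer coverage is re-checked against the cutoff. Mate pairs
are *not* used inside contig construction — only for scaffolding — keeping
the two stages independently testable.

Scaffolding maps each tag to the contig set; pairs whose tags map uniquely
to two different contigs vote for a junction between specific contig ends,
with the mate direction decoded from the library orientation convention.
Junctions need `min_pair_count` confirmations (default 120, appropriate to
the very deep coverage of real runs; scaled-down simulations use 5 — the
threshold scales with depth and is exposed in the parameters). Conflicts
resolve to the highest support with ties to the smaller contig id; cycles
break at their weakest junction. Gap lengths are estimated as the median
of insert-implied gaps, floored at zero. `expected_coverage` is recorded
for reporting but plays no role in construction.

## Ordering, gap closure, IR restoration

Scaffolds are split at their gap sentinels and every gap-free piece is
anchored to the reference by k-mers (k = 31) unique in both sequences,
chained by longest increasing subsequence; the better-scoring orientation
wins, and a piece whose two orientations tie — or that has no anchor — is
reported unplaced rather than guessed. Pieces are ordered by reference
midpoint and joined with exactly one `N` per junction. Neighbouring pieces
that overlap exactly (de Bruijn contigs sharing up to k−1 end bases, or
repeat-boundary spill-over) are merged seamlessly when a suffix–prefix
match of 12–200 nt is found. Splitting chimeric scaffolds falls out of
this design for free: the two sides of a mis-join re-anchor independently.

Gap closure locates each gap's flanks (windows of ≥ `min_overlap`,
default 100 nt) inside each finishing read by semi-global alignment
(edlib); a read matching both flanks in order donates the spanning
segment. When the read shows the two flanks *overlap* (negative gap), the
duplicated bases are trimmed instead. Every overlap column is tallied into
a discrepancy report — substitution mismatches and INDEL columns counted
separately, since a single combined figure would hide their different
causes. Non-gap columns of the pseudomolecule are never modified.

Reference coordinates (the single-copy start/end used to clip
repeat-derived spill-over, and the IRa boundaries used to rebuild IRb) are
transferred onto the assembly by aligning a 100 nt reference window
centred on the coordinate and walking the alignment columns; unlike
anchor-offset arithmetic this stays exact when an indel sits near the
boundary. IRb is then appended as revcomp(IRa) and the four junction
coordinates reported. An independent detector finds the longest inverted
repeat pair de novo (seed + maximal extension), used to excise IRb from
finished genomes without annotation.

## Comparative statistics

The genome aligner chains k-mers (k = 15) unique to and shared by both
sequences and fills inter-anchor segments with affine-gap global alignment
(match +1, mismatch −1, gap open −4, extend −1; declared defaults), with a
16M-cell bound on any single segment's DP. On small diverged pairs the
stitched alignment is property-tested to score identically to a
from-scratch quadratic Gotoh DP.

Counting conventions, chosen to match how plastome comparisons are
conventionally tabulated:

- substitution pairs are **unordered** (A→G and G→A pool into one
  transitional pair), since ancestral state is unknown in a pairwise
  comparison;
- **alignment length counts gap columns** — published whole-genome
  alignment lengths exceed the gap-free single-copy length, which is only
  consistent with gapped columns being counted;
- **INDEL length = total gap characters** across both rows (an event of
  length ℓ contributes ℓ);
- columns containing a gap, N or any ambiguity code are excluded from
  substitution counts (pairwise deletion) but kept in the alignment
  length;
- report rounding: rates to 2 decimals, R to 1, ratios to 3; unrounded
  values remain on the object. R is reported as infinite when sv = 0 with
  si > 0 and undefined (NaN) when there are no substitutions.

IRb is excluded before whole-genome comparison. Coding comparisons
concatenate gene features in genome order, reverse-complementing
minus-strand genes; overlapping annotations are both extracted, with a
warning.

## Phylogeny

With ≤ 9 taxa every unrooted binary topology is enumerated ((2n−5)!!,
15 for five taxa), so the parsimony search is exact and heuristics are
unnecessary; more taxa are refused rather than silently approximated.
Fitch scoring is vectorized over the distinct alignment columns with
multiplicities — the bootstrap then resamples column counts from a
multinomial, which is distribution-identical to resampling columns and
orders of magnitude cheaper at genome scale. Gaps and ambiguity codes are
treated as missing data (the full state set), never as a fifth state.
Bootstrap percentages are mapped onto the original best tree's
bipartitions; a replicate supports a bipartition only when it appears in
the strict consensus of the replicate's co-optimal trees (ties never
manufacture support). Character matrices for multiple genomes are built by
aligning each genome pairwise to a chosen backbone and projecting onto
backbone coordinates; columns inserted relative to the backbone are
dropped, a deliberate simplification of full multiple alignment. Outgroup
rooting places the root on the outgroup's pendant edge; the
basal-to-derived listing splits the smaller side first at every node
(cherries are unordered).

## Primer design

One pair per gap, scanned outward-in on 500 nt flanks: length 18–24 nt, Tm
by the Wallace rule 2(A+T) + 4(G+C) within 52–68 °C, no mononucleotide run
of ≥ 5. Gaps without compliant windows (including gaps within a flank
length of a molecule end) are flagged undesignable rather than forced.

## Problem sizes and determinism

The test suite and acceptance script run everything at reduced scale
chosen to keep a full run fast while leaving each statistic enough events
to be meaningful: plastomes at `size_factor` 0.1, 22k read pairs (~100×
chloroplast depth), 140 kb sequences for parameter recovery (≈ 7,000
substitution events), 200 matrices for the parsimony oracle, 1000
bootstrap replicates. All randomness flows through `numpy` Generators
seeded from a single integer, so every result is bit-reproducible.

## Known limitations

- The assembler is a clean-room de Bruijn implementation tuned for
  organelle-scale inputs; it is not a general-purpose assembler and makes
  no attempt at repeat resolution beyond the IR-aware pipeline structure.
- Mapping is ungapped; selection sensitivity decays for samples much more
  than ~10% diverged from the reference, where only the reiteration pass
  rescues reads.
- The comparative aligner's anchor-and-fill strategy can place gaps a few
  columns differently than an optimal full DP in low-complexity regions
  (scores are tested equal on small inputs, alignments need not be
  unique).
- Exhaustive parsimony caps at 9 taxa by design.
- SSC orientation is fixed in simulation; real plastomes exist as two
  SSC-orientation isomers.
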