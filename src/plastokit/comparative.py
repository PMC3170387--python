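"""Pairwise whole-genome divergence: anchored global alignment,
substitution classification, si/sv ratio, and INDEL statistics.

The aligner finds k-mers unique to and shared by both genomes, chains
them collinearly, and fills the inter-anchor segments with an affine-gap
global alignment; the concatenation is a full-length pairwise alignment.
Divergence statistics follow the standard plastome-comparison
conventions: substitutions are counted as unordered base pairs — A<->G
and C<->T are the two transitional pairs (si), the other four pairs are
transversional (sv), R = si/sv — the substitution rate is substitutions
per alignment column (gap columns included), and the INDEL ratio is
total gap characters over alignment columns. One inverted repeat (IRb)
is excluded before whole-genome comparison so the repeated sequence is
not double-counted.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .finishing import _lis_chain, _unique_kmer_positions, detect_inverted_repeat
from .sequences import is_transition, revcomp
from .simulate import Feature, PlastomeModel

#: affine-gap scores for inter-anchor global alignment
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -4, -1

#: refuse quadratic DP above this cell count for a single segment
DP_CELL_BOUND = 16_000_000


@dataclass
class PairwiseAlignment:
    """Two gapped rows of equal length; stripping gaps recovers the inputs."""

    row_a: str
    row_b: str

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("aligned rows differ in length")

    def __len__(self):
        return len(self.row_a)


@dataclass
class PairwiseDivergence:
    """Alignment-derived divergence statistics for one genome pair."""

    alignment_length: int
    substitutions: int
    si: int
    sv: int
    indels_length: int

    @property
    def r(self) -> float:
        """R = si/sv; inf when sv = 0 with si > 0, nan when both are 0."""
        if self.sv == 0:
            return math.inf if self.si > 0 else math.nan
        return self.si / self.sv

    @property
    def substitution_rate(self) -> float:
        return self.substitutions / self.alignment_length

    @property
    def indel_ratio(self) -> float:
        return self.indels_length / self.alignment_length

    def report_row(self, pair: str = ".", rate_decimals: int = 2,
                   ratio_decimals: int = 3) -> dict:
        """Rounded report row (rates to 2 decimals, ratios to 3, as
        conventionally printed); unrounded values stay on the object."""
        r = self.r
        return {
            "pair": pair,
            "alignment_length": self.alignment_length,
            "substitution_rate": round(self.substitution_rate, rate_decimals),
            "R": (round(r, 1) if math.isfinite(r) else "NA"),
            "indels_length": self.indels_length,
            "indel_ratio": round(self.indel_ratio, ratio_decimals),
        }


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global")
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _align_segment(a: str, b: str, aligner: Align.PairwiseAligner) -> tuple[str, str]:
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    if len(a) * len(b) > DP_CELL_BOUND:
        raise ValueError(
            f"inter-anchor segment too large for quadratic alignment "
            f"({len(a)} x {len(b)}); use smaller inputs or a smaller anchor k"
        )
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_genome_align(
    seq_a: str, seq_b: str, anchor_k: int = 15
) -> PairwiseAlignment:
    """Anchored global alignment of two genome-scale sequences."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner()
    pos_a = _unique_kmer_positions(seq_a, anchor_k)
    pos_b = _unique_kmer_positions(seq_b, anchor_k)
    matches = [(pa, pos_b[km]) for km, pa in pos_a.items() if km in pos_b]
    chain = _lis_chain(matches) if matches else []
    # drop anchors overlapping their predecessor on either sequence
    anchors: list[tuple[int, int]] = []
    last_a = last_b = -anchor_k
    for pa, pb in chain:
        if pa >= last_a + anchor_k and pb >= last_b + anchor_k:
            anchors.append((pa, pb))
            last_a, last_b = pa, pb
    rows_a: list[str] = []
    rows_b: list[str] = []
    ca = cb = 0
    for pa, pb in anchors:
        ra, rb = _align_segment(seq_a[ca:pa], seq_b[cb:pb], aligner)
        rows_a.append(ra)
        rows_b.append(rb)
        rows_a.append(seq_a[pa : pa + anchor_k])
        rows_b.append(seq_b[pb : pb + anchor_k])
        ca, cb = pa + anchor_k, pb + anchor_k
    ra, rb = _align_segment(seq_a[ca:], seq_b[cb:], aligner)
    rows_a.append(ra)
    rows_b.append(rb)
    return PairwiseAlignment("".join(rows_a), "".join(rows_b))


def exclude_irb(
    genome: PlastomeModel | str,
    irb_span: tuple[int, int] | None = None,
) -> str:
    """Return the LSC+IRa+SSC portion of a full plastome.

    Accepts a PlastomeModel (span known by construction), or a raw
    sequence with an annotated IRb span, or a raw sequence alone, in which
    case the repeat pair is detected de novo.
    """
    if isinstance(genome, PlastomeModel):
        return genome.single_copy
    if irb_span is None:
        _, irb_span = detect_inverted_repeat(genome)
    s, e = irb_span
    return genome[:s] + genome[e:]


def concatenate_coding(
    genome: str, features: Sequence[Feature]
) -> tuple[str, int]:
    """Concatenate gene features in genome order (minus-strand genes
    reverse-complemented). Returns (sequence, gene count)."""
    genes = sorted((f for f in features if f.kind == "gene"), key=lambda f: f.start)
    for f, g in zip(genes, genes[1:]):
        if g.start < f.end:
            warnings.warn(f"overlapping gene features {f.name}/{g.name}; "
                          "both extracted as annotated")
    parts = []
    for f in genes:
        seg = genome[f.start : f.end]
        parts.append(seg if f.strand == "+" else revcomp(seg))
    return "".join(parts), len(genes)


def divergence_stats(alignment: PairwiseAlignment) -> PairwiseDivergence:
    """Classify every alignment column and tally divergence statistics.

    Gap characters count toward ``indels_length`` and the alignment
    length; columns containing a gap, N, or any ambiguity code never
    contribute to the substitution counts.
    """
    si = sv = subs = gaps = 0
    acgt = frozenset("ACGT")
    for x, y in zip(alignment.row_a, alignment.row_b):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x not in acgt or y not in acgt:
            continue  # ambiguity treated as missing
        if x != y:
            subs += 1
            if is_transition(x, y):
                si += 1
            else:
                sv += 1
    return PairwiseDivergence(
        alignment_length=len(alignment),
        substitutions=subs,
        si=si,
        sv=sv,
        indels_length=gaps,
    )


def compare_genomes(
    seq_a: str, seq_b: str, anchor_k: int = 15
) -> PairwiseDivergence:
    """Convenience: align two (IRb-excluded) genomes and compute stats."""
    return divergence_stats(pairwise_genome_align(seq_a, seq_b, anchor_k))


def identity_windows(alignment: PairwiseAlignment, window: int = 100) -> list[tuple[int, float]]:
    """Per-window fraction of identical columns (plain-text conservation
    profile; the rendered-plot analogue is out of scope)."""
    out = []
    n = len(alignment)
    for start in range(0, n, window):
        cols = zip(alignment.row_a[start : start + window],
                   alignment.row_b[start : start + window])
        pairs = [(x, y) for x, y in cols]
        if not pairs:
            continue
        ident = sum(1 for x, y in pairs if x == y and x != "-")
        out.append((start, ident / len(pairs)))
    return out
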