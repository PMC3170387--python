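"""Synthetic plastomes, evolved relatives, and total-DNA mate-pair libraries.

The simulator provides ground truth for every downstream stage of the
pipeline: a quadripartite chloroplast genome model (LSC + IRa + SSC + IRb,
with IRb always the reverse complement of IRa), a sequence-evolution engine
with a controllable transition/transversion mix and INDEL load, and a
whole-cell DNA read simulator in which chloroplast fragments are
over-represented relative to nuclear and mitochondrial fragments, as they
are in unfractionated total-DNA libraries.

Mate pairs follow the long-insert convention of early SOLiD libraries:
~1.5 kb inserts, 50 nt tags, outward-facing by default (configurable).
Reads are plain base space with Phred-style quality values; colorspace
encoding is deliberately not modelled.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

from .sequences import BASES, random_dna, revcomp

# ---------------------------------------------------------------------------
# Plastome model
# ---------------------------------------------------------------------------

#: canonical segment proportions of the quadripartite architecture
#: (large single copy : inverted repeat : small single copy), in kilobases
SEGMENT_KB = {"LSC": 90, "IR": 31, "SSC": 10}

#: largest k-mer used anywhere in the toolkit (collinearity anchors);
#: a simulated segment must be at least 4x this long to be usable
MAX_K = 31


class Feature(NamedTuple):
    """Annotation interval on the full circular sequence (0-based, half-open)."""

    name: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str  # 'gene' | 'intron' | 'intergenic'


@dataclass(frozen=True)
class PlastomeModel:
    """Circular quadripartite plastome: LSC + IRa + SSC + IRb.

    Only LSC, IRa and SSC are stored; IRb is derived as the reverse
    complement of IRa, so the two repeats can never drift apart.
    """

    seq_lsc: str
    seq_ira: str
    seq_ssc: str
    features: tuple[Feature, ...] = ()
    circular: bool = True

    @property
    def seq_irb(self) -> str:
        return revcomp(self.seq_ira)

    @property
    def sequence(self) -> str:
        """Full circular sequence LSC + IRa + SSC + IRb."""
        return self.seq_lsc + self.seq_ira + self.seq_ssc + self.seq_irb

    @property
    def single_copy(self) -> str:
        """LSC + IRa + SSC, i.e. the genome with IRb excluded."""
        return self.seq_lsc + self.seq_ira + self.seq_ssc

    @property
    def ira_span(self) -> tuple[int, int]:
        s = len(self.seq_lsc)
        return s, s + len(self.seq_ira)

    @property
    def irb_span(self) -> tuple[int, int]:
        s = len(self.seq_lsc) + len(self.seq_ira) + len(self.seq_ssc)
        return s, s + len(self.seq_ira)

    def __len__(self) -> int:
        return len(self.seq_lsc) + 2 * len(self.seq_ira) + len(self.seq_ssc)

    def __post_init__(self):
        end = len(self)
        for f in self.features:
            if not (0 <= f.start < f.end <= end):
                raise ValueError(f"feature {f.name} outside sequence bounds")


def simulate_plastome(
    size_factor: float = 1.0,
    gene_count: int = 60,
    seed: int = 0,
    gc: float = 0.37,
) -> PlastomeModel:
    """Simulate a quadripartite plastome.

    Segment lengths are (90, 31, 10) kb scaled by ``size_factor``;
    ``gene_count`` non-overlapping gene features are placed across
    LSC, IRa and SSC. Deterministic per seed.
    """
    if size_factor <= 0:
        raise ValueError("size_factor must be positive")
    if gene_count < 0:
        raise ValueError("gene_count must be >= 0")
    lengths = {k: round(v * 1000 * size_factor) for k, v in SEGMENT_KB.items()}
    if min(lengths.values()) < 4 * MAX_K:
        raise ValueError(
            f"size_factor {size_factor} makes a segment shorter than "
            f"{4 * MAX_K} nt (4x the largest k-mer in use)"
        )
    rng = np.random.default_rng(seed)
    lsc = random_dna(lengths["LSC"], rng, gc)
    ira = random_dna(lengths["IR"], rng, gc)
    ssc = random_dna(lengths["SSC"], rng, gc)

    # place genes without overlap inside the single-copy portion + IRa:
    # one gene per evenly spaced slot, with jittered start and length
    sc_len = lengths["LSC"] + lengths["IR"] + lengths["SSC"]
    features: list[Feature] = []
    if gene_count:
        slot = sc_len // gene_count
        for i in range(gene_count):
            max_len = max(90, min(1200, int(0.7 * slot)))
            glen = 3 * int(rng.integers(30, max_len // 3 + 1))
            start = i * slot + int(rng.integers(0, max(1, slot - glen)))
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(f"gene{i + 1:03d}", start, start + glen, strand, "gene")
            )
    return PlastomeModel(lsc, ira, ssc, tuple(features))


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


class MutationEvent(NamedTuple):
    """One mutation on ancestor coordinates.

    ``position`` indexes the ancestor. Substitutions replace one base;
    deletions remove ``ancestral`` starting at ``position``; insertions add
    ``derived`` immediately *before* ``position``.
    """

    position: int
    kind: str  # 'substitution' | 'insertion' | 'deletion'
    ancestral: str
    derived: str


@dataclass
class MutationEventLog:
    """Ordered mutation events; replaying them on the ancestor reproduces
    the derived sequence exactly."""

    events: list[MutationEvent] = field(default_factory=list)

    def __len__(self):
        return len(self.events)

    def counts(self) -> dict[str, int]:
        c = {"substitution": 0, "insertion": 0, "deletion": 0}
        for e in self.events:
            c[e.kind] += 1
        return c

    @property
    def n_substitutions(self) -> int:
        return self.counts()["substitution"]

    @property
    def indel_length(self) -> int:
        """Total bases inserted plus bases deleted (gap columns implied)."""
        return sum(
            len(e.ancestral) + len(e.derived)
            for e in self.events
            if e.kind in ("insertion", "deletion")
        )

    def si_sv(self) -> tuple[int, int]:
        """Realized transition / transversion substitution counts."""
        from .sequences import is_transition

        si = sv = 0
        for e in self.events:
            if e.kind == "substitution":
                if is_transition(e.ancestral, e.derived):
                    si += 1
                else:
                    sv += 1
        return si, sv


def replay_log(ancestor: str, log: MutationEventLog) -> str:
    """Apply a mutation log to the ancestor, reproducing the derived sequence."""
    out: list[str] = []
    cur = 0
    for e in sorted(log.events, key=lambda e: (e.position, e.kind != "insertion")):
        out.append(ancestor[cur : e.position])
        cur = e.position
        if e.kind == "substitution":
            if ancestor[cur] != e.ancestral:
                raise ValueError("log does not match ancestor")
            out.append(e.derived)
            cur += 1
        elif e.kind == "deletion":
            if ancestor[cur : cur + len(e.ancestral)] != e.ancestral:
                raise ValueError("log does not match ancestor")
            cur += len(e.ancestral)
        else:  # insertion
            out.append(e.derived)
    out.append(ancestor[cur:])
    return "".join(out)


def log_to_alignment(ancestor: str, log: MutationEventLog) -> tuple[str, str]:
    """Gapped (ancestor_row, derived_row) alignment implied by the log."""
    row_a: list[str] = []
    row_b: list[str] = []
    cur = 0
    for e in sorted(log.events, key=lambda e: (e.position, e.kind != "insertion")):
        row_a.append(ancestor[cur : e.position])
        row_b.append(ancestor[cur : e.position])
        cur = e.position
        if e.kind == "substitution":
            row_a.append(e.ancestral)
            row_b.append(e.derived)
            cur += 1
        elif e.kind == "deletion":
            row_a.append(e.ancestral)
            row_b.append("-" * len(e.ancestral))
            cur += len(e.ancestral)
        else:
            row_a.append("-" * len(e.derived))
            row_b.append(e.derived)
    row_a.append(ancestor[cur:])
    row_b.append(ancestor[cur:])
    return "".join(row_a), "".join(row_b)


def map_coordinate(log: MutationEventLog, pos: int) -> int:
    """Lift an ancestor coordinate to the derived sequence."""
    offset = 0
    for e in sorted(log.events, key=lambda e: e.position):
        if e.position >= pos:
            break
        if e.kind == "insertion":
            offset += len(e.derived)
        elif e.kind == "deletion":
            del_end = e.position + len(e.ancestral)
            offset -= min(del_end, pos) - e.position
    return pos + offset


@dataclass(frozen=True)
class EvolutionParams:
    """Parameters of the divergence simulator.

    substitution_rate
        Expected substitutions per ancestral site.
    r_target
        Target transition/transversion ratio R = si/sv. A substituted site
        receives a transition with probability R/(1+R), else one of its two
        transversion partners, so E[si/sv] = R.
    indel_rate
        Expected INDEL *events* per ancestral site (insertions and
        deletions equally likely).
    indel_mean_length
        Mean of the geometric length distribution of INDEL events.
    coding_rate_multiplier
        Factor in (0, 1] applied to both rates inside features of kind
        'gene' (coding sequence evolves more slowly).
    """

    substitution_rate: float = 0.05
    r_target: float = 0.7
    indel_rate: float = 0.0
    indel_mean_length: float = 40.0
    coding_rate_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.r_target <= 0:
            raise ValueError("r_target must be > 0")
        if not (0 < self.coding_rate_multiplier <= 1):
            raise ValueError("coding_rate_multiplier must be in (0, 1]")
        if self.indel_rate > 0 and self.indel_mean_length < 1:
            raise ValueError("indel length distribution needs positive support")

    @classmethod
    def with_indel_ratio_target(
        cls, indel_ratio: float, indel_mean_length: float = 40.0, **kw
    ) -> "EvolutionParams":
        """Choose ``indel_rate`` so the expected alignment INDEL ratio
        (gap characters / alignment columns) matches ``indel_ratio``.

        With event rate d and mean length m, a pairwise alignment of the
        ancestor and the derived sequence has ~L*d*m gap characters over
        ~L*(1 + d*m/2) columns, so d = t / (m * (1 - t/2)) for target t.
        """
        d = indel_ratio / (indel_mean_length * (1 - indel_ratio / 2))
        return cls(indel_rate=d, indel_mean_length=indel_mean_length, **kw)


#: divergence presets mirroring observed whole-genome pairwise levels
#: between duckweed plastomes: same-tribe pairs run at ~5% substitutions
#: with R ~ 0.7 and INDEL ratio ~ 0.073; cross-tribe pairs at ~7% with
#: R ~ 0.6 and INDEL ratio ~ 0.089.
def divergence_preset(name: str, seed: int = 0) -> EvolutionParams:
    presets = {
        "intra-tribe": dict(substitution_rate=0.05, r_target=0.7, indel_ratio=0.073),
        "inter-tribe": dict(substitution_rate=0.07, r_target=0.6, indel_ratio=0.089),
    }
    p = presets[name]
    return EvolutionParams.with_indel_ratio_target(
        p["indel_ratio"],
        substitution_rate=p["substitution_rate"],
        r_target=p["r_target"],
        seed=seed,
    )


_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def _coding_mask(length: int, features: Sequence[Feature], offset: int = 0) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for f in features:
        if f.kind == "gene":
            s = max(0, f.start - offset)
            e = min(length, f.end - offset)
            if s < e:
                mask[s:e] = True
    return mask


def evolve_sequence(
    ancestor: str,
    params: EvolutionParams,
    rng: np.random.Generator | None = None,
    features: Sequence[Feature] = (),
    feature_offset: int = 0,
) -> tuple[str, MutationEventLog]:
    """Evolve a linear sequence; return the derived sequence and event log.

    Substitutions are per-site Bernoulli draws; the substitution type is a
    transition with probability r_target/(1+r_target). INDEL events start
    per-site Bernoulli; lengths are geometric with the configured mean;
    insertions and deletions are equally likely. Events never overlap.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L = len(ancestor)
    if L == 0:
        raise ValueError("ancestor must be non-empty")
    events: list[MutationEvent] = []
    if params.substitution_rate == 0 and params.indel_rate == 0:
        return ancestor, MutationEventLog([])

    coding = _coding_mask(L, features, feature_offset)
    rate_scale = np.where(coding, params.coding_rate_multiplier, 1.0)

    # INDEL starts first; substitutions then avoid deleted sites.
    deleted = np.zeros(L, dtype=bool)
    if params.indel_rate > 0:
        starts = np.flatnonzero(rng.random(L) < params.indel_rate * rate_scale)
        # geometric with mean m: p = 1/m, support {1, 2, ...}
        p_geom = 1.0 / params.indel_mean_length
        next_free = 0
        for pos in starts:
            pos = int(pos)
            if pos < next_free:
                continue  # would overlap the previous deletion
            length = int(rng.geometric(p_geom))
            if rng.random() < 0.5:  # deletion
                length = min(length, L - pos)
                if length == 0:
                    continue
                events.append(
                    MutationEvent(pos, "deletion", ancestor[pos : pos + length], "")
                )
                deleted[pos : pos + length] = True
                next_free = pos + length
            else:  # insertion before pos
                ins = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
                events.append(MutationEvent(pos, "insertion", "", ins))
                next_free = pos

    p_ti = params.r_target / (1.0 + params.r_target)
    sub_sites = np.flatnonzero(
        (rng.random(L) < params.substitution_rate * rate_scale) & ~deleted
    )
    for pos in sub_sites:
        pos = int(pos)
        a = ancestor[pos]
        if a not in _TRANSITION_OF:
            continue
        if rng.random() < p_ti:
            d = _TRANSITION_OF[a]
        else:
            d = _TRANSVERSIONS_OF[a][int(rng.integers(0, 2))]
        events.append(MutationEvent(pos, "substitution", a, d))

    events.sort(key=lambda e: (e.position, e.kind != "insertion"))
    log = MutationEventLog(events)
    return replay_log(ancestor, log), log


def evolve_genome(
    ancestor: PlastomeModel, params: EvolutionParams
) -> tuple[PlastomeModel, MutationEventLog]:
    """Evolve a plastome, mirroring IRa mutations into IRb.

    The three stored segments (LSC, IRa, SSC) are evolved as one
    concatenated sequence so the event log uses single-copy coordinates;
    IRb of the derived genome is rebuilt as revcomp(derived IRa), keeping
    the two repeats identical. Feature coordinates are lifted through the
    log so derived annotations stay consistent.
    """
    rng = np.random.default_rng(params.seed)
    sc = ancestor.single_copy
    derived_sc, log = evolve_sequence(sc, params, rng, ancestor.features)

    lsc_end = len(ancestor.seq_lsc)
    ira_end = lsc_end + len(ancestor.seq_ira)
    d_lsc_end = map_coordinate(log, lsc_end)
    d_ira_end = map_coordinate(log, ira_end)
    new_lsc = derived_sc[:d_lsc_end]
    new_ira = derived_sc[d_lsc_end:d_ira_end]
    new_ssc = derived_sc[d_ira_end:]

    new_features = []
    sc_len = len(sc)
    for f in ancestor.features:
        if f.end > sc_len:
            continue  # features inside IRb are implied by the IRa copy
        s, e = map_coordinate(log, f.start), map_coordinate(log, f.end)
        if e > s:
            new_features.append(Feature(f.name, s, e, f.strand, f.kind))
    derived = PlastomeModel(new_lsc, new_ira, new_ssc, tuple(new_features))
    return derived, log


# ---------------------------------------------------------------------------
# Total-DNA mate-pair library simulation
# ---------------------------------------------------------------------------


class Read(NamedTuple):
    """One sequencing tag: sequence plus per-base Phred quality values."""

    seq: str
    qv: np.ndarray


class Origin(NamedTuple):
    """Hidden truth for a simulated pair (compartment + fragment layout)."""

    compartment: str  # 'chloroplast' | 'nuclear' | 'mitochondrial'
    start: int  # fragment start on the source (forward strand coords)
    length: int  # fragment length
    strand: str  # strand the fragment was drawn from


@dataclass
class ReadPair:
    tag_f: Read
    tag_r: Read
    origin: Origin | None = None


@dataclass
class MatePairLibrary:
    """A collection of mate pairs plus the library parameters."""

    pairs: list[ReadPair]
    tag_length: int = 50
    insert_mean: float = 1500.0
    insert_sd: float = 150.0
    orientation: Literal["outward", "inward"] = "outward"

    def __post_init__(self):
        if self.insert_mean <= 2 * self.tag_length:
            raise ValueError("insert_mean must exceed 2 x tag_length")
        for p in self.pairs:
            for t in (p.tag_f, p.tag_r):
                if len(t.seq) != len(t.qv):
                    raise ValueError("sequence and QV arrays differ in length")

    def __len__(self):
        return len(self.pairs)

    def tags(self) -> Iterable[str]:
        for p in self.pairs:
            yield p.tag_f.seq
            yield p.tag_r.seq


@dataclass(frozen=True)
class QVModel:
    """Per-base quality model: QV ~ clamp(Normal(mu, sigma), lo, hi), with a
    configurable fraction of low-quality reads (mu = bad_mu) so that a
    mean-QV filter has genuine work to do."""

    mu: float = 28.0
    sigma: float = 6.0
    lo: int = 2
    hi: int = 40
    bad_fraction: float = 0.08
    bad_mu: float = 12.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mu = self.bad_mu if rng.random() < self.bad_fraction else self.mu
        q = np.clip(np.rint(rng.normal(mu, self.sigma, size=n)), self.lo, self.hi)
        return q.astype(np.int16)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    mask = rng.random(len(seq)) < error_rate
    if not mask.any():
        return seq
    out = list(seq)
    for i in np.flatnonzero(mask):
        b = out[i]
        choices = [c for c in BASES if c != b]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def simulate_total_dna_library(
    plastome: PlastomeModel,
    nuclear_size: int = 100_000,
    mito_size: int = 30_000,
    copy_ratio_chl_per_nuclear: float = 100.0,
    mito_copies_per_nuclear: float = 10.0,
    n_pairs: int = 10_000,
    tag_length: int = 50,
    insert_mean: float = 1500.0,
    insert_sd: float = 150.0,
    error_rate: float = 0.002,
    qv_model: QVModel | None = None,
    orientation: Literal["outward", "inward"] = "outward",
    seed: int = 0,
) -> MatePairLibrary:
    """Simulate a mate-pair library from unfractionated total DNA.

    Fragments are drawn from the chloroplast, nuclear and mitochondrial
    compartments with probability proportional to copy number x compartment
    length; the chloroplast is heavily over-represented (default 100 genome
    copies per nuclear copy). Each fragment of ~Normal(insert_mean,
    insert_sd) length yields two ``tag_length`` tags; with the default
    'outward' convention the forward tag is the reverse complement of the
    fragment prefix and the reverse tag is the fragment suffix.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    for name, size in (("nuclear", nuclear_size), ("mitochondrial", mito_size)):
        if size <= insert_mean:
            raise ValueError(f"{name} compartment smaller than insert_mean")
    if len(plastome) <= insert_mean:
        raise ValueError("plastome smaller than insert_mean")
    rng = np.random.default_rng(seed)
    qv_model = qv_model or QVModel()

    chl = plastome.sequence
    nuc = random_dna(nuclear_size, rng)
    mito = random_dna(mito_size, rng)
    sources = {
        "chloroplast": (chl, True),
        "nuclear": (nuc, False),
        "mitochondrial": (mito, True),
    }
    weights = np.array(
        [
            copy_ratio_chl_per_nuclear * len(chl),
            1.0 * nuclear_size,
            mito_copies_per_nuclear * mito_size,
        ]
    )
    probs = weights / weights.sum()
    names = list(sources)

    min_len = 2 * tag_length + 10
    pairs: list[ReadPair] = []
    comp_idx = rng.choice(3, size=n_pairs, p=probs)
    for ci in comp_idx:
        comp = names[int(ci)]
        src, circular = sources[comp]
        frag_len = max(min_len, int(round(rng.normal(insert_mean, insert_sd))))
        frag_len = min(frag_len, len(src))
        if circular:
            start = int(rng.integers(0, len(src)))
            frag = (src + src)[start : start + frag_len]
        else:
            start = int(rng.integers(0, len(src) - frag_len + 1))
            frag = src[start : start + frag_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        if orientation == "outward":
            t1, t2 = revcomp(frag[:tag_length]), frag[-tag_length:]
        else:
            t1, t2 = frag[:tag_length], revcomp(frag[-tag_length:])
        t1 = _apply_errors(t1, error_rate, rng)
        t2 = _apply_errors(t2, error_rate, rng)
        pairs.append(
            ReadPair(
                Read(t1, qv_model.draw(tag_length, rng)),
                Read(t2, qv_model.draw(tag_length, rng)),
                Origin(comp, start, frag_len, strand),
            )
        )
    return MatePairLibrary(pairs, tag_length, insert_mean, insert_sd, orientation)


def simulate_mate_pair_library(
    source: str,
    n_pairs: int,
    tag_length: int = 50,
    insert_mean: float = 1500.0,
    insert_sd: float = 150.0,
    error_rate: float = 0.0,
    qv_model: QVModel | None = None,
    orientation: Literal["outward", "inward"] = "outward",
    circular: bool = False,
    seed: int = 0,
) -> MatePairLibrary:
    """Mate pairs from a single source sequence (no compartment mixture).

    Origins are recorded with compartment ``'source'`` so fragment layouts
    remain available as ground truth.
    """
    if len(source) <= insert_mean:
        raise ValueError("source shorter than insert_mean")
    rng = np.random.default_rng(seed)
    qv_model = qv_model or QVModel(bad_fraction=0.0)
    min_len = 2 * tag_length + 10
    pairs: list[ReadPair] = []
    for _ in range(n_pairs):
        frag_len = max(min_len, int(round(rng.normal(insert_mean, insert_sd))))
        frag_len = min(frag_len, len(source))
        if circular:
            start = int(rng.integers(0, len(source)))
            frag = (source + source)[start : start + frag_len]
        else:
            start = int(rng.integers(0, len(source) - frag_len + 1))
            frag = source[start : start + frag_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        if orientation == "outward":
            t1, t2 = revcomp(frag[:tag_length]), frag[-tag_length:]
        else:
            t1, t2 = frag[:tag_length], revcomp(frag[-tag_length:])
        t1 = _apply_errors(t1, error_rate, rng)
        t2 = _apply_errors(t2, error_rate, rng)
        pairs.append(
            ReadPair(
                Read(t1, qv_model.draw(tag_length, rng)),
                Read(t2, qv_model.draw(tag_length, rng)),
                Origin("source", start, frag_len, strand),
            )
        )
    return MatePairLibrary(pairs, tag_length, insert_mean, insert_sd, orientation)


def simulate_finishing_reads(
    truth: str,
    read_length: int = 800,
    step: int = 400,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Long 'finishing' reads tiling the truth sequence (CE-read stand-ins).

    Reads of ``read_length`` start every ``step`` bases, so any short gap in
    an assembly is spanned with generous flanks on both sides.
    """
    rng = np.random.default_rng(seed)
    reads = []
    i = 0
    n = 0
    while i < len(truth):
        seq = truth[i : i + read_length]
        if len(seq) >= 100:
            reads.append((f"fin{n:04d}", _apply_errors(seq, error_rate, rng)))
            n += 1
        i += step
    return reads


# ---------------------------------------------------------------------------
# File output (FASTQ pair, truth FASTA/GFF3, event-log TSV)
# ---------------------------------------------------------------------------


def write_fastq_pair(library: MatePairLibrary, path_f, path_r, prefix: str = "pair"):
    """Write the two tags of every pair to /1 and /2 FASTQ files."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    def records(which: int):
        for i, p in enumerate(library.pairs):
            tag = p.tag_f if which == 1 else p.tag_r
            rec = SeqRecord(Seq(tag.seq), id=f"{prefix}{i:07d}/{which}", description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in tag.qv]
            yield rec

    SeqIO.write(records(1), path_f, "fastq")
    SeqIO.write(records(2), path_r, "fastq")


def read_fastq_pair(path_f, path_r, **library_kw) -> MatePairLibrary:
    """Load a mate-pair library from /1 and /2 FASTQ files."""
    from Bio import SeqIO

    pairs = []
    for r1, r2 in zip(SeqIO.parse(path_f, "fastq"), SeqIO.parse(path_r, "fastq")):
        pairs.append(
            ReadPair(
                Read(str(r1.seq), np.array(r1.letter_annotations["phred_quality"])),
                Read(str(r2.seq), np.array(r2.letter_annotations["phred_quality"])),
            )
        )
    tag_len = len(pairs[0].tag_f.seq) if pairs else library_kw.pop("tag_length", 50)
    library_kw.setdefault("tag_length", tag_len)
    return MatePairLibrary(pairs, **library_kw)


def write_truth(plastome: PlastomeModel, fasta_path, gff_path, name: str = "plastome"):
    """Write the full sequence as FASTA and its features as GFF3."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{name} circular quadripartite plastome\n")
        seq = plastome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {name} 1 {len(plastome)}\n")
        for f in plastome.features:
            fh.write(
                f"{name}\tplastokit\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.name}\n"
            )
        a0, a1 = plastome.ira_span
        b0, b1 = plastome.irb_span
        fh.write(f"{name}\tplastokit\trepeat_region\t{a0 + 1}\t{a1}\t.\t+\t.\tID=IRa\n")
        fh.write(f"{name}\tplastokit\trepeat_region\t{b0 + 1}\t{b1}\t.\t-\t.\tID=IRb\n")


def write_event_log(log: MutationEventLog, path):
    with open(path, "w") as fh:
        fh.write("position\tkind\tancestral\tderived\n")
        for e in log.events:
            fh.write(f"{e.position}\t{e.kind}\t{e.ancestral}\t{e.derived}\n")
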