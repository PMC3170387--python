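"""De novo assembly: de Bruijn contigs and mate-pair scaffolding.

Contigs are maximal non-branching paths of a de Bruijn graph over
canonical k-mers (k odd so no k-mer is its own reverse complement).
k-mers below the coverage cutoff are discarded before graph construction;
short dead-end paths (tips, < 2k nt) are trimmed and simple bubbles are
popped in favour of the higher-coverage branch — the standard hygiene of
short-read assemblers.

Scaffolding joins contigs using mate pairs whose two tags land on
different contigs in a compatible orientation; a junction needs at least
``min_pair_count`` supporting pairs (the default 120 matches deep
sequencing runs and is meant to be scaled down with coverage).
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .mapping import MapperParams, ReferenceIndex
from .sequences import BASES, canonical, revcomp
from .simulate import MatePairLibrary


@dataclass(frozen=True)
class AssemblyParams:
    hash_length: int = 19  # odd k
    coverage_cutoff: int = 11  # min k-mer multiplicity (and contig mean)
    min_pair_count: int = 120  # mate-pair confirmations per junction
    expected_coverage: float = 150.0  # informational only

    def __post_init__(self):
        if self.hash_length < 11 or self.hash_length % 2 == 0:
            raise ValueError("hash_length must be odd and >= 11")
        if self.coverage_cutoff < 1:
            raise ValueError("coverage_cutoff must be >= 1")
        if self.min_pair_count < 1:
            raise ValueError("min_pair_count must be >= 1")


@dataclass
class Contig:
    id: int
    sequence: str
    coverage: float  # mean multiplicity of its k-mers

    def __len__(self):
        return len(self.sequence)


@dataclass
class ScaffoldEntry:
    contig_id: int
    orientation: str  # '+' or '-'
    gap_to_next: int  # estimated, >= 0; ignored for the last entry


@dataclass
class Scaffold:
    id: int
    entries: list[ScaffoldEntry]
    junction_support: list[int] = field(default_factory=list)

    def length(self, contigs: dict[int, Contig]) -> int:
        n = sum(len(contigs[e.contig_id]) for e in self.entries)
        n += sum(max(e.gap_to_next, 0) for e in self.entries[:-1])
        return n

    def sequence(self, contigs: dict[int, Contig], gap_char: str = "N",
                 single_n: bool = True) -> str:
        """Scaffold sequence; gaps as one N (default) or the estimated run."""
        parts = []
        for i, e in enumerate(self.entries):
            s = contigs[e.contig_id].sequence
            parts.append(s if e.orientation == "+" else revcomp(s))
            if i < len(self.entries) - 1:
                parts.append(gap_char if single_n else gap_char * max(1, e.gap_to_next))
        return "".join(parts)


@dataclass
class AssemblyStats:
    n_contigs: int
    n_scaffolds: int
    n50_contig: int
    n50_scaffold: int
    total_contig_length: int

    def to_tsv(self) -> str:
        header = "Sc\tN50 Sc (bp)\tCo\tN50 Co (bp)\tCo length (bp)\n"
        return header + (
            f"{self.n_scaffolds}\t{self.n50_scaffold}\t{self.n_contigs}\t"
            f"{self.n50_contig}\t{self.total_contig_length}\n"
        )


def n50(lengths: Iterable[int]) -> int:
    """Length of the shortest sequence in the smallest set of longest
    sequences covering at least half the total length."""
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    if total == 0:
        return 0
    acc = 0
    for l in ls:
        acc += l
        if 2 * acc >= total:
            return l
    return ls[-1]


# ---------------------------------------------------------------------------
# de Bruijn contig construction
# ---------------------------------------------------------------------------


def count_kmers(reads: Iterable[str], k: int) -> Counter:
    counts: Counter = Counter()
    for read in reads:
        for i in range(len(read) - k + 1):
            km = read[i : i + k]
            if "N" not in km:
                counts[canonical(km)] += 1
    return counts


class _Graph:
    """Oriented walks over a canonical k-mer set."""

    def __init__(self, kmer_set: set, k: int):
        self.kmers = kmer_set
        self.k = k

    def present(self, oriented: str) -> bool:
        return canonical(oriented) in self.kmers

    def successors(self, s: str) -> list[str]:
        suf = s[1:]
        return [suf + b for b in BASES if self.present(suf + b)]

    def predecessors(self, s: str) -> list[str]:
        pre = s[:-1]
        return [b + pre for b in BASES if self.present(b + pre)]


def _walk_unitig(g: _Graph, start: str) -> list[str]:
    """Maximal non-branching oriented path through ``start``."""
    path = [start]
    # extend right
    seen = {canonical(start)}
    cur = start
    while True:
        nxt = g.successors(cur)
        if len(nxt) != 1:
            break
        n = nxt[0]
        if len(g.predecessors(n)) != 1 or canonical(n) in seen:
            break
        path.append(n)
        seen.add(canonical(n))
        cur = n
    # extend left
    cur = start
    while True:
        prv = g.predecessors(cur)
        if len(prv) != 1:
            break
        p = prv[0]
        if len(g.successors(p)) != 1 or canonical(p) in seen:
            break
        path.insert(0, p)
        seen.add(canonical(p))
        cur = p
    return path


def _unitigs(g: _Graph) -> list[list[str]]:
    done: set[str] = set()
    out = []
    for km in sorted(g.kmers):
        if km in done:
            continue
        path = _walk_unitig(g, km)
        for s in path:
            done.add(canonical(s))
        out.append(path)
    return out


def _trim_tips(kmer_set: set, k: int) -> set:
    """Remove unitigs that dead-end on at least one side and are < 2k nt."""
    g = _Graph(kmer_set, k)
    removed = set()
    for path in _unitigs(g):
        length_nt = len(path) + k - 1
        if length_nt >= 2 * k:
            continue
        left_open = len(g.predecessors(path[0])) == 0
        right_open = len(g.successors(path[-1])) == 0
        # a tip hangs free on at least one end but is attached on the other
        if (left_open != right_open):
            removed.update(canonical(s) for s in path)
    return kmer_set - removed


def _pop_bubbles(kmer_set: set, k: int, counts: Counter) -> set:
    """Collapse pairs of unitigs sharing both neighbourhoods, keeping the
    higher-coverage branch."""
    g = _Graph(kmer_set, k)
    paths = _unitigs(g)

    def signature(path):
        left = frozenset(canonical(p) for p in g.predecessors(path[0]))
        right = frozenset(canonical(s) for s in g.successors(path[-1]))
        return left, right

    def mean_cov(path):
        return sum(counts[canonical(s)] for s in path) / len(path)

    groups: dict[tuple, list] = defaultdict(list)
    for path in paths:
        left, right = signature(path)
        if left and right:
            # canonicalize the two neighbourhood sets so both orientations
            # of the same bubble branch land in one group
            key = frozenset((left, right))
            groups[key].append(path)
    removed = set()
    for key, group in groups.items():
        if len(group) < 2:
            continue
        group.sort(key=mean_cov, reverse=True)
        for path in group[1:]:
            removed.update(canonical(s) for s in path)
    return kmer_set - removed


def build_contigs(
    reads: Iterable[str], params: AssemblyParams | None = None
) -> list[Contig]:
    """Assemble contigs from (uniformly truncated) reads.

    Returns maximal non-branching paths of the cutoff-filtered de Bruijn
    graph, after tip trimming and bubble popping; contigs whose mean k-mer
    multiplicity falls below the cutoff are dropped. Deterministic for a
    given read multiset.
    """
    params = params or AssemblyParams()
    k = params.hash_length
    counts = count_kmers(reads, k)
    kmer_set = {km for km, c in counts.items() if c >= params.coverage_cutoff}
    if not kmer_set:
        return []
    for _ in range(2):  # tip trimming can expose new tips once
        before = len(kmer_set)
        kmer_set = _trim_tips(kmer_set, k)
        kmer_set = _pop_bubbles(kmer_set, k, counts)
        if len(kmer_set) == before:
            break
    g = _Graph(kmer_set, k)
    contigs = []
    for path in _unitigs(g):
        seq = path[0] + "".join(s[-1] for s in path[1:])
        cov = sum(counts[canonical(s)] for s in path) / len(path)
        if cov < params.coverage_cutoff:
            continue
        contigs.append((seq, cov))
    # deterministic ids: longest first, ties by sequence
    contigs.sort(key=lambda t: (-len(t[0]), t[0]))
    return [Contig(i, seq, cov) for i, (seq, cov) in enumerate(contigs)]


# ---------------------------------------------------------------------------
# Mate-pair scaffolding
# ---------------------------------------------------------------------------


def _mate_direction(strand: str, which: str, orientation: str) -> str:
    """Direction ('R' right / 'L' left) of the mate relative to a mapped tag.

    With the outward convention the forward tag is stored as the reverse
    complement of the fragment prefix, so a '-' mapping of tag F means the
    fragment runs rightward and the mate lies to the right.
    """
    if orientation == "outward":
        frag_forward = (strand == "-") if which == "F" else (strand == "+")
    else:  # inward: F = fragment prefix, R = revcomp of fragment suffix
        frag_forward = (strand == "+") if which == "F" else (strand == "-")
    if which == "F":
        return "R" if frag_forward else "L"
    return "L" if frag_forward else "R"


def scaffold_contigs(
    contigs: Sequence[Contig],
    library: MatePairLibrary,
    params: AssemblyParams | None = None,
    mapper_params: MapperParams | None = None,
) -> list[Scaffold]:
    """Join contigs into scaffolds using mate-pair evidence.

    Each tag is mapped to the contig set; pairs whose tags map uniquely to
    two different contigs vote for a junction between specific contig ends.
    Junctions with >= min_pair_count votes are accepted; conflicts resolve
    to the highest support (ties to the smaller contig id) and cycles are
    broken at their weakest junction. Gap lengths are estimated from the
    library insert size, floored at 0.
    """
    params = params or AssemblyParams()
    mapper_params = mapper_params or MapperParams()
    cdict = {c.id: c for c in contigs}
    if not contigs:
        return []
    ids = [c.id for c in contigs]
    idx = ReferenceIndex(
        [cdict[i].sequence for i in ids], mapper_params.chunk_len(library.tag_length)
    )

    votes: dict[tuple, list[int]] = defaultdict(list)  # edge -> gap estimates
    for pair in library.pairs:
        try:
            hits_f = idx.map_tag(pair.tag_f.seq, mapper_params)
            hits_r = idx.map_tag(pair.tag_r.seq, mapper_params)
        except ValueError:
            continue
        if len(hits_f) != 1 or len(hits_r) != 1:
            continue
        hf, hr = hits_f[0], hits_r[0]
        if hf.ref_id == hr.ref_id:
            continue
        cid_f, cid_r = ids[hf.ref_id], ids[hr.ref_id]
        dir_f = _mate_direction(hf.strand, "F", library.orientation)
        dir_r = _mate_direction(hr.strand, "R", library.orientation)
        len_f, len_r = len(cdict[cid_f]), len(cdict[cid_r])
        tl = library.tag_length
        d_f = (len_f - hf.position) if dir_f == "R" else (hf.position + tl)
        d_r = (len_r - hr.position) if dir_r == "R" else (hr.position + tl)
        gap = int(round(library.insert_mean - d_f - d_r))
        end_f = ("R" if dir_f == "R" else "L")
        end_r = ("R" if dir_r == "R" else "L")
        a, b = (cid_f, end_f), (cid_r, end_r)
        edge = (a, b) if a <= b else (b, a)
        votes[edge].append(gap)

    # accept junctions, one partner per contig end
    accepted = sorted(
        ((len(gaps), edge, gaps) for edge, gaps in votes.items()
         if len(gaps) >= params.min_pair_count),
        key=lambda t: (-t[0], t[1]),
    )
    partner: dict[tuple, tuple] = {}
    support: dict[frozenset, int] = {}
    gap_est: dict[frozenset, int] = {}
    for count, (a, b), gaps in accepted:
        if a in partner or b in partner or a[0] == b[0]:
            continue
        partner[a] = b
        partner[b] = a
        key = frozenset((a, b))
        support[key] = count
        gaps.sort()
        gap_est[key] = max(0, gaps[len(gaps) // 2])

    # break cycles at the weakest junction
    def find_cycles():
        seen = set()
        for cid in ids:
            if cid in seen:
                continue
            comp, edges = _component(cid, partner)
            seen.update(comp)
            if edges and len(edges) >= len(comp):  # as many joins as contigs
                yield edges

    for edges in list(find_cycles()):
        weakest = min(edges, key=lambda e: (support[e], sorted(e)))
        a, b = tuple(weakest)
        partner.pop(a, None)
        partner.pop(b, None)

    # traverse components into scaffolds
    scaffolds = []
    visited: set[int] = set()
    for cid in ids:
        if cid in visited:
            continue
        comp, edges = _component(cid, partner)
        visited.update(comp)
        entries = _linearize(comp, partner, gap_est)
        sup = [
            support[frozenset(((entries[i].contig_id, _join_end(entries[i], True)),
                               (entries[i + 1].contig_id, _join_end(entries[i + 1], False))))]
            for i in range(len(entries) - 1)
        ]
        scaffolds.append(Scaffold(len(scaffolds), entries, sup))
    # larger scaffolds first, deterministic
    scaffolds.sort(key=lambda s: (-sum(len(cdict[e.contig_id]) for e in s.entries),
                                  s.entries[0].contig_id))
    for i, s in enumerate(scaffolds):
        s.id = i
    return scaffolds


def _join_end(entry: ScaffoldEntry, outgoing: bool) -> str:
    """Physical contig end used by the junction leaving (or entering) an
    entry, given its orientation in the scaffold."""
    if outgoing:  # junction to the next entry: right end in scaffold coords
        return "R" if entry.orientation == "+" else "L"
    return "L" if entry.orientation == "+" else "R"


def _component(cid: int, partner: dict) -> tuple[list[int], set]:
    comp = {cid}
    edges = set()
    frontier = [cid]
    while frontier:
        c = frontier.pop()
        for end in ("L", "R"):
            other = partner.get((c, end))
            if other is None:
                continue
            edges.add(frozenset(((c, end), other)))
            if other[0] not in comp:
                comp.add(other[0])
                frontier.append(other[0])
    return sorted(comp), edges


def _linearize(comp: list[int], partner: dict, gap_est: dict) -> list[ScaffoldEntry]:
    if len(comp) == 1:
        return [ScaffoldEntry(comp[0], "+", 0)]
    # find a terminal contig (an end with no partner)
    start = None
    for c in comp:
        free = [e for e in ("L", "R") if (c, e) not in partner]
        if free:
            start = (c, free[0])
            break
    assert start is not None  # cycles were broken above
    c, free_end = start
    orientation = "+" if free_end == "L" else "-"
    entries = [ScaffoldEntry(c, orientation, 0)]
    used = {c}
    while True:
        cur = entries[-1]
        out_end = _join_end(cur, True)
        nxt = partner.get((cur.contig_id, out_end))
        if nxt is None or nxt[0] in used:
            break
        key = frozenset(((cur.contig_id, out_end), nxt))
        cur.gap_to_next = gap_est.get(key, 0)
        ncid, nend = nxt
        entries.append(ScaffoldEntry(ncid, "+" if nend == "L" else "-", 0))
        used.add(ncid)
    return entries


def assembly_metrics(
    contigs: Sequence[Contig], scaffolds: Sequence[Scaffold]
) -> AssemblyStats:
    cdict = {c.id: c for c in contigs}
    contig_lengths = [len(c) for c in contigs]
    scaffold_lengths = [s.length(cdict) for s in scaffolds]
    return AssemblyStats(
        n_contigs=len(contigs),
        n_scaffolds=len(scaffolds),
        n50_contig=n50(contig_lengths),
        n50_scaffold=n50(scaffold_lengths),
        total_contig_length=sum(contig_lengths),
    )
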