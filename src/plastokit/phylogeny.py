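"""Maximum-parsimony phylogeny with exhaustive search and bootstrap.

For the handful of taxa a plastome comparison involves, the space of
unrooted binary topologies is tiny ((2n-5)!! trees: 15 for five taxa), so
the search is exact rather than heuristic: every topology is enumerated
and scored with the Fitch algorithm. Gaps and ambiguity codes are treated
as missing data (the full state set), so they never force a change.
Bootstrap support resamples alignment columns with replacement and maps
each internal bipartition's replicate frequency onto the original best
tree.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequences import BASES

_CODE = {"A": 1, "C": 2, "G": 4, "T": 8}
MISSING = 15  # gap / N / ambiguity: compatible with every state

EXHAUSTIVE_BOUND = 9  # 135,135 topologies; beyond this, refuse


@dataclass
class CharacterMatrix:
    """Aligned DNA characters over named taxa, bit-encoded per state."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_columns) uint8 bitmasks

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxa")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "CharacterMatrix":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("aligned rows must all have equal length")
        n = lengths.pop()
        M = np.full((len(taxa), n), MISSING, dtype=np.uint8)
        for i, t in enumerate(taxa):
            row = seqs[t].upper()
            M[i] = [_CODE.get(c, MISSING) for c in row]
        return cls(taxa, M)

    def unique_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique column matrix, multiplicities) — the workhorse that makes
        genome-scale parsimony cheap."""
        cols, counts = np.unique(self.matrix.T, axis=0, return_counts=True)
        return cols.T.copy(), counts

    def to_fasta(self, path):
        with open(path, "w") as fh:
            rev = {v: k for k, v in _CODE.items()}
            for i, t in enumerate(self.taxa):
                fh.write(f">{t}\n")
                fh.write("".join(rev.get(int(c), "-") for c in self.matrix[i]) + "\n")

    @classmethod
    def from_fasta(cls, path) -> "CharacterMatrix":
        from Bio import SeqIO

        return cls.from_sequences(
            {r.id: str(r.seq) for r in SeqIO.parse(path, "fasta")}
        )


# ---------------------------------------------------------------------------
# Topologies
# ---------------------------------------------------------------------------
# An unrooted binary topology over taxon indices is a tuple with three
# subtrees at the (arbitrary) central node; every other internal node is a
# pair. Leaves are ints.


def _sub_insert(node, t):
    yield (node, t)  # insertion into the edge above this node
    if isinstance(node, tuple):
        a, b = node
        for va in _sub_insert(a, t):
            yield (va, b)
        for vb in _sub_insert(b, t):
            yield (a, vb)


def enumerate_topologies(n_taxa: int):
    """All unrooted binary topologies over taxa 0..n-1 ((2n-5)!! of them)."""
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa for an unrooted topology search")
    trees = [(0, 1, 2)]
    for t in range(3, n_taxa):
        nxt = []
        for tr in trees:
            a, b, c = tr
            for va in _sub_insert(a, t):
                nxt.append((va, b, c))
            for vb in _sub_insert(b, t):
                nxt.append((a, vb, c))
            for vc in _sub_insert(c, t):
                nxt.append((a, b, vc))
        trees = nxt
    return trees


def _as_binary(topology):
    """Re-root a 3-child central tuple along one edge (Fitch length is
    invariant to the rooting)."""
    if len(topology) == 3:
        a, b, c = topology
        return (a, (b, c))
    return topology


def leaves_of(node) -> frozenset:
    if not isinstance(node, tuple):
        return frozenset((node,))
    out = frozenset()
    for child in node:
        out |= leaves_of(child)
    return out


def bipartitions(topology, n_taxa: int) -> set[frozenset]:
    """Non-trivial bipartitions, each canonicalized as the side that does
    not contain taxon 0."""
    all_taxa = frozenset(range(n_taxa))
    out: set[frozenset] = set()

    def walk(node, at_root=False):
        if not isinstance(node, tuple):
            return
        if not at_root:
            side = leaves_of(node)
            if 1 < len(side) < n_taxa - 1:
                out.add(side if 0 not in side else all_taxa - side)
        for child in node:
            walk(child)

    walk(topology, at_root=True)
    return out


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


def _fitch_columns(topology, M: np.ndarray) -> np.ndarray:
    """Per-column minimum change counts (vectorized bottom-up Fitch pass)."""
    score = np.zeros(M.shape[1], dtype=np.int64)

    def rec(node) -> np.ndarray:
        if not isinstance(node, tuple):
            return M[node]
        acc = rec(node[0])
        for child in node[1:]:
            b = rec(child)
            inter = acc & b
            empty = inter == 0
            score[empty] += 1
            acc = np.where(empty, acc | b, inter)
        return acc

    rec(_as_binary(topology))
    return score


def fitch_length(
    matrix: CharacterMatrix,
    topology,
    weights: np.ndarray | None = None,
    _cols: np.ndarray | None = None,
) -> int:
    """Parsimony length of a topology: summed Fitch minimum changes.

    ``topology`` uses taxon indices into ``matrix.taxa``. Missing states
    (gap/N) carry the full state set and never force a change.
    """
    M = matrix.matrix if _cols is None else _cols
    if leaves_of(topology) != frozenset(range(len(matrix.taxa))):
        raise ValueError("topology taxa do not match the matrix")
    per_col = _fitch_columns(topology, M)
    if weights is None:
        return int(per_col.sum())
    return int((per_col * weights).sum())


@dataclass
class PhyloTree:
    """Best topology with parsimony context and optional bootstrap support."""

    taxa: list[str]
    topology: tuple
    length: int
    support: dict[frozenset, float] = field(default_factory=dict)  # pct
    co_optimal: list[tuple] = field(default_factory=list)
    outgroup: str | None = None
    rooted_topology: tuple | None = None

    def named_bipartitions(self) -> dict[frozenset, float]:
        return {
            frozenset(self.taxa[i] for i in bp): pct
            for bp, pct in self.support.items()
        }

    def to_newick(self) -> str:
        """Newick string; internal nodes labelled with bootstrap support
        when available."""
        topo = self.rooted_topology if self.rooted_topology is not None else self.topology

        def render(node) -> str:
            if not isinstance(node, tuple):
                return self.taxa[node]
            inner = ",".join(render(c) for c in node)
            label = ""
            side = leaves_of(node)
            n = len(self.taxa)
            key = side if 0 not in side else frozenset(range(n)) - side
            if key in self.support:
                label = f"{self.support[key]:.0f}"
            return f"({inner}){label}"

        return render(topo) + ";"


def strict_consensus(topologies: Sequence[tuple], n_taxa: int) -> set[frozenset]:
    """Bipartitions shared by every topology in the set."""
    it = iter(topologies)
    out = bipartitions(next(it), n_taxa)
    for t in it:
        out &= bipartitions(t, n_taxa)
    return out


def mp_search(
    matrix: CharacterMatrix, exhaustive_bound: int = EXHAUSTIVE_BOUND
) -> PhyloTree:
    """Exhaustive maximum-parsimony search.

    Scores every unrooted topology and returns the best; co-optimal
    topologies are attached, and the reported topology of a tie is the
    first in enumeration order (the strict consensus of the tie set is
    available via ``strict_consensus(tree.co_optimal, n)``).
    """
    n = len(matrix.taxa)
    if n < 4:
        raise ValueError("need >= 4 taxa")
    if n > exhaustive_bound:
        raise ValueError(
            f"{n} taxa exceeds the exhaustive bound {exhaustive_bound}; "
            "reduce the taxon set (heuristic search is out of scope)"
        )
    cols, counts = matrix.unique_columns()
    best_len = None
    best: list[tuple] = []
    for topo in enumerate_topologies(n):
        ln = int((_fitch_columns(topo, cols) * counts).sum())
        if best_len is None or ln < best_len:
            best_len = ln
            best = [topo]
        elif ln == best_len:
            best.append(topo)
    return PhyloTree(
        taxa=list(matrix.taxa),
        topology=best[0],
        length=best_len,
        co_optimal=best,
    )


def bootstrap_support(
    matrix: CharacterMatrix,
    reps: int = 1000,
    seed: int = 0,
    exhaustive_bound: int = EXHAUSTIVE_BOUND,
) -> PhyloTree:
    """Column bootstrap: resample columns with replacement ``reps`` times,
    re-run the exhaustive search, and record each internal bipartition's
    frequency (percent) on the original best tree. Deterministic per seed.

    A replicate supports a bipartition only if the bipartition is in the
    strict consensus of that replicate's co-optimal trees.
    """
    rng = np.random.default_rng(seed)
    tree = mp_search(matrix, exhaustive_bound)
    n = len(matrix.taxa)
    target_bps = bipartitions(tree.topology, n)
    cols, counts = matrix.unique_columns()
    total = int(counts.sum())
    p = counts / total
    topologies = enumerate_topologies(n)
    per_col = np.stack([_fitch_columns(t, cols) for t in topologies])
    bp_sets = [bipartitions(t, n) for t in topologies]
    hits = {bp: 0 for bp in target_bps}
    for _ in range(reps):
        w = rng.multinomial(total, p)
        lens = per_col @ w
        best = np.flatnonzero(lens == lens.min())
        consensus = bp_sets[best[0]].copy()
        for i in best[1:]:
            consensus &= bp_sets[i]
        for bp in target_bps:
            if bp in consensus:
                hits[bp] += 1
    tree.support = {bp: 100.0 * h / reps for bp, h in hits.items()}
    return tree


# ---------------------------------------------------------------------------
# Outgroup rooting
# ---------------------------------------------------------------------------


def _adjacency(topology):
    """Undirected adjacency of the topology; internal nodes get fresh ids."""
    adj: dict = {}
    counter = [-1]

    def new_internal():
        counter[0] -= 1
        return counter[0]

    def add_edge(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def walk(node):
        if not isinstance(node, tuple):
            return node
        me = new_internal()
        for child in node:
            add_edge(me, walk(child))
        return me

    walk(topology)
    return adj


def root_with_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Place the root on the outgroup's pendant edge.

    Returns the tree with ``rooted_topology`` set to
    (outgroup, ingroup subtree); re-rooting with the same outgroup is
    idempotent.
    """
    if outgroup not in tree.taxa:
        raise ValueError(f"unknown taxon {outgroup!r}")
    og = tree.taxa.index(outgroup)
    adj = _adjacency(tree.topology)

    def build(node, parent):
        kids = [k for k in adj[node] if k != parent]
        if not kids:
            return node
        subs = tuple(build(k, node) for k in kids)
        return subs[0] if len(subs) == 1 else subs

    attach = adj[og][0]
    ingroup = build(attach, og)
    tree.outgroup = outgroup
    tree.rooted_topology = (og, ingroup)
    return tree


def ingroup_order(tree: PhyloTree) -> list[str]:
    """Basal-to-derived listing of ingroup taxa on a rooted tree: at every
    node the smaller side splits off first (cherries are unordered)."""
    if tree.rooted_topology is None:
        raise ValueError("root the tree first (root_with_outgroup)")
    order: list[int] = []

    def walk(node):
        if not isinstance(node, tuple):
            order.append(node)
            return
        kids = sorted(node, key=lambda c: (len(leaves_of(c)), min(leaves_of(c))))
        for k in kids:
            walk(k)

    walk(tree.rooted_topology[1])
    return [tree.taxa[i] for i in order]


# ---------------------------------------------------------------------------
# Matrix construction and simulation helpers
# ---------------------------------------------------------------------------


def build_matrix_from_genomes(
    seqs: dict[str, str], backbone: str, anchor_k: int = 15
) -> CharacterMatrix:
    """Stack genomes into a character matrix by aligning each one pairwise
    to a backbone genome and projecting onto backbone coordinates
    (insertions relative to the backbone are dropped)."""
    from .comparative import pairwise_genome_align

    if backbone not in seqs:
        raise ValueError("backbone must be among the sequences")
    ref = seqs[backbone]
    rows = {backbone: ref}
    for name, seq in seqs.items():
        if name == backbone:
            continue
        aln = pairwise_genome_align(ref, seq, anchor_k)
        proj = []
        for x, y in zip(aln.row_a, aln.row_b):
            if x != "-":
                proj.append(y)
        rows[name] = "".join(proj)
    return CharacterMatrix.from_sequences(rows)


def simulate_matrix_on_tree(
    rooted_tree,
    taxa: list[str],
    n_columns: int = 2000,
    branch_rate: float = 0.02,
    r_target: float = 0.7,
    seed: int = 0,
) -> CharacterMatrix:
    """Evolve a root sequence along a rooted nested-tuple tree of taxon
    indices (substitutions only, so columns stay aligned) and return the
    leaf matrix. Truth generator for topology-recovery tests."""
    from .sequences import random_dna
    from .simulate import EvolutionParams, evolve_sequence

    rng = np.random.default_rng(seed)
    root_seq = random_dna(n_columns, rng, gc=0.45)
    params = EvolutionParams(substitution_rate=branch_rate, r_target=r_target)
    leaves: dict[str, str] = {}

    def walk(node, seq):
        if not isinstance(node, tuple):
            leaves[taxa[node]] = seq
            return
        for child in node:
            derived, _ = evolve_sequence(seq, params, rng)
            walk(child, derived)

    walk(rooted_tree, root_seq)
    # keep row order == taxa order so leaf indices stay meaningful
    return CharacterMatrix.from_sequences({t: leaves[t] for t in taxa})
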