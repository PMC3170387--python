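"""Seed-and-extend short-tag mapper and reference-anchored pair selection.

The mapper reports every end-to-end ungapped placement of a tag (either
strand) with at most ``max_mismatch_frac x tag length`` mismatches. Seeding
uses the pigeonhole principle: the tag is cut into ``max_mismatches + 1``
disjoint chunks, so any qualifying placement leaves at least one chunk
error-free and is guaranteed to be found — on small references the mapper
is exactly equivalent to brute-force scanning of every offset and strand.

Selection keeps a mate pair when at least one of its two tags anchors to
the chloroplast reference; the un-anchored mate may then reach into
diverged or unassembled sequence, which is what makes reference-baited
de novo assembly work.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .sequences import revcomp
from .simulate import MatePairLibrary, ReadPair


@dataclass(frozen=True)
class MapperParams:
    seed_k: int = 13
    max_mismatch_frac: float = 0.10
    min_anchor_len: int | None = None  # None = full tag (end-to-end only)

    def __post_init__(self):
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        if not (0 <= self.max_mismatch_frac < 0.5):
            raise ValueError("max_mismatch_frac must be in [0, 0.5)")

    def max_mismatches(self, tag_len: int) -> int:
        return int(self.max_mismatch_frac * tag_len)

    def chunk_len(self, tag_len: int) -> int:
        """Effective seed length: shrink below seed_k only when the
        pigeonhole guarantee (max_mm + 1 disjoint chunks) demands it."""
        return max(1, min(self.seed_k, tag_len // (self.max_mismatches(tag_len) + 1)))


class MappingHit(NamedTuple):
    read_id: int  # caller-assigned; -1 for ad-hoc mapping
    ref_id: int  # index into the reference list (0 for a single reference)
    position: int  # leftmost 0-based reference coordinate
    strand: str  # '+' or '-'
    mismatches: int


def _hamming(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


class ReferenceIndex:
    """Chunk-mer index over one or more reference sequences."""

    def __init__(self, references: Sequence[str], chunk_len: int):
        self.references = list(references)
        self.q = chunk_len
        self.index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        q = chunk_len
        for rid, ref in enumerate(self.references):
            for i in range(len(ref) - q + 1):
                km = ref[i : i + q]
                if "N" not in km:
                    self.index[km].append((rid, i))

    def map_tag(
        self, tag: str, params: MapperParams, read_id: int = -1
    ) -> list[MappingHit]:
        L = len(tag)
        if L < params.seed_k:
            raise ValueError(f"tag of length {L} shorter than seed_k={params.seed_k}")
        max_mm = params.max_mismatches(L)
        q = self.q
        hits: list[MappingHit] = []
        seen: set[tuple[int, int, str]] = set()
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            n_chunks = max_mm + 1
            for c in range(n_chunks):
                off = c * q
                if off + q > L:
                    break
                chunk = query[off : off + q]
                for rid, p in self.index.get(chunk, ()):
                    start = p - off
                    ref = self.references[rid]
                    if start < 0 or start + L > len(ref):
                        continue
                    key = (rid, start, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    mm = _hamming(query, ref[start : start + L], max_mm)
                    if mm <= max_mm:
                        hits.append(MappingHit(read_id, rid, start, strand, mm))
        hits.sort(key=lambda h: (h.ref_id, h.position, h.strand))
        return hits


def map_read(
    tag: str, reference: str, params: MapperParams | None = None
) -> list[MappingHit]:
    """Map one tag against one reference (both strands, end-to-end)."""
    params = params or MapperParams()
    idx = ReferenceIndex([reference], params.chunk_len(len(tag)))
    return idx.map_tag(tag, params)


@dataclass
class SelectionReport:
    n_input_pairs: int = 0
    n_retained_pairs: int = 0
    #: per-compartment (retained, total) counts when hidden origins exist
    by_origin: dict = field(default_factory=dict)

    @property
    def retained_fraction(self) -> float:
        return self.n_retained_pairs / self.n_input_pairs if self.n_input_pairs else 0.0

    def recall(self, compartment: str = "chloroplast") -> float:
        kept, total = self.by_origin.get(compartment, (0, 0))
        return kept / total if total else 0.0

    def precision(self, compartment: str = "chloroplast") -> float:
        kept_target, _ = self.by_origin.get(compartment, (0, 0))
        kept_all = sum(k for k, _ in self.by_origin.values())
        return kept_target / kept_all if kept_all else 0.0

    def to_tsv(self) -> str:
        lines = [
            f"input_pairs\t{self.n_input_pairs}",
            f"retained_pairs\t{self.n_retained_pairs}",
            f"retained_fraction\t{self.retained_fraction:.4f}",
        ]
        for comp, (kept, total) in sorted(self.by_origin.items()):
            lines.append(f"retained_{comp}\t{kept}/{total}")
        return "\n".join(lines) + "\n"


def select_anchored_pairs(
    library: MatePairLibrary,
    reference: str,
    params: MapperParams | None = None,
) -> tuple[MatePairLibrary, SelectionReport]:
    """Keep pairs with at least one tag anchored to the reference."""
    params = params or MapperParams()
    report = SelectionReport(n_input_pairs=len(library))
    if not library.pairs:
        return (
            MatePairLibrary([], library.tag_length, library.insert_mean,
                            library.insert_sd, library.orientation),
            report,
        )
    idx = ReferenceIndex([reference], params.chunk_len(library.tag_length))
    kept: list[ReadPair] = []
    totals: dict[str, int] = defaultdict(int)
    kept_by: dict[str, int] = defaultdict(int)
    for pair in library.pairs:
        comp = pair.origin.compartment if pair.origin else None
        if comp:
            totals[comp] += 1
        anchored = bool(idx.map_tag(pair.tag_f.seq, params)) or bool(
            idx.map_tag(pair.tag_r.seq, params)
        )
        if anchored:
            kept.append(pair)
            if comp:
                kept_by[comp] += 1
    report.n_retained_pairs = len(kept)
    report.by_origin = {c: (kept_by.get(c, 0), t) for c, t in totals.items()}
    out = MatePairLibrary(kept, library.tag_length, library.insert_mean,
                          library.insert_sd, library.orientation)
    return out, report


def coverage_profile(
    hits: Sequence[MappingHit],
    reference_length: int,
    tag_length: int,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-base depth from a set of mapping hits.

    Hits sharing a read id are ambiguous placements (e.g. the two inverted
    repeats); one is chosen uniformly at random (seeded) so total read
    placements are conserved while repeat coverage splits between copies.
    """
    rng = np.random.default_rng(seed)
    by_read: dict[int, list[MappingHit]] = defaultdict(list)
    singles: list[MappingHit] = []
    for h in hits:
        if h.read_id == -1:
            singles.append(h)
        else:
            by_read[h.read_id].append(h)
    chosen = singles + [
        hs[0] if len(hs) == 1 else hs[int(rng.integers(0, len(hs)))]
        for hs in by_read.values()
    ]
    depth = np.zeros(reference_length + 1, dtype=np.int64)
    for h in chosen:
        start = max(0, h.position)
        end = min(reference_length, h.position + tag_length)
        if start < end:
            depth[start] += 1
            depth[end] -= 1
    depth = np.cumsum(depth[:-1])
    mean = float(depth.mean()) if reference_length else 0.0
    return depth, mean


def plot_coverage(depth: np.ndarray, path, title: str = "Depth of coverage"):
    """Coverage-along-the-genome plot (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.fill_between(np.arange(len(depth)), depth, color="steelblue", lw=0)
    ax.set_xlabel("genome coordinate (nt)")
    ax.set_ylabel("depth")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
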