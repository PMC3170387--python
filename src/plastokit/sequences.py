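"""Low-level DNA string helpers shared across the toolkit.

Sequences are plain Python ``str`` over the alphabet ``ACGTN``; all
coordinates are 0-based half-open.
"""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: unordered transition pairs (within purines / within pyrimidines)
TRANSITION_PAIRS = frozenset({frozenset("AG"), frozenset("CT")})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.40) -> str:
    """Random DNA with a given GC content (chloroplast genomes are AT-rich)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def kmers(seq: str, k: int):
    """Yield (offset, k-mer) for every k-mer free of non-ACGT characters."""
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            yield i, km


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def is_transition(a: str, b: str) -> bool:
    """True when a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return frozenset((a, b)) in TRANSITION_PAIRS
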