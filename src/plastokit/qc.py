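"""Mate-pair quality filtering: truncation + mean-QV threshold.

Tags are truncated to a fixed prefix (default 40 nt) and a tag survives
only if the mean quality of that prefix strictly exceeds the threshold
(default QV 20). By default a pair is kept only when both mates pass, since
downstream scaffolding relies on intact pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .simulate import MatePairLibrary, Read, ReadPair


@dataclass(frozen=True)
class FilterParams:
    truncate_to: int = 40
    min_mean_qv: float = 20.0
    require_both_mates: bool = True

    def __post_init__(self):
        if self.truncate_to <= 0:
            raise ValueError("truncate_to must be positive")
        if self.min_mean_qv < 0:
            raise ValueError("min_mean_qv must be >= 0")


@dataclass
class FilterReport:
    n_input_pairs: int = 0
    n_kept_pairs: int = 0
    dropped_short: int = 0  # pairs with a tag shorter than truncate_to
    dropped_quality: int = 0  # pairs failing the mean-QV rule

    @property
    def n_dropped_pairs(self) -> int:
        return self.dropped_short + self.dropped_quality

    def to_tsv(self) -> str:
        rows = [
            ("input_pairs", self.n_input_pairs),
            ("kept_pairs", self.n_kept_pairs),
            ("dropped_short", self.dropped_short),
            ("dropped_quality", self.dropped_quality),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def _truncate(tag: Read, n: int) -> Read:
    return Read(tag.seq[:n], tag.qv[:n])


def _passes(tag: Read, params: FilterParams) -> bool:
    # mean computed on the truncated prefix; strictly 'exceeds' the threshold
    return float(tag.qv.mean()) > params.min_mean_qv


def filter_mate_pairs(
    library: MatePairLibrary, params: FilterParams | None = None
) -> tuple[MatePairLibrary, FilterReport]:
    """Truncate tags and drop pairs failing the mean-quality rule.

    Returns the filtered library (tags exactly ``truncate_to`` long) and a
    report with kept/dropped counts; kept + dropped = input.
    """
    params = params or FilterParams()
    report = FilterReport(n_input_pairs=len(library))
    kept: list[ReadPair] = []
    for pair in library.pairs:
        tags = (pair.tag_f, pair.tag_r)
        if any(len(t.seq) < params.truncate_to for t in tags):
            report.dropped_short += 1
            continue
        tf = _truncate(pair.tag_f, params.truncate_to)
        tr = _truncate(pair.tag_r, params.truncate_to)
        ok_f, ok_r = _passes(tf, params), _passes(tr, params)
        ok = (ok_f and ok_r) if params.require_both_mates else (ok_f or ok_r)
        if not ok:
            report.dropped_quality += 1
            continue
        kept.append(ReadPair(tf, tr, pair.origin))
    report.n_kept_pairs = len(kept)
    out = MatePairLibrary(
        kept,
        tag_length=min(params.truncate_to, library.tag_length),
        insert_mean=library.insert_mean,
        insert_sd=library.insert_sd,
        orientation=library.orientation,
    )
    return out, report
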