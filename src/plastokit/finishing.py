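"""Reference-collinear ordering, reiteration, gap primers, gap closure,
and inverted-repeat reconstruction.

After de novo assembly the scaffolds are laid against a related reference
genome: each gap-free piece is anchored by maximal unique matches, chained
collinearly, then all pieces are ordered and oriented by their reference
midpoint and concatenated with exactly one ``N`` per junction — the
pseudomolecule. Mis-joined (chimeric) scaffolds are implicitly corrected
because pieces are re-anchored independently on either side of their gaps.

Gaps are then closed with long "finishing" reads (CE-read stand-ins): a
read anchoring to both flanks of a gap donates its spanning segment, and
every overlap column between read and assembly is tallied into a
discrepancy report. Finally IRb, which was deliberately left out of
assembly, is restored as the reverse complement of IRa.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import edlib

from .assembly import AssemblyParams, Contig, Scaffold, build_contigs, scaffold_contigs
from .mapping import MapperParams, select_anchored_pairs
from .sequences import revcomp
from .simulate import MatePairLibrary

ANCHOR_K = 31  # maximal-unique-match seed length for collinearity


class AnchorBlock(NamedTuple):
    """One collinear exact-match block between query and reference."""

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    orientation: str


@dataclass
class CollinearityAlignment:
    query_id: int
    orientation: str
    blocks: list[AnchorBlock]

    @property
    def ref_midpoint(self) -> float:
        if not self.blocks:
            return float("nan")
        lo = min(b.r_start for b in self.blocks)
        hi = max(b.r_end for b in self.blocks)
        return (lo + hi) / 2

    @property
    def anchored_length(self) -> int:
        return sum(b.q_end - b.q_start for b in self.blocks)


@dataclass
class Pseudomolecule:
    """Ordered concatenation of assembly pieces with one N per gap."""

    sequence: str
    provenance: list[tuple[int, str, int, int]]  # (piece id, orient, start, end)
    unplaced: list[int] = field(default_factory=list)

    @property
    def gap_positions(self) -> list[int]:
        return [i for i, c in enumerate(self.sequence) if c == "N"]

    @property
    def n_gaps(self) -> int:
        return len(self.gap_positions)


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        if km in pos:
            dup.add(km)
        else:
            pos[km] = i
    for km in dup:
        del pos[km]
    return pos


def _lis_chain(matches: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of matches increasing in both coordinates (O(n log n))."""
    import bisect

    matches = sorted(matches)
    tails: list[int] = []  # r-coordinates
    tails_idx: list[int] = []
    prev = [-1] * len(matches)
    for i, (_, r) in enumerate(matches):
        j = bisect.bisect_left(tails, r)
        if j == len(tails):
            tails.append(r)
            tails_idx.append(i)
        else:
            tails[j] = r
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i != -1:
        chain.append(matches[i])
        i = prev[i]
    return chain[::-1]


def anchor_to_reference(
    query: str, ref_pos: dict[str, int], k: int = ANCHOR_K
) -> CollinearityAlignment | None:
    """Anchor a sequence to the reference by unique shared k-mers, chained
    by longest increasing subsequence; the better-scoring orientation wins.
    Ambiguous pieces (both orientations tie) return None."""
    results = {}
    for orient, q in (("+", query), ("-", revcomp(query))):
        qpos = _unique_kmer_positions(q, k)
        matches = [(qp, ref_pos[km]) for km, qp in qpos.items() if km in ref_pos]
        if not matches:
            results[orient] = (0, [])
            continue
        chain = _lis_chain(matches)
        # merge co-diagonal runs into blocks
        blocks: list[AnchorBlock] = []
        for qp, rp in chain:
            if blocks and blocks[-1].q_end >= qp and \
               (rp - qp) == (blocks[-1].r_start - blocks[-1].q_start):
                b = blocks[-1]
                blocks[-1] = AnchorBlock(b.q_start, qp + k, b.r_start, rp + k, orient)
            else:
                blocks.append(AnchorBlock(qp, qp + k, rp, rp + k, orient))
        score = sum(b.q_end - b.q_start for b in blocks)
        results[orient] = (score, blocks)
    s_fwd, b_fwd = results["+"]
    s_rev, b_rev = results["-"]
    if s_fwd == 0 and s_rev == 0:
        return None
    if s_fwd == s_rev:
        return None  # ambiguous placement: report, never guess
    orient = "+" if s_fwd > s_rev else "-"
    return CollinearityAlignment(-1, orient, results[orient][1])


def order_against_reference(
    pieces: Sequence[str],
    reference: str,
    anchor_k: int = ANCHOR_K,
) -> Pseudomolecule:
    """Order and orient assembly sequences against a reference genome.

    Input sequences may contain ``N`` gap sentinels (scaffolds); they are
    split at the Ns and every gap-free piece is anchored independently,
    which both orders small contigs and breaks scaffolds that are
    non-collinear with the reference at a gap. Anchored pieces are sorted
    by reference midpoint, oriented, and joined with one N per junction;
    unanchored or ambiguous pieces are reported in ``unplaced``.
    """
    fragments: list[str] = []
    for seq in pieces:
        fragments.extend(p for p in seq.split("N") if p)
    if not fragments:
        raise ValueError("no sequence to order")
    ref_pos = _unique_kmer_positions(reference, anchor_k)
    placed = []
    unplaced = []
    for fid, frag in enumerate(fragments):
        aln = anchor_to_reference(frag, ref_pos, anchor_k)
        if aln is None:
            unplaced.append(fid)
            continue
        aln.query_id = fid
        placed.append((aln.ref_midpoint, fid, aln.orientation))
    if not placed:
        raise ValueError(
            "no piece anchors to the reference; wrong or missing reference?"
        )
    placed.sort()
    parts: list[str] = []
    provenance = []
    cursor = 0
    for i, (_, fid, orient) in enumerate(placed):
        seq = fragments[fid] if orient == "+" else revcomp(fragments[fid])
        if parts:
            o = _exact_overlap(parts[-1], seq)
            if o:
                seq = seq[o:]  # neighbours overlap (e.g. k-1 de Bruijn ends)
            else:
                parts.append("N")
                cursor += 1
        parts.append(seq)
        provenance.append((fid, orient, cursor, cursor + len(seq)))
        cursor += len(seq)
    return Pseudomolecule("".join(parts), provenance, unplaced)


def _exact_overlap(left: str, right: str, min_o: int = 12, max_o: int = 200) -> int:
    """Largest exact suffix(left)/prefix(right) overlap in [min_o, max_o]."""
    hi = min(max_o, len(left), len(right))
    for o in range(hi, min_o - 1, -1):
        if left[-o:] == right[:o]:
            return o
    return 0


def reiterate(
    library: MatePairLibrary,
    pseudomolecule: Pseudomolecule,
    assembly_params: AssemblyParams | None = None,
    mapper_params: MapperParams | None = None,
) -> tuple[list[Contig], list[Scaffold], Pseudomolecule]:
    """Second assembly pass with the pseudomolecule as its own reference.

    Reads that failed to map against the original (diverged) reference are
    recaptured against the first-pass assembly, then assembly and ordering
    are repeated.
    """
    assembly_params = assembly_params or AssemblyParams()
    mapper_params = mapper_params or MapperParams()
    selected, _ = select_anchored_pairs(
        library, pseudomolecule.sequence, mapper_params
    )
    contigs = build_contigs(selected.tags(), assembly_params)
    scaffolds = scaffold_contigs(contigs, selected, assembly_params, mapper_params)
    cdict = {c.id: c for c in contigs}
    seqs = [s.sequence(cdict) for s in scaffolds]
    new_pm = order_against_reference(seqs, pseudomolecule.sequence.replace("N", ""))
    return contigs, scaffolds, new_pm


# ---------------------------------------------------------------------------
# Primer design (Wallace-rule Tm)
# ---------------------------------------------------------------------------


class PrimerPair(NamedTuple):
    gap_position: int
    forward: str
    forward_start: int
    reverse: str  # revcomp of the right-flank window, 5'->3'
    reverse_start: int
    tm_forward: float
    tm_reverse: float
    product_span: int


def wallace_tm(primer: str) -> float:
    """Tm by the 2(A+T) + 4(G+C) rule."""
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


def _has_long_run(seq: str, n: int = 5) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run >= n:
            return True
    return False


def design_gap_primers(
    pm: Pseudomolecule,
    flank_len: int = 500,
    primer_len: tuple[int, int] = (18, 24),
    tm_bounds: tuple[float, float] = (52.0, 68.0),
) -> list[PrimerPair | None]:
    """One primer pair per gap, or None where no compliant window exists.

    Primers face each other across the gap, satisfy the length and
    Wallace-Tm bounds, and contain no mononucleotide run of 5+.
    """
    seq = pm.sequence
    out: list[PrimerPair | None] = []

    def scan(flank: str, from_end: bool) -> tuple[str, int] | None:
        lo, hi = primer_len
        positions = range(len(flank) - lo, -1, -1) if from_end else range(0, len(flank) - lo + 1)
        for start in positions:
            for plen in range(lo, hi + 1):
                if start + plen > len(flank):
                    break
                cand = flank[start : start + plen]
                if "N" in cand or _has_long_run(cand):
                    continue
                tm = wallace_tm(cand)
                if tm_bounds[0] <= tm <= tm_bounds[1]:
                    return cand, start
        return None

    for g in pm.gap_positions:
        left_start = max(0, g - flank_len)
        left = seq[left_start:g]
        right = seq[g + 1 : g + 1 + flank_len]
        if len(left) < flank_len or len(right) < flank_len or "N" in left or "N" in right:
            out.append(None)  # gap too close to an end or another gap
            continue
        fwd = scan(left, from_end=True)
        rev = scan(right, from_end=False)
        if fwd is None or rev is None:
            out.append(None)
            continue
        fseq, fstart = fwd
        rseq, rstart = rev
        f_abs = left_start + fstart
        r_abs = g + 1 + rstart
        out.append(
            PrimerPair(
                gap_position=g,
                forward=fseq,
                forward_start=f_abs,
                reverse=revcomp(rseq),
                reverse_start=r_abs,
                tm_forward=wallace_tm(fseq),
                tm_reverse=wallace_tm(rseq),
                product_span=(r_abs + len(rseq)) - f_abs,
            )
        )
    return out


def primer_table_tsv(primers: Sequence[PrimerPair | None]) -> str:
    lines = ["gap_position\tforward\ttm_f\treverse\ttm_r\tproduct_span\tstatus"]
    for p in primers:
        if p is None:
            lines.append(".\t.\t.\t.\t.\t.\tundesignable")
        else:
            lines.append(
                f"{p.gap_position}\t{p.forward}\t{p.tm_forward:.0f}\t"
                f"{p.reverse}\t{p.tm_reverse:.0f}\t{p.product_span}\tok"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Gap closure with long finishing reads
# ---------------------------------------------------------------------------


@dataclass
class DiscrepancyReport:
    """Column-by-column comparison of finishing reads vs the assembly over
    their overlaps: substitution mismatches and INDEL columns are tallied
    separately."""

    overlap_length: int = 0
    mismatches: int = 0
    indel_columns: int = 0
    closed_gaps: int = 0
    open_gaps: int = 0

    @property
    def rate(self) -> float:
        return self.mismatches / self.overlap_length if self.overlap_length else 0.0


def _cigar_tallies(cigar: str) -> tuple[int, int, int]:
    """(columns, mismatches, indel columns) from an edlib extended cigar."""
    cols = mm = ind = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "X":
                mm += n
            elif ch in "ID":
                ind += n
    return cols, mm, ind


def close_gaps(
    pm: Pseudomolecule,
    finishing_reads: Sequence[tuple[str, str]],
    min_overlap: int = 100,
    max_divergence: float = 0.05,
) -> tuple[str, DiscrepancyReport]:
    """Close single-N gaps using long reads that anchor to both flanks.

    For each gap, the trailing ``min_overlap``+ bases of the left flank and
    the leading bases of the right flank are located inside each candidate
    read (semi-global alignment); a read matching both, in order, donates
    the segment between the two matches. All overlap columns are compared
    and accumulated into the DiscrepancyReport. Non-gap columns of the
    pseudomolecule are never modified.
    """
    report = DiscrepancyReport()
    seq = pm.sequence
    gaps = pm.gap_positions
    if not gaps:
        return seq, report
    window = max(min_overlap, 150)
    candidates = [(rid, rs) for rid, rs in finishing_reads]
    candidates += [(rid + "_rc", revcomp(rs)) for rid, rs in finishing_reads]

    pieces: list[str] = []
    prev = 0
    pending_trim = 0  # bases to drop from the next segment (flank overlap)
    for g in gaps:
        # flank limited to the N-free stretch adjacent to this gap
        lstart = max(seq.rfind("N", 0, g) + 1, 0)
        rend_n = seq.find("N", g + 1)
        rend = rend_n if rend_n != -1 else len(seq)
        lf = seq[max(lstart, g - window) : g]
        rf = seq[g + 1 : min(rend, g + 1 + window)]
        best = None
        best_dist = None
        if len(lf) >= min_overlap and len(rf) >= min_overlap:
            k_tol = int(max_divergence * window)
            for rid, rs in candidates:
                r1 = edlib.align(lf, rs, mode="HW", task="locations", k=k_tol)
                if r1["editDistance"] < 0:
                    continue
                r2 = edlib.align(rf, rs, mode="HW", task="locations", k=k_tol)
                if r2["editDistance"] < 0:
                    continue
                e1 = r1["locations"][0][1]
                s2 = r2["locations"][0][0]
                overlap_trim = max(0, e1 - s2 + 1)
                if overlap_trim >= len(rf):
                    continue  # flanks grossly out of order in this read
                dist = r1["editDistance"] + r2["editDistance"]
                if best_dist is None or dist < best_dist:
                    best_dist = dist
                    fill = rs[e1 + 1 : s2] if s2 > e1 else ""
                    best = (rid, rs, lf, rf, fill, overlap_trim)
        mid = seq[prev:g][pending_trim:]
        pending_trim = 0
        if best is None:
            report.open_gaps += 1
            pieces.append(mid + "N")  # gap stays open
        else:
            report.closed_gaps += 1
            _, rs, lf, rf, fill, overlap_trim = best
            for flank in (lf, rf):
                r = edlib.align(flank, rs, mode="HW", task="path",
                                k=int(max_divergence * window))
                cols, mm, ind = _cigar_tallies(r["cigar"])
                report.overlap_length += cols
                report.mismatches += mm
                report.indel_columns += ind
            pieces.append(mid)
            pieces.append(fill)
            # the read shows the two flanks overlap by this much: the
            # duplicated bases are trimmed from the right flank
            pending_trim = overlap_trim
        prev = g + 1
    pieces.append(seq[prev:][pending_trim:])
    return "".join(pieces), report


# ---------------------------------------------------------------------------
# Inverted-repeat reconstruction
# ---------------------------------------------------------------------------


def detect_inverted_repeat(
    seq: str, k: int = ANCHOR_K, min_ir_len: int = 1000
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the longest inverted repeat pair (IRa span, IRb span) in a
    full genome by seeding k-mers of the sequence against its reverse
    complement and extending maximally."""
    L = len(seq)
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(L - k + 1):
        pos[seq[i : i + k]].append(i)
    best = None
    rc = revcomp(seq)
    seen_pairs: set[tuple[int, int]] = set()
    for j in range(0, L - k + 1, k // 2):
        km = rc[j : j + k]
        for i in pos.get(km, ()):
            b = L - j - k  # start of the partner on the forward strand
            if i >= b:
                continue
            # extend outward: seq[i..] vs revcomp of segment ending at b+k
            left, right = i, i + k
            pl, pr = b, b + k
            while left > 0 and pr < L and seq[left - 1] == revcomp(seq[pr]) :
                left -= 1
                pr += 1
            while right < L and pl > 0 and seq[right] == revcomp(seq[pl - 1]):
                right += 1
                pl -= 1
            if right <= pl:
                pair = ((left, right), (pl, pr))
                key = (left, pl)
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                if best is None or (right - left) > (best[0][1] - best[0][0]):
                    best = pair
    if best is None or (best[0][1] - best[0][0]) < min_ir_len:
        raise ValueError(f"no inverted repeat of >= {min_ir_len} nt found")
    return best


def add_inverted_repeat(
    closed_seq: str,
    ira_span: tuple[int, int],
) -> tuple[str, dict]:
    """Append IRb = revcomp(IRa) to a LSC+IRa+SSC molecule.

    Returns the full circular genome and a junction report with the four
    boundary coordinates (LSC/IRa, IRa/SSC, SSC/IRb, IRb/LSC-origin).
    """
    s, e = ira_span
    if not (0 <= s < e <= len(closed_seq)):
        raise ValueError("IRa span outside sequence")
    ira = closed_seq[s:e]
    full = closed_seq + revcomp(ira)
    junctions = {
        "LSC/IRa": s,
        "IRa/SSC": e,
        "SSC/IRb": len(closed_seq),
        "IRb/origin": len(full),
        "circular": True,
    }
    return full, junctions


def locate_ref_coord(
    assembled: str,
    reference: str,
    ref_coord: int,
    window: int = 100,
    max_divergence: float = 0.25,
) -> int:
    """Map one reference coordinate onto an assembled molecule.

    A ``window``-wide slice of the reference centred on the coordinate is
    located in the assembly by semi-global alignment, and the coordinate is
    walked through the alignment columns; this stays accurate even when
    indels sit near the boundary, which simple anchor-offset arithmetic
    does not.
    """
    half = window // 2
    w_start = max(0, ref_coord - half)
    query = reference[w_start : w_start + window]
    if len(query) < 20:
        raise ValueError("reference window too short to locate")
    offset = ref_coord - w_start  # query columns to consume
    r = edlib.align(query, assembled, mode="HW", task="path",
                    k=max(4, int(max_divergence * len(query))))
    if r["editDistance"] < 0:
        raise ValueError("reference window not found in assembled molecule")
    t = r["locations"][0][0]
    qi = 0
    num = ""
    for ch in r["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            if qi + n > offset:
                t += offset - qi
                qi = offset
                break
            qi += n
            t += n
        elif ch == "I":  # consumes query only
            if qi + n > offset:
                qi = offset
                break
            qi += n
        elif ch == "D":  # consumes target only
            t += n
        if qi >= offset:
            break
    return max(0, min(len(assembled), t))


def transfer_ir_span(
    assembled: str,
    reference: str,
    ref_ira_span: tuple[int, int],
    window: int = 100,
) -> tuple[int, int]:
    """Map the reference's annotated IRa boundaries onto an assembled
    LSC+IRa+SSC molecule (boundary-window alignment, indel-tolerant)."""
    rs, re_ = ref_ira_span
    s = locate_ref_coord(assembled, reference, rs, window)
    e = locate_ref_coord(assembled, reference, re_, window)
    if not s < e:
        raise ValueError("transferred IR boundaries collapsed")
    return s, e
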