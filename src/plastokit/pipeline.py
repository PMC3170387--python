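"""End-to-end driver: QC -> selection -> assembly -> ordering ->
reiteration -> gap closure -> inverted-repeat reconstruction.

The reference is a related finished plastome; the output is the full
circular genome of the sequenced sample. Each stage's intermediate
products and reports are kept on the result object so any step can be
inspected or rerun with different parameters.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .assembly import (AssemblyParams, AssemblyStats, Contig, Scaffold,
                       assembly_metrics, build_contigs, scaffold_contigs)
from .finishing import (DiscrepancyReport, Pseudomolecule, add_inverted_repeat,
                        close_gaps, locate_ref_coord, order_against_reference,
                        reiterate, transfer_ir_span)
from .mapping import MapperParams, SelectionReport, select_anchored_pairs
from .qc import FilterParams, FilterReport, filter_mate_pairs
from .simulate import MatePairLibrary, PlastomeModel


def sequence_identity(a: str, b: str) -> float:
    """Global identity 1 - edits/max(len); 1.0 for equal sequences."""
    if not a and not b:
        return 1.0
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


@dataclass
class PipelineResult:
    filter_report: FilterReport
    selection_report: SelectionReport
    contigs: list[Contig]
    scaffolds: list[Scaffold]
    stats: AssemblyStats
    pseudomolecule: Pseudomolecule
    contigs2: list[Contig] | None = None
    scaffolds2: list[Scaffold] | None = None
    stats2: AssemblyStats | None = None
    pseudomolecule2: Pseudomolecule | None = None
    closed_sequence: str | None = None
    discrepancy: DiscrepancyReport | None = None
    ira_span: tuple[int, int] | None = None
    final_genome: str | None = None
    junctions: dict = field(default_factory=dict)

    @property
    def best_pseudomolecule(self) -> Pseudomolecule:
        return self.pseudomolecule2 or self.pseudomolecule


def run_pipeline(
    library: MatePairLibrary,
    reference: PlastomeModel,
    finishing_reads: Sequence[tuple[str, str]] | None = None,
    filter_params: FilterParams | None = None,
    mapper_params: MapperParams | None = None,
    assembly_params: AssemblyParams | None = None,
    do_reiterate: bool = True,
) -> PipelineResult:
    """Assemble a plastome from a total-DNA mate-pair library.

    The reference's full sequence baits chloroplast reads; assembly and
    ordering work on the IRb-excluded molecule (LSC+IRa+SSC), and IRb is
    restored at the end as the reverse complement of IRa, its boundaries
    transferred from the reference annotation.
    """
    filter_params = filter_params or FilterParams()
    mapper_params = mapper_params or MapperParams()
    assembly_params = assembly_params or AssemblyParams()

    filtered, filter_report = filter_mate_pairs(library, filter_params)
    selected, selection_report = select_anchored_pairs(
        filtered, reference.sequence, mapper_params
    )
    contigs = build_contigs(selected.tags(), assembly_params)
    scaffolds = scaffold_contigs(contigs, selected, assembly_params, mapper_params)
    cdict = {c.id: c for c in contigs}
    ref_sc = reference.single_copy
    pm = order_against_reference([s.sequence(cdict) for s in scaffolds], ref_sc)
    result = PipelineResult(
        filter_report=filter_report,
        selection_report=selection_report,
        contigs=contigs,
        scaffolds=scaffolds,
        stats=assembly_metrics(contigs, scaffolds),
        pseudomolecule=pm,
    )

    if do_reiterate:
        c2, s2, pm2 = reiterate(filtered, pm, assembly_params, mapper_params)
        result.contigs2, result.scaffolds2, result.pseudomolecule2 = c2, s2, pm2
        result.stats2 = assembly_metrics(c2, s2)

    working = result.best_pseudomolecule
    if finishing_reads:
        closed, report = close_gaps(working, finishing_reads)
        result.closed_sequence = closed
        result.discrepancy = report
    else:
        result.closed_sequence = working.sequence
        result.discrepancy = DiscrepancyReport(open_gaps=working.n_gaps)

    # clip to the reference-collinear span (assembly can carry a few
    # repeat-derived bases past the single-copy boundaries)
    closed = result.closed_sequence
    start = locate_ref_coord(closed, ref_sc, 0)
    end = locate_ref_coord(closed, ref_sc, len(ref_sc))
    closed = closed[start:end]
    result.closed_sequence = closed

    ira = transfer_ir_span(closed, ref_sc, reference.ira_span)
    result.ira_span = ira
    result.final_genome, result.junctions = add_inverted_repeat(closed, ira)
    return result
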