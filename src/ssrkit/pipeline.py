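"""End-to-end orchestration: scan -> classify -> design -> evaluate.

Assembles MarkerRecord objects — one per SSR locus with its primer pair
and every downstream evaluation flag — the unit the marker table, the
pre-selection filter and the transferability study all operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .association import mirna_association, te_association
from .io_formats import PipelineConfig, SequenceRecord
from .insilico_pcr import physical_map, transferability_matrix
from .marker_design import (
    FlankedLocus,
    PrimerPair,
    deduplicate_primers,
    design_primer_pair,
    extract_flanks,
)
from .repeat_scan import SSRLocus, find_perfect_ssrs, merge_compound
from .ssr_classify import composition_class, length_class


@dataclass
class MarkerRecord:
    """One SSR locus with its primer pair and evaluation flags."""

    marker_id: str
    locus: SSRLocus
    flanked: FlankedLocus | None = None
    primer_pair: PrimerPair | None = None
    length_class: str = ""
    composition: str = ""
    map_status: str = ""  # unique | multi | none | excluded_compound
    map_seq_id: str | None = None
    transferable_count: int = 0
    polymorphism: str = ""  # polymorphic | monomorphic | ""
    te_associated: bool = False
    mirna_associated: bool = False
    function_category: str = ""


def scan_dataset(
    records: Sequence[SequenceRecord],
    config: PipelineConfig | None = None,
    compound: bool = True,
) -> list[SSRLocus]:
    """Scan every record; optionally merge zero-gap neighbours into compounds."""
    config = config or PipelineConfig()
    loci: list[SSRLocus] = []
    for rec in records:
        found = find_perfect_ssrs(rec, config)
        loci.extend(merge_compound(found) if compound else found)
    return loci


def develop_markers(
    records: Sequence[SequenceRecord],
    config: PipelineConfig | None = None,
) -> list[MarkerRecord]:
    """Scan, classify, flank and design primers for one dataset.

    Every locus becomes a MarkerRecord whether or not design succeeded;
    failures carry their reason in the primer status.
    """
    config = config or PipelineConfig()
    by_id = {r.id: r for r in records}
    markers: list[MarkerRecord] = []
    for locus in scan_dataset(records, config):
        rec = by_id[locus.seq_id]
        flanked = extract_flanks(locus, rec, config.flank_length)
        pair = design_primer_pair(flanked, config)
        rep = locus.members[0] if locus.is_compound else locus
        markers.append(
            MarkerRecord(
                marker_id=locus.locus_id,
                locus=locus,
                flanked=flanked,
                primer_pair=pair,
                length_class=length_class(locus),
                composition=composition_class(rep.motif),
            )
        )
    return markers


def deduplicate_markers(
    markers: Sequence[MarkerRecord],
) -> tuple[list[MarkerRecord], "object"]:
    """Drop markers whose designed primer pairs are redundant."""
    designed = [m for m in markers if m.primer_pair and m.primer_pair.status == "designed"]
    kept_pairs, report = deduplicate_primers([m.primer_pair for m in designed])
    kept_ids = {p.locus_id for p in kept_pairs}
    return [m for m in designed if m.marker_id in kept_ids], report


def evaluate_markers(
    markers: Sequence[MarkerRecord],
    reference: Sequence[SequenceRecord],
    genomes: dict[str, Sequence[SequenceRecord]] | None = None,
    te_library: Sequence | None = None,
    mature_mirnas: Sequence | None = None,
    annotations: dict[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> list[MarkerRecord]:
    """Physically map markers, run cross-taxon ePCR and association screens.

    Mutates and returns the marker list. Only uniquely mapped, non-compound
    markers enter the transferability matrix.
    """
    from .association import categorize_annotation

    config = config or PipelineConfig()
    mapping = physical_map(markers, reference, config)
    for m in markers:
        m.map_status, m.map_seq_id = mapping[m.marker_id]

    unique = [m for m in markers if m.map_status == "unique"]
    if genomes:
        matrix = transferability_matrix(unique, genomes, config)
        for m in unique:
            cells = [matrix.cells[(m.marker_id, g)] for g in matrix.genome_ids]
            m.transferable_count = sum(1 for c in cells if c != "no_hit")
            if any(c == "polymorphic" for c in cells):
                m.polymorphism = "polymorphic"
            elif any(c == "monomorphic" for c in cells):
                m.polymorphism = "monomorphic"

    for m in markers:
        if m.flanked is None:
            continue
        if te_library:
            m.te_associated = (
                te_association(
                    m.flanked, te_library,
                    min_identity=config.te_min_identity,
                    max_evalue=config.te_max_evalue,
                )
                is not None
            )
        if mature_mirnas:
            m.mirna_associated = bool(
                mirna_association(
                    m.flanked, mature_mirnas,
                    max_mismatches=config.mirna_max_mismatches,
                )
            )
        m.function_category = categorize_annotation(
            (annotations or {}).get(m.marker_id)
        )
    return list(markers)
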