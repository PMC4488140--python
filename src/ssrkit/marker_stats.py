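"""Marker-potential statistics from genotype data and the five-step
pre-selection filter.

Allele calls are treated as codominant allele sizes (bp). PIC uses the
Botstein et al. definition

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2,

with the simpler expected-heterozygosity form (1 - sum p_i^2) available by
switch. The cohort mean alleles-per-locus is truncated, not rounded, to
two decimals (1047 alleles over 243 loci prints as 4.30).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dna import truncate2


@dataclass
class GenotypeTable:
    """markers x accessions grid; each cell a tuple of allele sizes or None."""

    markers: list[str]
    accessions: list[str]
    calls: dict[tuple[str, str], tuple[int, ...] | None] = field(default_factory=dict)

    def alleles_of(self, marker_id: str) -> list[int]:
        if marker_id not in self.markers:
            raise KeyError(marker_id)
        out: list[int] = []
        for acc in self.accessions:
            cell = self.calls.get((marker_id, acc))
            if cell:
                out.extend(cell)
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for m in self.markers:
            for a in self.accessions:
                cell = self.calls.get((m, a))
                rows.append(
                    {
                        "marker": m,
                        "accession": a,
                        "alleles": ",".join(map(str, cell)) if cell else "",
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"alleles": str}, keep_default_na=False)
        markers: list[str] = []
        accessions: list[str] = []
        calls: dict[tuple[str, str], tuple[int, ...] | None] = {}
        for _, row in df.iterrows():
            m, a, cell = row["marker"], row["accession"], row["alleles"]
            if m not in markers:
                markers.append(m)
            if a not in accessions:
                accessions.append(a)
            calls[(m, a)] = (
                tuple(int(x) for x in cell.split(",")) if cell else None
            )
        return cls(markers=markers, accessions=accessions, calls=calls)


def allele_frequencies(table: GenotypeTable, marker_id: str) -> dict[int, float]:
    """Pooled allele frequencies for one marker across all accessions."""
    alleles = table.alleles_of(marker_id)
    if not alleles:
        raise ValueError(f"marker {marker_id}: all cells missing")
    total = len(alleles)
    counts: dict[int, int] = {}
    for a in alleles:
        counts[a] = counts.get(a, 0) + 1
    return {size: c / total for size, c in sorted(counts.items())}


def pic(frequencies: Sequence[float], method: str = "botstein") -> float:
    """Polymorphism information content of a frequency vector."""
    p = np.asarray(list(frequencies), dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    het = 1.0 - float(np.sum(p**2))
    if method == "simple":
        return het
    if method != "botstein":
        raise ValueError(f"unknown PIC method {method!r}")
    sq = p**2
    cross = (float(np.sum(sq)) ** 2 - float(np.sum(sq**2))) / 1.0  # 2*sum_{i<j} pi^2 pj^2
    return het - cross


@dataclass
class MarkerPotential:
    marker_id: str
    n_alleles: int
    frequencies: dict[int, float]
    pic: float
    polymorphic: bool
    transferable: bool  # amplified in >= 1 non-source accession


@dataclass
class CohortSummary:
    markers_tested: int
    markers_amplified: int
    markers_polymorphic: int
    total_alleles_polymorphic: int
    mean_alleles_per_locus: float  # truncated to 2 decimals
    allele_count_min: int
    allele_count_max: int
    pic_min: float
    pic_max: float
    pic_mean: float


def summarize_genotypes(
    table: GenotypeTable, pic_method: str = "botstein"
) -> tuple[dict[str, MarkerPotential], CohortSummary]:
    """Per-marker potential plus the cohort summary.

    A marker is amplified when at least one accession has a call,
    polymorphic when it shows >= 2 distinct alleles. Allele totals, the
    mean alleles/locus and the PIC range are reported over the polymorphic
    markers, matching standard wet-lab reporting.
    """
    if not table.markers:
        raise ValueError("empty genotype table")
    potentials: dict[str, MarkerPotential] = {}
    for m in table.markers:
        cells = [
            table.calls.get((m, a)) for a in table.accessions
        ]
        amplified = [c for c in cells if c]
        if not amplified:
            continue
        freqs = allele_frequencies(table, m)
        n_alleles = len(freqs)
        potentials[m] = MarkerPotential(
            marker_id=m,
            n_alleles=n_alleles,
            frequencies=freqs,
            pic=pic(list(freqs.values()), method=pic_method),
            polymorphic=n_alleles >= 2,
            transferable=len(amplified) >= 2,
        )
    poly = [p for p in potentials.values() if p.polymorphic]
    total_alleles = sum(p.n_alleles for p in poly)
    pics = [p.pic for p in poly]
    summary = CohortSummary(
        markers_tested=len(table.markers),
        markers_amplified=len(potentials),
        markers_polymorphic=len(poly),
        total_alleles_polymorphic=total_alleles,
        mean_alleles_per_locus=(
            truncate2(total_alleles / len(poly)) if poly else 0.0
        ),
        allele_count_min=min((p.n_alleles for p in poly), default=0),
        allele_count_max=max((p.n_alleles for p in poly), default=0),
        pic_min=min(pics, default=0.0),
        pic_max=max(pics, default=0.0),
        pic_mean=(sum(pics) / len(pics)) if pics else 0.0,
    )
    return potentials, summary


def pic_histogram(
    potentials: dict[str, MarkerPotential], bin_width: float = 0.1
) -> dict[str, int]:
    """PIC distribution bins (for the polymorphic markers)."""
    bins: dict[str, int] = {}
    edges = np.arange(0.0, 1.0 + 1e-9, bin_width)
    for p in potentials.values():
        if not p.polymorphic:
            continue
        idx = min(int(p.pic / bin_width), len(edges) - 2)
        label = f"{edges[idx]:.1f}-{edges[idx + 1]:.1f}"
        bins[label] = bins.get(label, 0) + 1
    return dict(sorted(bins.items()))


@dataclass
class SelectionReport:
    input_count: int
    removed_multi_or_no_hit: int = 0
    removed_not_transferable: int = 0
    removed_monomorphic: int = 0
    removed_te_associated: int = 0
    selected: int = 0


def select_markers(markers: Sequence, report: SelectionReport | None = None):
    """Apply the five pre-selection criteria in order.

    (i) a single hit on the reference genome; (ii) transferability to at
    least one other taxon; (iii) in-silico polymorphism; (iv) no
    transposon association; (v) priority (a sort key, not a filter) for
    markers with a functional annotation. Returns the filtered, ranked
    list; the report counts removals per criterion.
    """
    if report is None:
        report = SelectionReport(input_count=len(markers))
    else:
        report.input_count = len(markers)
    stage = [m for m in markers if m.map_status == "unique"]
    report.removed_multi_or_no_hit = len(markers) - len(stage)
    stage2 = [m for m in stage if m.transferable_count >= 1]
    report.removed_not_transferable = len(stage) - len(stage2)
    stage3 = [m for m in stage2 if m.polymorphism == "polymorphic"]
    report.removed_monomorphic = len(stage2) - len(stage3)
    stage4 = [m for m in stage3 if not m.te_associated]
    report.removed_te_associated = len(stage3) - len(stage4)
    functional = {"non_functional", "", None}
    ranked = sorted(
        stage4,
        key=lambda m: (m.function_category in functional, m.marker_id),
    )
    report.selected = len(ranked)
    return ranked, report
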