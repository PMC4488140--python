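"""Attribute classification of SSR loci and cross-dataset summary tables.

Loci are classified along three axes: length class (Class I, tract >= 20 bp,
vs Class II), motif base composition (AT-rich / GC-rich / balanced at an
exact A+T fraction of one half), and repeat class (motif period 2-6).
Per-dataset tables carry counts plus integer percentages; the overall
column is the unweighted arithmetic mean of the per-dataset integer
percentages — the convention consistent with the printed study tables,
where pooled counts would give a different dinucleotide share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dna import round_half_away
from .repeat_scan import PERIODS, SSRLocus

CLASS_I_MIN_BP = 20  # tracts of exactly 20 bp are Class I

REPEAT_CLASS_NAMES = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


def length_class(locus: SSRLocus) -> str:
    """ClassI for tracts of >= 20 bp, ClassII below."""
    return "ClassI" if locus.tract_length >= CLASS_I_MIN_BP else "ClassII"


def composition_class(motif: str) -> str:
    """AT-rich / GC-rich / balanced from the motif's base counts."""
    at = sum(motif.count(b) for b in "AT")
    frac = at / len(motif)
    if frac > 0.5:
        return "AT-rich"
    if frac < 0.5:
        return "GC-rich"
    return "balanced"


def percent_of(part: int, whole: int) -> int:
    """Integer percentage, rounded half away from zero (528/1850 -> 29)."""
    if whole == 0:
        return 0
    return round_half_away(100 * part / whole)


@dataclass
class DatasetSummary:
    """Classification counts and integer percentages for one dataset."""

    dataset_tag: str
    total: int
    repeat_class_counts: dict[int, int] = field(default_factory=dict)
    repeat_class_percent: dict[int, int] = field(default_factory=dict)
    motif_counts: dict[str, int] = field(default_factory=dict)
    length_class_counts: dict[str, int] = field(default_factory=dict)
    length_class_percent: dict[str, int] = field(default_factory=dict)
    composition_counts: dict[str, int] = field(default_factory=dict)
    composition_percent: dict[str, int] = field(default_factory=dict)
    kbp_per_ssr: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in PERIODS:
            rows.append(
                {
                    "axis": "repeat_class",
                    "key": REPEAT_CLASS_NAMES[p],
                    "count": self.repeat_class_counts.get(p, 0),
                    "percent": self.repeat_class_percent.get(p, 0),
                }
            )
        for key in ("ClassI", "ClassII"):
            rows.append(
                {
                    "axis": "length_class",
                    "key": key,
                    "count": self.length_class_counts.get(key, 0),
                    "percent": self.length_class_percent.get(key, 0),
                }
            )
        for key in ("AT-rich", "GC-rich", "balanced"):
            rows.append(
                {
                    "axis": "composition",
                    "key": key,
                    "count": self.composition_counts.get(key, 0),
                    "percent": self.composition_percent.get(key, 0),
                }
            )
        for motif, count in sorted(self.motif_counts.items()):
            rows.append(
                {"axis": "motif", "key": motif, "count": count,
                 "percent": percent_of(count, self.total)}
            )
        df = pd.DataFrame(rows, columns=["axis", "key", "count", "percent"])
        df.insert(0, "dataset", self.dataset_tag)
        return df


def _classification_units(loci: list[SSRLocus]) -> list[SSRLocus]:
    """Expand compound loci into members for motif/class tallies.

    Compound events count once in dataset totals, but their member motifs
    contribute individually to the per-motif and per-period tables.
    """
    units: list[SSRLocus] = []
    for loc in loci:
        if loc.is_compound:
            units.extend(loc.members)
        else:
            units.append(loc)
    return units


def tabulate_dataset(
    loci: list[SSRLocus],
    dataset_tag: str,
    kbp_per_ssr: int | None = None,
) -> DatasetSummary:
    """Count and percentage every classification axis for one dataset."""
    units = _classification_units(loci)
    total = len(units)
    summary = DatasetSummary(dataset_tag=dataset_tag, total=total,
                             kbp_per_ssr=kbp_per_ssr)
    for u in units:
        summary.repeat_class_counts[u.period] = (
            summary.repeat_class_counts.get(u.period, 0) + 1
        )
        summary.motif_counts[u.canonical_motif] = (
            summary.motif_counts.get(u.canonical_motif, 0) + 1
        )
        lc = length_class(u)
        summary.length_class_counts[lc] = summary.length_class_counts.get(lc, 0) + 1
        cc = composition_class(u.motif)
        summary.composition_counts[cc] = summary.composition_counts.get(cc, 0) + 1
    summary.repeat_class_percent = {
        p: percent_of(c, total) for p, c in summary.repeat_class_counts.items()
    }
    summary.length_class_percent = {
        k: percent_of(c, total) for k, c in summary.length_class_counts.items()
    }
    summary.composition_percent = {
        k: percent_of(c, total) for k, c in summary.composition_counts.items()
    }
    return summary


def combine_percentages(percentages: list[int | float]) -> int:
    """Unweighted mean of per-dataset integer percentages, half away from zero."""
    if not percentages:
        raise ValueError("no percentages to combine")
    return round_half_away(sum(percentages) / len(percentages))


def combine_summaries(summaries: list[DatasetSummary]) -> dict:
    """The overall column: unweighted means of the per-dataset percentages."""
    if not summaries:
        raise ValueError("need at least one summary")
    overall: dict = {"dataset_tag": "overall"}
    overall["repeat_class_percent"] = {
        p: combine_percentages(
            [s.repeat_class_percent.get(p, 0) for s in summaries]
        )
        for p in PERIODS
    }
    overall["length_class_percent"] = {
        k: combine_percentages(
            [s.length_class_percent.get(k, 0) for s in summaries]
        )
        for k in ("ClassI", "ClassII")
    }
    overall["composition_percent"] = {
        k: combine_percentages(
            [s.composition_percent.get(k, 0) for s in summaries]
        )
        for k in ("AT-rich", "GC-rich", "balanced")
    }
    densities = [s.kbp_per_ssr for s in summaries if s.kbp_per_ssr is not None]
    overall["kbp_per_ssr"] = combine_percentages(densities) if densities else None
    return overall
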