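"""Perfect microsatellite detection and density summaries.

The scanner reports maximal perfect tracts of di- to hexanucleotide motifs
(MISA-style): a tract qualifies when it reaches the configured minimum
number of complete repeat units for its period (6/5/5/4/4 for periods
2/3/4/5/6), is reported once under its smallest (primitive) period, and is
truncated to whole units. N breaks a tract; mononucleotide runs are not
searched. Immediately adjacent tracts of different motifs (zero-gap) are
merged into compound loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import is_primitive, revcomp, round_half_away
from .io_formats import PipelineConfig, SequenceRecord

PERIODS = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class SSRLocus:
    """One detected perfect (or compound) repeat tract.

    Coordinates are 0-based half-open on the source sequence. For simple
    loci ``end - start == period * repeat_units``. Compound loci keep their
    member tracts in order; their motif fields describe the joined event.
    """

    locus_id: str
    seq_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    period: int
    repeat_units: int
    is_compound: bool = False
    members: tuple = ()

    @property
    def tract_length(self) -> int:
        return self.end - self.start

    @classmethod
    def simple(cls, locus_id, seq_id, start, end, motif, repeat_units) -> "SSRLocus":
        period = len(motif)
        if end - start != period * repeat_units:
            raise ValueError(f"{locus_id}: tract length != period * units")
        return cls(
            locus_id=locus_id,
            seq_id=seq_id,
            start=start,
            end=end,
            motif=motif,
            canonical_motif=canonical_motif(motif),
            period=period,
            repeat_units=repeat_units,
            is_compound=False,
        )

    @classmethod
    def compound(cls, locus_id, members) -> "SSRLocus":
        members = tuple(members)
        if len(members) < 2:
            raise ValueError("compound locus needs >= 2 members")
        for a, b in zip(members, members[1:]):
            if a.end != b.start:
                raise ValueError("compound members must abut (zero gap)")
        return cls(
            locus_id=locus_id,
            seq_id=members[0].seq_id,
            start=members[0].start,
            end=members[-1].end,
            motif="-".join(m.motif for m in members),
            canonical_motif="-".join(m.canonical_motif for m in members),
            period=0,
            repeat_units=0,
            is_compound=True,
            members=members,
        )


def canonical_motif(motif: str) -> str:
    """Family representative of a repeat motif.

    The lexicographically smallest string among all cyclic rotations of the
    motif and all cyclic rotations of its reverse complement, so e.g. TC,
    CT, GA and AG all map to AG. Idempotent by construction.
    """
    if "N" in motif:
        raise ValueError("motif contains N")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = revcomp(motif)
    n = len(motif)
    candidates = [motif[i:] + motif[:i] for i in range(n)]
    candidates += [rc[i:] + rc[:i] for i in range(n)]
    return min(candidates)


def find_perfect_ssrs(
    record: SequenceRecord, config: PipelineConfig | None = None
) -> list[SSRLocus]:
    """Detect all maximal perfect SSR tracts in one sequence.

    For each period p, positions where ``seq[i] == seq[i+p]`` (both
    unambiguous bases) form match runs; a run covering region [i, j+p)
    yields ``units = floor((j+p-i)/p)`` complete repeat units anchored at
    the run start. The region is reported iff units reaches the period's
    minimum and its leading ``p`` bases form a primitive motif — a
    lower-period tract seen at a multiple of its true period has a
    non-primitive leading unit and is skipped, which enforces the
    smallest-period rule. Loci are returned sorted by start.
    """
    config = config or PipelineConfig()
    seq = record.seq
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    loci: list[SSRLocus] = []
    for p in PERIODS:
        min_units = config.min_repeat_units[p]
        if n < p * min_units:
            continue
        match = (arr[:-p] == arr[p:]) & valid[:-p] & valid[p:]
        # boundaries of True runs in `match`
        padded = np.concatenate(([False], match, [False]))
        diffs = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diffs == 1)
        ends = np.flatnonzero(diffs == -1)  # run is match[s:e]
        for s, e in zip(starts, ends):
            region_len = (e - s) + p  # tract region [s, e+p)
            units = region_len // p
            if units < min_units:
                continue
            motif = seq[s : s + p]
            if not is_primitive(motif):
                continue
            loci.append(
                SSRLocus.simple(
                    locus_id="",  # assigned after sorting
                    seq_id=record.id,
                    start=int(s),
                    end=int(s + units * p),
                    motif=motif,
                    repeat_units=int(units),
                )
            )
    loci.sort(key=lambda l: (l.start, l.period))
    return [
        SSRLocus.simple(
            locus_id=f"{record.id}.ssr{i + 1}",
            seq_id=l.seq_id,
            start=l.start,
            end=l.end,
            motif=l.motif,
            repeat_units=l.repeat_units,
        )
        for i, l in enumerate(loci)
    ]


def merge_compound(loci: list[SSRLocus]) -> list[SSRLocus]:
    """Merge maximal runs of zero-gap adjacent loci into compound loci.

    Input must be simple loci from one sequence, sorted and non-overlapping
    (overlap is a scanner-bug signal and raises). Loci separated by even a
    single base pass through unchanged.
    """
    for a, b in zip(loci, loci[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping loci {a.locus_id} / {b.locus_id}")
    out: list[SSRLocus] = []
    i = 0
    while i < len(loci):
        j = i
        while j + 1 < len(loci) and loci[j + 1].start == loci[j].end:
            j += 1
        if j > i:
            members = loci[i : j + 1]
            out.append(SSRLocus.compound(members[0].locus_id + "c", members))
        else:
            out.append(loci[i])
        i = j + 1
    return out


@dataclass
class DensityStats:
    """Per-dataset SSR isolation summary (one column of the study's Table 1)."""

    dataset_tag: str
    total_ssrs: int
    sequences_examined: int
    total_bp: int
    sequences_with_ssr: int
    sequences_with_multiple_ssr: int
    compound_count: int  # compound events (counted once each in total_ssrs)
    compound_member_count: int  # simple tracts participating in compounds
    kbp_per_ssr: int | None
    ssr_per_mbp: float | None


def density_from_counts(total_bp: int, total_ssrs: int) -> int | None:
    """kbp of sequence per SSR, rounded half away from zero; None if no SSRs."""
    if total_ssrs == 0:
        return None
    return round_half_away(total_bp / 1000 / total_ssrs)


def summarize_density(
    loci: list[SSRLocus],
    dataset: list[SequenceRecord],
    dataset_tag: str | None = None,
) -> DensityStats:
    """Fill the per-dataset isolation statistics from scanned loci.

    Compound events are counted once in the total and additionally tallied
    in the compound row.
    """
    tag = dataset_tag or (dataset[0].dataset_tag if dataset else "other")
    total_bp = sum(len(r) for r in dataset)
    per_seq: dict[str, int] = {}
    compound = 0
    compound_members = 0
    for loc in loci:
        per_seq[loc.seq_id] = per_seq.get(loc.seq_id, 0) + 1
        if loc.is_compound:
            compound += 1
            compound_members += len(loc.members)
    total = len(loci)
    return DensityStats(
        dataset_tag=tag,
        total_ssrs=total,
        sequences_examined=len(dataset),
        total_bp=total_bp,
        sequences_with_ssr=len(per_seq),
        sequences_with_multiple_ssr=sum(1 for v in per_seq.values() if v > 1),
        compound_count=compound,
        compound_member_count=compound_members,
        kbp_per_ssr=density_from_counts(total_bp, total),
        ssr_per_mbp=(total / (total_bp / 1e6)) if total and total_bp else None,
    )
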