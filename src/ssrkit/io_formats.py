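"""Sequence and table input/output plus the pipeline configuration.

All internal coordinates are 0-based half-open; everything serialized
(GFF3, marker tables) is 1-based inclusive per the GFF3 convention.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("ssrkit")

DATASET_TAGS = ("AA", "BB", "EST", "GSS", "other")

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with its dataset provenance tag."""

    id: str
    seq: str
    dataset_tag: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, defaulting to the study values.

    min_repeat_units maps motif period (2-6) to the minimum number of
    repeat units a perfect tract must reach: six for dinucleotides, five
    for tri- and tetranucleotides, four for penta- and hexanucleotides.
    """

    min_repeat_units: dict[int, int] = field(
        default_factory=lambda: {2: 6, 3: 5, 4: 5, 5: 4, 6: 4}
    )
    flank_length: int = 200
    # primer constraints (simplified primer3-style design)
    primer_min_len: int = 18
    primer_max_len: int = 24
    tm_min: float = 55.0
    tm_max: float = 60.0
    gc_min: float = 40.0
    gc_max: float = 60.0
    product_min: int = 100
    product_max: int = 400
    # electronic PCR budgets
    epcr_max_mismatches: int = 3
    epcr_max_gaps: int = 2
    epcr_anchor3: int = 2
    epcr_max_product: int = 5000
    # marker evaluation
    polymorphism_threshold: int = 10
    te_min_identity: float = 65.0
    te_max_evalue: float = 1e-10
    mirna_max_mismatches: int = 4
    hairpin_min_paired_fraction: float = 0.55
    hairpin_min_mature_paired: float = 0.60
    # EST cleanup
    est_min_tail: int = 8
    est_min_keep: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for period, units in self.min_repeat_units.items():
            if period < 2 or period > 6 or units < 2:
                raise ValueError(f"bad min_repeat_units entry {period}:{units}")
        for name in (
            "flank_length", "primer_min_len", "primer_max_len", "tm_min",
            "tm_max", "gc_min", "gc_max", "product_min", "product_max",
            "epcr_max_product", "polymorphism_threshold", "te_min_identity",
            "te_max_evalue", "est_min_tail", "est_min_keep",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "min_repeat_units" in raw:
            raw["min_repeat_units"] = {
                int(k): int(v) for k, v in raw["min_repeat_units"].items()
            }
        return cls(**raw)


def read_fasta(path: str | Path, dataset_tag: str = "other") -> list[SequenceRecord]:
    """Read a multi-FASTA file into SequenceRecords.

    Sequences are uppercased; ambiguity codes other than N are coerced to
    N (count logged). Duplicate ids are a hard error naming the id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    coerced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        seq, n_sub = _NON_ACGTN.subn("N", seq)
        coerced += n_sub
        records.append(SequenceRecord(id=rec.id, seq=seq, dataset_tag=dataset_tag))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if coerced:
        logger.warning("%s: coerced %d non-ACGTN characters to N", path, coerced)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# EST end cleanup
# ---------------------------------------------------------------------------

@dataclass
class TrimReport:
    kept: int = 0
    dropped: int = 0
    bases_removed: int = 0


def trim_est(
    record: SequenceRecord,
    min_tail: int = 8,
    min_keep: int = 100,
    report: TrimReport | None = None,
) -> SequenceRecord | None:
    """Strip terminal poly-A (3'), poly-T (5') and N runs from an EST read.

    Homopolymer tails are removed only when the terminal run reaches
    ``min_tail`` bases; terminal N runs are always removed. Runs are
    stripped repeatedly until the sequence is stable, so the operation is
    idempotent. Returns None (a reported outcome, not an error) when the
    cleaned sequence is shorter than ``min_keep``.
    """
    seq = record.seq
    while True:
        before = seq
        seq = seq.strip("N")
        m = re.search(r"A+$", seq)
        if m and len(m.group()) >= min_tail:
            seq = seq[: m.start()]
        m = re.match(r"^T+", seq)
        if m and len(m.group()) >= min_tail:
            seq = seq[m.end() :]
        if seq == before:
            break
    if report is not None:
        report.bases_removed += len(record.seq) - len(seq)
    if len(seq) < min_keep:
        if report is not None:
            report.dropped += 1
        return None
    if report is not None:
        report.kept += 1
    return SequenceRecord(id=record.id, seq=seq, dataset_tag=record.dataset_tag)


# ---------------------------------------------------------------------------
# GFF3 serialization of SSR loci
# ---------------------------------------------------------------------------

def write_ssr_gff3(loci: Sequence, path: str | Path) -> None:
    """Write SSR loci as GFF3 ``microsatellite`` features (1-based inclusive).

    Compound loci carry their members in a ``members`` attribute encoded as
    ``motif|start|end|units`` 1-based segments joined by commas, so the file
    round-trips through :func:`read_ssr_gff3`.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = [f"ID={loc.locus_id}"]
            if loc.is_compound:
                members = ",".join(
                    f"{m.motif}|{m.start + 1}|{m.end}|{m.repeat_units}"
                    for m in loc.members
                )
                attrs.append("compound=true")
                attrs.append(f"members={members}")
            else:
                attrs.append(f"motif={loc.motif}")
                attrs.append(f"canonical_motif={loc.canonical_motif}")
                attrs.append(f"repeat_units={loc.repeat_units}")
                attrs.append(f"period={loc.period}")
            fh.write(
                "\t".join(
                    (
                        loc.seq_id,
                        "ssrkit",
                        "microsatellite",
                        str(loc.start + 1),
                        str(loc.end),
                        ".",
                        "+",
                        ".",
                        ";".join(attrs),
                    )
                )
                + "\n"
            )


def read_ssr_gff3(path: str | Path) -> list:
    """Parse a file written by :func:`write_ssr_gff3` back into SSRLocus objects."""
    from .repeat_scan import SSRLocus  # local import avoids a cycle

    loci = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        seq_id, _, ftype, start, end, _, _, _, attr_s = cols
        if ftype != "microsatellite":
            continue
        attrs = dict(kv.split("=", 1) for kv in attr_s.split(";"))
        start0, end0 = int(start) - 1, int(end)
        if attrs.get("compound") == "true":
            members = []
            for tok in attrs["members"].split(","):
                motif, ms, me, mu = tok.split("|")
                members.append(
                    SSRLocus.simple(
                        locus_id=f"{attrs['ID']}.m{len(members) + 1}",
                        seq_id=seq_id,
                        start=int(ms) - 1,
                        end=int(me),
                        motif=motif,
                        repeat_units=int(mu),
                    )
                )
            loci.append(SSRLocus.compound(attrs["ID"], members))
        else:
            loci.append(
                SSRLocus.simple(
                    locus_id=attrs["ID"],
                    seq_id=seq_id,
                    start=start0,
                    end=end0,
                    motif=attrs["motif"],
                    repeat_units=int(attrs["repeat_units"]),
                )
            )
    return loci


# ---------------------------------------------------------------------------
# Marker table serialization
# ---------------------------------------------------------------------------

MARKER_COLUMNS = [
    "marker_id",
    "seq_id",
    "start",
    "end",
    "motif",
    "canonical_motif",
    "period",
    "repeat_units",
    "length_class",
    "composition",
    "is_compound",
    "forward",
    "reverse",
    "tm_forward",
    "tm_reverse",
    "expected_product",
    "primer_status",
    "map_status",
    "transferable_count",
    "polymorphism",
    "te_associated",
    "mirna_associated",
    "function_category",
]


def write_marker_table(markers: Sequence, path: str | Path) -> None:
    """Write evaluated markers as a tab-delimited table (1-based coordinates)."""
    rows = []
    for m in markers:
        loc = m.locus
        pp = m.primer_pair
        rows.append(
            {
                "marker_id": m.marker_id,
                "seq_id": loc.seq_id,
                "start": loc.start + 1,
                "end": loc.end,
                "motif": loc.motif,
                "canonical_motif": loc.canonical_motif,
                "period": loc.period,
                "repeat_units": loc.repeat_units,
                "length_class": m.length_class or "",
                "composition": m.composition or "",
                "is_compound": loc.is_compound,
                "forward": pp.forward if pp and pp.status == "designed" else "",
                "reverse": pp.reverse if pp and pp.status == "designed" else "",
                "tm_forward": pp.tm_forward if pp and pp.status == "designed" else "",
                "tm_reverse": pp.tm_reverse if pp and pp.status == "designed" else "",
                "expected_product": (
                    pp.expected_product if pp and pp.status == "designed" else ""
                ),
                "primer_status": pp.status if pp else "failed(insufficient_flank)",
                "map_status": m.map_status or "",
                "transferable_count": m.transferable_count,
                "polymorphism": m.polymorphism or "",
                "te_associated": m.te_associated,
                "mirna_associated": m.mirna_associated,
                "function_category": m.function_category or "",
            }
        )
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"forward": str, "reverse": str})
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    return df
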