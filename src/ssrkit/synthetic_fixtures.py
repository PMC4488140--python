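"""Reproducible synthetic inputs for every pipeline stage.

Generates random background genomes at a chosen GC content, plants SSR
tracts, protein-coding transposable-element fragments and pre-miRNA
hairpins at known positions (with an exact truth table), produces diverged
genome copies for transferability experiments, and samples diploid
genotype tables from known allele frequencies. A single seed governs all
randomness.

The default whole-pipeline fixture emulates the study conditions at desk
scale: a 1 Mbp genome at GC 0.39 (Musa-like) carrying 200 planted SSRs
spanning all periods and both length classes, 10 TE fragments and 10
hairpins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dna import revcomp
from .io_formats import PipelineConfig, SequenceRecord
from .marker_stats import GenotypeTable
from .repeat_scan import find_perfect_ssrs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# one codon per amino acid keeps reverse translation deterministic
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class PlantSpec:
    """One element to plant: an SSR tract, a TE fragment or a pre-miRNA hairpin."""

    kind: str  # "ssr" | "te_fragment" | "mirna_hairpin"
    position: int
    # ssr
    motif: str = ""
    units: int = 0
    # te_fragment
    protein: str = ""
    te_family: str = ""
    # mirna_hairpin
    stem_len: int = 0
    loop_len: int = 0
    mature: str = ""
    mature_offset: int = 0  # offset of the mature site within the planted window

    def payload(self) -> str:
        if self.kind == "ssr":
            return self.motif * self.units
        if self.kind == "te_fragment":
            return "".join(_CODON[a] for a in self.protein)
        if self.kind == "mirna_hairpin":
            return _hairpin_payload(self)
        raise ValueError(f"unknown plant kind {self.kind!r}")


def _hairpin_payload(spec: PlantSpec) -> str:
    """Perfect inverted repeat: 5' arm (contains the mature site), loop, 3' arm."""
    arm = spec.mature
    pad = spec.stem_len - len(arm)
    if pad < 0:
        raise ValueError("stem shorter than mature sequence")
    rng = np.random.default_rng(abs(hash((spec.mature, spec.position))) % 2**31)
    left_pad = "".join("ACGT"[i] for i in rng.integers(0, 4, spec.mature_offset))
    right_pad = "".join(
        "ACGT"[i] for i in rng.integers(0, 4, pad - spec.mature_offset)
    )
    arm5 = left_pad + arm + right_pad
    loop = "".join("ACGT"[i] for i in rng.integers(0, 4, spec.loop_len))
    return arm5 + loop + revcomp(arm5)


@dataclass
class TruthRow:
    kind: str
    seq_id: str
    start: int
    end: int
    detail: str


@dataclass
class TruthTable:
    genome_seed: int
    gc: float
    rows: list[TruthRow] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[TruthRow]:
        return [r for r in self.rows if r.kind == kind]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.rows])
        with open(path, "w") as fh:
            fh.write(f"# genome_seed={self.genome_seed} gc={self.gc}\n")
            df.to_csv(fh, sep="\t", index=False)


def generate_genome(
    length: int,
    gc: float = 0.39,
    seed: int = 0,
    repeat_free: bool = False,
    config: PipelineConfig | None = None,
    seq_id: str = "synthetic",
    dataset_tag: str = "other",
) -> SequenceRecord:
    """I.i.d. background genome with P(G)+P(C) = gc.

    With ``repeat_free`` set, windows containing qualifying SSR tracts are
    redrawn until the scanner reports none, so the background can serve as
    a zero-false-positive substrate.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = _BASES[rng.choice(4, size=length, p=probs)]
    record = SequenceRecord(
        id=seq_id, seq=arr.tobytes().decode(), dataset_tag=dataset_tag
    )
    if repeat_free:
        config = config or PipelineConfig()
        for _ in range(100):
            loci = find_perfect_ssrs(record, config)
            if not loci:
                break
            for loc in loci:
                arr[loc.start : loc.end] = _BASES[
                    rng.choice(4, size=loc.tract_length, p=probs)
                ]
            record = SequenceRecord(
                id=seq_id, seq=arr.tobytes().decode(), dataset_tag=dataset_tag
            )
        else:
            raise RuntimeError("could not clear accidental SSRs")
    return record


def plant_elements(
    genome: SequenceRecord, specs: Sequence[PlantSpec], gc: float = 0.39,
    seed: int = 0,
) -> tuple[SequenceRecord, TruthTable]:
    """Overwrite the background with each spec's payload; exact truth table.

    Overlapping specs are a hard error. For SSR payloads one guard base on
    each side of the tract is set to a base that cannot continue the
    repeat, so the planted coordinates are exactly the maximal tract the
    scanner reports.
    """
    intervals = []
    for spec in specs:
        payload = spec.payload()
        intervals.append((spec.position, spec.position + len(payload), spec, payload))
    intervals.sort()
    for (s1, e1, *_), (s2, _, *_) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(f"planted elements overlap at {s2}")
    seq = list(genome.seq)
    truth = TruthTable(genome_seed=seed, gc=gc)
    for start, end, spec, payload in intervals:
        if end > len(seq):
            raise ValueError(f"element at {start} exceeds genome bounds")
        seq[start:end] = payload
        if spec.kind == "ssr":
            # guard bases: break the same-period match at both boundaries
            p = len(spec.motif)
            if start > 0:
                seq[start - 1] = next(
                    b for b in "ACGT" if b != spec.motif[p - 1]
                )
            if end < len(seq):
                seq[end] = next(b for b in "ACGT" if b != spec.motif[0])
            detail = f"motif={spec.motif};units={spec.units}"
        elif spec.kind == "te_fragment":
            detail = f"family={spec.te_family};codons={len(spec.protein)}"
        else:
            detail = (
                f"stem={spec.stem_len};loop={spec.loop_len};"
                f"mature={spec.mature};mature_offset={spec.mature_offset}"
            )
        truth.rows.append(
            TruthRow(kind=spec.kind, seq_id=genome.id, start=start, end=end,
                     detail=detail)
        )
    return (
        SequenceRecord(
            id=genome.id, seq="".join(seq), dataset_tag=genome.dataset_tag
        ),
        truth,
    )


def diverge_genome(
    genome: SequenceRecord,
    sub_rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> SequenceRecord:
    """Point-substituted (and optionally indel-bearing) copy of a genome.

    Substitutions are uniform over the three alternative bases; indels
    initiate per-base with geometric length (mean 2), insertion or
    deletion with equal probability.
    """
    if not 0 <= sub_rate <= 0.5 or not 0 <= indel_rate <= 0.5:
        raise ValueError("rates must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    if sub_rate > 0:
        hit = np.flatnonzero(rng.random(n) < sub_rate)
        # uniform over the 3 other bases: index shift 1..3 in base order
        idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(idx + shift) % 4]
    seq = arr.tobytes().decode()
    if indel_rate > 0:
        pieces: list[str] = []
        pos = 0
        events = np.flatnonzero(rng.random(n) < indel_rate)
        for e in events:
            if e < pos:
                continue
            length = int(rng.geometric(0.5))
            pieces.append(seq[pos:e])
            if rng.random() < 0.5:  # insertion
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
                pieces.append(ins + seq[e])
                pos = e + 1
            else:  # deletion
                pos = e + length
        pieces.append(seq[pos:])
        seq = "".join(pieces)
    return SequenceRecord(
        id=genome.id, seq=seq, dataset_tag=genome.dataset_tag
    )


def generate_genotypes(
    marker_freqs: dict[str, dict[int, float]],
    n_accessions: int,
    seed: int = 0,
) -> GenotypeTable:
    """Diploid genotype table sampled i.i.d. from known allele frequencies."""
    rng = np.random.default_rng(seed)
    accessions = [f"acc{i + 1}" for i in range(n_accessions)]
    table = GenotypeTable(markers=list(marker_freqs), accessions=accessions)
    for marker, freqs in marker_freqs.items():
        sizes = np.array(list(freqs.keys()))
        probs = np.array(list(freqs.values()), dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"{marker}: frequencies must sum to 1")
        for acc in accessions:
            pair = rng.choice(sizes, size=2, p=probs)
            table.calls[(marker, acc)] = tuple(sorted(int(x) for x in pair))
    return table


# ---------------------------------------------------------------------------
# Library generators and the default whole-pipeline fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """Minimal FASTA-like protein entry (duck-typed against Bio.SeqRecord)."""

    id: str
    seq: str
    description: str = ""


def make_te_library(
    n: int = 5, n_codons: int = 120, seed: int = 0
) -> list[ProteinRecord]:
    """Random protein library with Class/Family headers (LTR/Copia etc.)."""
    rng = np.random.default_rng(seed)
    families = ["LTR/Copia", "LTR/Gypsy", "DNA/hAT", "DNA/MuDR", "LINE/L1"]
    out = []
    for i in range(n):
        prot = "".join(_AA[j] for j in rng.integers(0, len(_AA), n_codons))
        fam = families[i % len(families)]
        out.append(
            ProteinRecord(id=f"TE{i + 1:04d}", seq=prot, description=fam)
        )
    return out


def make_mature_mirnas(
    n: int = 5, length: int = 21, seed: int = 0
) -> list[ProteinRecord]:
    """Random mature miRNA set (DNA alphabet, 18-26 nt)."""
    rng = np.random.default_rng(seed)
    return [
        ProteinRecord(
            id=f"mir{i + 1:03d}",
            seq="".join("ACGT"[j] for j in rng.integers(0, 4, length)),
        )
        for i in range(n)
    ]


def default_ssr_specs(
    genome_length: int, n_ssrs: int = 200, seed: int = 0, spacing: int = 1200
) -> list[PlantSpec]:
    """SSR plant specs spanning all periods and both length classes."""
    rng = np.random.default_rng(seed)
    motifs = {
        2: ["AT", "AG", "AC", "CG"],
        3: ["AAT", "AAG", "AGG", "ACG"],
        4: ["AAAT", "AGAT", "ACGT"[:4], "AGGC"],
        5: ["AAAAT", "AATAT", "AGAGG"],
        6: ["AATAAG", "ACATAT", "AAGAGG"],
    }
    min_units = {2: 6, 3: 5, 4: 5, 5: 4, 6: 4}
    specs: list[PlantSpec] = []
    pos = spacing
    for i in range(n_ssrs):
        period = [2, 3, 4, 5, 6][i % 5]
        motif = motifs[period][i % len(motifs[period])]
        # alternate short (Class II) and long (Class I) tracts
        extra = int(rng.integers(0, 3)) if i % 2 == 0 else int(rng.integers(5, 10))
        units = min_units[period] + extra
        specs.append(PlantSpec(kind="ssr", position=pos, motif=motif, units=units))
        pos += spacing + period * units
        if pos > genome_length - spacing:
            break
    return specs


@dataclass
class PipelineFixture:
    genome: SequenceRecord
    truth: TruthTable
    te_library: list[ProteinRecord]
    mature_mirnas: list[ProteinRecord]


def make_pipeline_fixture(
    genome_length: int = 1_000_000,
    gc: float = 0.39,
    n_ssrs: int = 200,
    n_te: int = 10,
    n_hairpins: int = 10,
    seed: int = 0,
) -> PipelineFixture:
    """The default end-to-end fixture: repeat-free background plus planted
    SSRs, TE fragments next to dedicated SSRs, and pre-miRNA hairpins."""
    background = generate_genome(
        genome_length, gc=gc, seed=seed, repeat_free=True, seq_id="chr1"
    )
    te_library = make_te_library(n=max(n_te, 1), seed=seed + 1)
    mirnas = make_mature_mirnas(n=max(n_hairpins, 1), seed=seed + 2)
    specs = default_ssr_specs(genome_length, n_ssrs=n_ssrs, seed=seed + 3)
    rng = np.random.default_rng(seed + 4)
    n_ssr_specs = len(specs)
    n_te = min(n_te, n_ssr_specs // 2)
    n_hairpins = min(n_hairpins, n_ssr_specs - n_te)
    # TE fragments 30 bp downstream of the first n_te planted SSRs
    for i in range(n_te):
        ssr = specs[i]
        start = ssr.position + len(ssr.payload()) + 30
        prot = te_library[i % len(te_library)]
        specs.append(
            PlantSpec(
                kind="te_fragment",
                position=start,
                protein=prot.seq[:60],
                te_family=prot.description,
            )
        )
    # hairpins 40 bp downstream of the next n_hairpins SSRs
    for i in range(n_hairpins):
        ssr = specs[n_te + i]
        start = ssr.position + len(ssr.payload()) + 40
        mat = mirnas[i % len(mirnas)]
        specs.append(
            PlantSpec(
                kind="mirna_hairpin",
                position=start,
                stem_len=30,
                loop_len=5,
                mature=str(mat.seq),
                mature_offset=int(rng.integers(0, 9)),
            )
        )
    genome, truth = plant_elements(background, specs, gc=gc, seed=seed)
    return PipelineFixture(
        genome=genome, truth=truth, te_library=te_library, mature_mirnas=mirnas
    )
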