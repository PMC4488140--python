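"""Transposon and miRNA association of SSR markers, hairpin validation and
keyword-based functional categorization.

The TE screen translates marker flanks in six frames and aligns each frame
locally (Smith-Waterman, BLOSUM62, gap open 11 / extend 1) against a
protein library of transposable-element families; a marker is TE-associated
when the best alignment reaches 65% identity over the aligned region and a
Karlin-Altschul E-value of at most 1e-10. The miRNA screen is an ungapped
full-length slide of each mature sequence (both orientations) along the
flanked region, keeping hits with at most 4 mismatches. Candidate
pre-miRNA hairpins are validated with a base-pair-maximization fold
(Watson-Crick plus G:U wobble, minimum loop 3) rather than a
thermodynamic minimum-free-energy model; the validity thresholds are
toolkit choices, configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .dna import revcomp
from .marker_design import FlankedLocus

# Karlin-Altschul parameters for ungapped BLOSUM62 statistics
_KA_LAMBDA = 0.3176
_KA_K = 0.134

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class TEHit:
    marker_id: str
    te_family: str
    library_id: str
    frame: int  # -3..-1, +1..+3
    identity: float  # percent over aligned region
    alignment_length: int
    score: float
    e_value: float


@dataclass(frozen=True)
class MiRNAHit:
    marker_id: str
    mirna_id: str
    mismatches: int
    offset: int  # 0-based offset of the mature match in the flanked region
    strand: str
    hairpin_valid: bool | None = None


def translate_six_frames(dna: str) -> dict[int, str]:
    """Standard-code translation in frames +1..+3 and -1..-3 (stops as '*').

    Reverse-strand frames translate the reverse complement; trailing
    partial codons are dropped.
    """
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    frames: dict[int, str] = {}
    rc = revcomp(dna)
    for off in range(3):
        fwd = dna[off : off + 3 * ((len(dna) - off) // 3)]
        rev = rc[off : off + 3 * ((len(rc) - off) // 3)]
        frames[off + 1] = str(Seq(fwd).translate())
        frames[-(off + 1)] = str(Seq(rev).translate())
    return frames


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def te_family_of(header_id: str, description: str = "") -> str:
    """TE family from a library FASTA header using the Class/Family token."""
    for token in (header_id + " " + description).split():
        if "/" in token:
            return token
    return "unknown"


def te_association(
    flanked: FlankedLocus,
    te_proteins: Sequence,
    min_identity: float = 65.0,
    max_evalue: float = 1e-10,
) -> TEHit | None:
    """Best qualifying translated local alignment against the TE library.

    ``te_proteins`` is a sequence of objects with ``id``, ``seq`` and
    optionally ``description`` (Biopython SeqRecords or similar). The
    E-value uses the ungapped Karlin-Altschul approximation over frame
    length x total library residues. Ties go to the higher score, then
    the earlier library entry.
    """
    if not te_proteins:
        return None
    aligner = _make_aligner()
    total_residues = sum(len(str(p.seq)) for p in te_proteins)
    frames = translate_six_frames(flanked.region)
    best: TEHit | None = None
    for frame, peptide in sorted(frames.items(), key=lambda kv: (kv[0] < 0, abs(kv[0]))):
        if len(peptide) < 5:
            continue
        for entry_idx, prot in enumerate(te_proteins):
            target = str(prot.seq)
            if not target:
                continue
            try:
                aln = aligner.align(peptide, target)
            except ValueError:
                continue  # residues outside the matrix alphabet
            if len(aln) == 0:
                continue
            top = aln[0]
            score = top.score
            if score <= 0:
                continue
            q, t = top[0], top[1]  # aligned strings with gaps
            length = len(q)
            ident = sum(1 for a, b in zip(q, t) if a == b)
            identity = 100.0 * ident / length if length else 0.0
            e_value = _KA_K * len(peptide) * total_residues * math.exp(
                -_KA_LAMBDA * score
            )
            if identity >= min_identity and e_value <= max_evalue:
                cand = TEHit(
                    marker_id=flanked.locus.locus_id,
                    te_family=te_family_of(prot.id, getattr(prot, "description", "")),
                    library_id=prot.id,
                    frame=frame,
                    identity=identity,
                    alignment_length=length,
                    score=score,
                    e_value=e_value,
                )
                if best is None or cand.score > best.score:
                    best = cand
    return best


def mirna_association(
    flanked: FlankedLocus,
    mature_mirnas: Sequence,
    max_mismatches: int = 4,
) -> list[MiRNAHit]:
    """Ungapped full-length scan of each mature miRNA along the flanked region.

    Both the mature sequence and its reverse complement are slid across
    left flank + tract + right flank; every offset with at most
    ``max_mismatches`` substitutions is reported.
    """
    region = flanked.region
    n = len(region)
    region_arr = np.frombuffer(region.encode(), dtype=np.uint8)
    hits: list[MiRNAHit] = []
    for mat in mature_mirnas:
        mature = str(mat.seq).upper().replace("U", "T")
        if not (18 <= len(mature) <= 26):
            raise ValueError(f"mature miRNA {mat.id} length outside 18-26 nt")
        for strand, pattern in (("+", mature), ("-", revcomp(mature))):
            m = len(pattern)
            if m > n:
                continue
            p_arr = np.frombuffer(pattern.encode(), dtype=np.uint8)
            # mismatch count at every offset via a sliding window view
            windows = np.lib.stride_tricks.sliding_window_view(region_arr, m)
            mm = (windows != p_arr).sum(axis=1)
            for off in np.flatnonzero(mm <= max_mismatches):
                hits.append(
                    MiRNAHit(
                        marker_id=flanked.locus.locus_id,
                        mirna_id=mat.id,
                        mismatches=int(mm[off]),
                        offset=int(off),
                        strand=strand,
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.mirna_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Hairpin validation (base-pair maximization)
# ---------------------------------------------------------------------------

def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def nussinov_pairs(seq: str, min_loop: int = 3) -> list[tuple[int, int]]:
    """Maximum Watson-Crick/G:U base pairing of a DNA window.

    Bottom-up dynamic program; the inner split-point maximization is
    vectorized. Returns the traceback pair list (i < j, 0-based).
    """
    n = len(seq)
    if n == 0:
        return []
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if _can_pair(seq[i], seq[j]):
                pairable[i, j] = True
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i, j - 1]
            # k pairs with j, i <= k <= j - min_loop - 1
            hi = j - min_loop
            ks = np.flatnonzero(pairable[i:hi, j]) + i
            if ks.size:
                left = np.where(ks > i, N[i, np.maximum(ks - 1, i)], 0)
                # N[i, k-1] is 0 when k == i (empty prefix)
                left[ks == i] = 0
                right = N[np.minimum(ks + 1, j - 1), j - 1]
                right[ks + 1 > j - 1] = 0
                best = max(best, int((left + right).max() + 1))
            N[i, j] = best
    pairs: list[tuple[int, int]] = []
    _traceback(N, pairable, 0, n - 1, min_loop, pairs)
    return sorted(pairs)


def _traceback(N, pairable, i, j, min_loop, pairs) -> None:
    while i < j:
        if N[i, j] == N[i, j - 1]:
            j -= 1
            continue
        hi = j - min_loop
        for k in range(i, hi):
            if not pairable[k, j]:
                continue
            left = N[i, k - 1] if k > i else 0
            right = N[k + 1, j - 1] if k + 1 <= j - 1 else 0
            if N[i, j] == left + right + 1:
                pairs.append((k, j))
                if k > i:
                    _traceback(N, pairable, i, k - 1, min_loop, pairs)
                i, j = k + 1, j - 1
                break
        else:  # pragma: no cover - defensive; recurrence guarantees a branch
            j -= 1


def _stem_loops(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into stem-loops: each hairpin loop plus the nested pairs
    enclosing it up to the first branch point."""
    pairs = sorted(pairs)
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        par = stack[-1] if stack else None
        parent[p] = par
        children.setdefault(par, []).append(p)
        children.setdefault(p, [])
        stack.append(p)
    stems: list[list[tuple[int, int]]] = []
    # leaves = hairpin loops; walk upward while the chain is unbranched
    for p in pairs:
        if children[p]:
            continue
        stem = [p]
        cur = parent[p]
        while cur is not None and len(children[cur]) == 1:
            stem.append(cur)
            cur = parent[cur]
        stems.append(stem)
    return stems


def validate_hairpin(
    window: str,
    mature_offset: int,
    mature_length: int,
    min_paired_fraction: float = 0.55,
    min_mature_paired: float = 0.60,
    min_loop: int = 3,
) -> bool:
    """Fold-back check for a candidate pre-miRNA window.

    Valid iff the maximum-pairing structure pairs at least
    ``min_paired_fraction`` of the window's bases AND a single stem-loop
    contains at least ``min_mature_paired`` of the mature-site bases in
    paired positions.
    """
    if len(window) < 20:
        raise ValueError("hairpin window too short")
    pairs = nussinov_pairs(window, min_loop=min_loop)
    paired_fraction = 2 * len(pairs) / len(window)
    if paired_fraction < min_paired_fraction:
        return False
    mature = set(range(mature_offset, mature_offset + mature_length))
    for stem in _stem_loops(pairs):
        covered = set()
        for i, j in stem:
            covered.add(i)
            covered.add(j)
        if len(covered & mature) >= min_mature_paired * mature_length:
            return True
    return False


# ---------------------------------------------------------------------------
# Functional categorization of annotation strings
# ---------------------------------------------------------------------------

DEFAULT_KEYWORDS: dict[str, list[str]] = {
    "hypothetical_uncharacterized": [
        "hypothetical", "putative", "uncharacterized", "unknown",
    ],
    "stress_related": [
        "heat shock", "pathogenesis", "drought", "osmotic", "dehydrin",
        "stress", "cold-responsive", "salt tolerance",
    ],
    "transcription_factor": [
        "transcription factor", "zinc finger", "myb", "wrky", "bzip",
        "homeobox", "bhlh",
    ],
    "housekeeping": [
        "ribosomal", "actin", "tubulin", "ubiquitin", "histone",
        "elongation factor", "atp synthase", "polymerase", "kinase",
        "dehydrogenase", "synthase", "reductase", "transferase",
    ],
}

CATEGORY_ORDER = [
    "hypothetical_uncharacterized",
    "stress_related",
    "transcription_factor",
    "housekeeping",
]


def categorize_annotation(
    description: str | None,
    keywords: dict[str, list[str]] | None = None,
) -> str:
    """Map a free-text protein annotation to one of five categories.

    Case-insensitive keyword matching in a fixed priority order; an absent
    annotation is ``non_functional``; an unmatched one is ``other``.
    """
    if description is None or not description.strip():
        return "non_functional"
    keywords = keywords or DEFAULT_KEYWORDS
    text = description.lower()
    for category in CATEGORY_ORDER:
        for kw in keywords.get(category, []):
            if kw in text:
                return category
    return "other"
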