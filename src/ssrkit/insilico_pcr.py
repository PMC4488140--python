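"""Electronic PCR: primer-site search, amplicon extraction, physical mapping,
cross-taxon transferability and amplicon-size polymorphism calls.

A primer binds a site when a semi-global alignment uses at most the
mismatch budget (default 3) and the gap budget (default 2, counted per
inserted/deleted base) and its 3'-terminal anchor bases (default 2) match
exactly. Budgets are per primer. Candidate alignments (any alignment of
cost <= max_mm + 2*max_gaps, cost = mismatches + 2*gaps) that overlap are
collapsed to the minimum-cost one (ties: fewer gaps, then leftmost), and
the budgets are judged on that collapsed alignment — so a site whose best
explanation is four substitutions is rejected even though a contrived
three-mismatch/two-gap alignment of it exists.

The search runs a layered dynamic program vectorized over genome
positions: layer g holds the minimum mismatch count achievable with at
most g gaps, so the whole genome is processed with O(primer_len x gaps)
numpy passes rather than per-offset alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dna import revcomp
from .io_formats import PipelineConfig, SequenceRecord
from .marker_design import PrimerPair

_INF = 9999


@dataclass(frozen=True)
class BindingSite:
    """One qualifying primer binding site (0-based half-open on + strand)."""

    seq_id: str
    strand: str  # "+" : primer 5'->3' equals genome left->right
    start: int
    end: int
    mismatches: int
    gaps: int

    @property
    def cost(self) -> int:
        return self.mismatches + 2 * self.gaps


@dataclass(frozen=True)
class AmpliconHit:
    """One in-silico PCR product."""

    marker_id: str
    genome_id: str
    seq_id: str
    start: int  # forward-site 5' position
    end: int  # one past reverse-site 5' position
    product_size: int
    forward_site: BindingSite
    reverse_site: BindingSite


def _layered_dp_end_costs(
    pattern: str, text_arr: np.ndarray, max_mm: int, max_gaps: int, anchor: int
) -> np.ndarray:
    """Minimum candidate-alignment cost ending at each text position.

    Returns an int array ``cost[j]`` = min over g<=max_gaps of
    (mismatches + 2*g) for a semi-global alignment of ``pattern`` ending
    exactly at text position j (exclusive end) whose cost is within the
    candidate bound max_mm + 2*max_gaps, with the last ``anchor`` pattern
    bases matched exactly without gaps; _INF where no candidate ends.
    """
    m = len(pattern)
    n = len(text_arr)
    if n < m - max_gaps:
        return np.full(1, _INF, dtype=np.int16)
    p_arr = np.frombuffer(pattern.encode(), dtype=np.uint8)
    # D[g][i] is a vector over text positions j=0..n: min mismatches
    # aligning pattern[:i] ending at j using at most g gaps.
    D_prev_g: list[np.ndarray] | None = None
    best = np.full(n + 1, _INF, dtype=np.int16)
    for g in range(max_gaps + 1):
        rows: list[np.ndarray] = []
        row = np.zeros(n + 1, dtype=np.int16)  # i = 0: free start
        rows.append(row)
        for i in range(1, m + 1):
            anchored = i > m - anchor
            mism = (text_arr != p_arr[i - 1]).astype(np.int16)
            new = np.full(n + 1, _INF, dtype=np.int16)
            if anchored:
                # exact-match diagonal only
                prev = rows[i - 1]
                cand = prev[:-1] + np.where(mism == 0, 0, _INF)
                new[1:] = np.minimum(new[1:], cand)
            else:
                prev = rows[i - 1]
                new[1:] = np.minimum(new[1:], prev[:-1] + mism)
                if D_prev_g is not None:
                    # gap in text: pattern base i unaligned
                    new = np.minimum(new, D_prev_g[i - 1])
                    # gap in pattern: text base consumed silently
                    new[1:] = np.minimum(new[1:], D_prev_g[i][:-1])
            np.minimum(new, _INF, out=new)
            rows.append(new)
        final = rows[m]
        bound = max_mm + 2 * max_gaps
        cost = np.where(final + 2 * g <= bound, final + 2 * g, _INF).astype(np.int16)
        best = np.minimum(best, cost)
        D_prev_g = rows
    return best


def _traceback_span(
    pattern: str, text: str, end: int, max_mm: int, max_gaps: int, anchor: int
) -> tuple[int, int, int] | None:
    """Best (start, mismatches, gaps) for an alignment ending at ``end``.

    Small per-site DP over the window preceding ``end``; minimizes
    mismatches + 2*gaps over all candidate alignments (cost within
    max_mm + 2*max_gaps), then prefers fewer gaps, then leftmost start.
    """
    cost_bound = max_mm + 2 * max_gaps
    m = len(pattern)
    lo = max(0, end - m - max_gaps)
    window = text[lo:end]
    n = len(window)
    # dp[(i, j, g)] = min mismatches; iterate directly
    best_final: tuple[int, int, int] | None = None  # (cost, gaps, start)
    # enumerate alignments anchored at the right edge of the window
    # dp over reversed strings so the fixed end becomes a fixed start
    rp = pattern[::-1]
    rw = window[::-1]
    # state: (i chars of rp consumed, j chars of rw consumed, g gaps) -> min mm
    cur = {(0, 0, 0): 0}
    results: list[tuple[int, int, int]] = []  # (mm, g, j_consumed)
    for _ in range(m + n + max_gaps + 1):
        nxt: dict[tuple[int, int, int], int] = {}
        if not cur:
            break
        for (i, j, g), mm in cur.items():
            if i == m:
                results.append((mm, g, j))
                continue
            anchored = i < anchor  # first chars of rp are the 3' anchor
            if j < n:
                match = rp[i] == rw[j]
                if anchored:
                    if match:
                        k = (i + 1, j + 1, g)
                        if nxt.get(k, _INF) > mm:
                            nxt[k] = mm
                else:
                    k = (i + 1, j + 1, g)
                    v = mm + (0 if match else 1)
                    if v + 2 * g <= cost_bound and nxt.get(k, _INF) > v:
                        nxt[k] = v
            if not anchored and g < max_gaps:
                k = (i + 1, j, g + 1)  # pattern base unaligned
                if nxt.get(k, _INF) > mm:
                    nxt[k] = mm
                if j < n:
                    k = (i, j + 1, g + 1)  # text base unaligned
                    if nxt.get(k, _INF) > mm:
                        nxt[k] = mm
        cur = nxt
    for mm, g, j in results:
        if mm + 2 * g > cost_bound or g > max_gaps:
            continue
        cand = (mm + 2 * g, g, end - j)
        if best_final is None or cand < best_final:
            best_final = cand
    if best_final is None:
        return None
    cost, g, start = best_final
    return start, cost - 2 * g, g


def _collapse_sites(sites: list[BindingSite]) -> list[BindingSite]:
    """Collapse overlapping qualifying sites to the min-cost, leftmost one."""
    out: list[BindingSite] = []
    for s in sorted(sites, key=lambda x: (x.start, x.end)):
        if out and s.start < out[-1].end:
            if s.cost < out[-1].cost:
                out[-1] = s
        else:
            out.append(s)
    return out


def _exact_sites(pattern: str, text: str, seq_id: str, strand_label: str,
                 flip_len: int | None) -> list[BindingSite]:
    """Fast path for zero budgets: plain substring search."""
    sites = []
    idx = text.find(pattern)
    while idx != -1:
        start, end = idx, idx + len(pattern)
        if flip_len is not None:
            start, end = flip_len - end, flip_len - start
        sites.append(
            BindingSite(seq_id=seq_id, strand=strand_label, start=start,
                        end=end, mismatches=0, gaps=0)
        )
        idx = text.find(pattern, idx + 1)
    return sites


def find_binding_sites(
    primer: str,
    record: SequenceRecord,
    max_mismatches: int = 3,
    max_gaps: int = 2,
    anchor3: int = 2,
) -> list[BindingSite]:
    """All qualifying binding sites of a primer on both strands of a sequence.

    A "+" site means the primer sequence itself aligns left-to-right; a
    "-" site means its reverse complement does (the primer anneals to the
    plus strand and extends leftward). Coordinates are always on the plus
    strand, 0-based half-open.
    """
    if len(primer) < 8:
        raise ValueError("primer shorter than 8 nt")
    sites: list[BindingSite] = []
    n = len(record.seq)
    for strand_label in "+-":
        if strand_label == "+":
            text = record.seq
            pattern = primer
            flip = None
        else:
            # search the reverse complement of the genome; pattern 3' anchor
            # stays at the pattern end, coordinates map back as n-e..n-s
            text = revcomp(record.seq)
            pattern = primer
            flip = n
        if max_mismatches == 0 and max_gaps == 0:
            sites.extend(_exact_sites(pattern, text, record.id, strand_label, flip))
            continue
        text_arr = np.frombuffer(text.encode(), dtype=np.uint8)
        costs = _layered_dp_end_costs(
            pattern, text_arr, max_mismatches, max_gaps, anchor3
        )
        ends = np.flatnonzero(costs < _INF)
        strand_sites: list[BindingSite] = []
        for e in ends:
            tb = _traceback_span(
                pattern, text, int(e), max_mismatches, max_gaps, anchor3
            )
            if tb is None:
                continue
            start, mm, gaps = tb
            s0, e0 = start, int(e)
            if flip is not None:
                s0, e0 = flip - int(e), flip - start
            strand_sites.append(
                BindingSite(
                    seq_id=record.id, strand=strand_label, start=s0, end=e0,
                    mismatches=mm, gaps=gaps,
                )
            )
        sites.extend(
            s
            for s in _collapse_sites(strand_sites)
            if s.mismatches <= max_mismatches and s.gaps <= max_gaps
        )
    sites.sort(key=lambda s: (s.start, s.end, s.strand))
    return sites


def epcr(
    pair: PrimerPair,
    genome: Sequence[SequenceRecord],
    genome_id: str = "",
    max_mismatches: int = 3,
    max_gaps: int = 2,
    anchor3: int = 2,
    max_product: int = 5000,
) -> list[AmpliconHit]:
    """All virtual amplicons of a primer pair in a genome.

    Both orientations are searched: forward primer on + with reverse
    primer converging from -, and the mirrored configuration (reverse on
    +, forward on -). Product size is the 5'-to-5' span.
    """
    if pair.status != "designed":
        return []
    hits: list[AmpliconHit] = []
    for rec in genome:
        f_sites = find_binding_sites(pair.forward, rec, max_mismatches, max_gaps, anchor3)
        r_sites = find_binding_sites(pair.reverse, rec, max_mismatches, max_gaps, anchor3)
        for left_name, right_name, left_sites, right_sites in (
            ("forward", "reverse", f_sites, r_sites),
            ("reverse", "forward", r_sites, f_sites),
        ):
            for ls in left_sites:
                if ls.strand != "+":
                    continue
                for rs in right_sites:
                    if rs.strand != "-":
                        continue
                    if rs.start < ls.end:
                        continue  # primers must not overlap; convergent only
                    product = rs.end - ls.start
                    if product > max_product:
                        continue
                    fwd_site, rev_site = (
                        (ls, rs) if left_name == "forward" else (rs, ls)
                    )
                    hits.append(
                        AmpliconHit(
                            marker_id=pair.locus_id,
                            genome_id=genome_id,
                            seq_id=rec.id,
                            start=ls.start,
                            end=rs.end,
                            product_size=product,
                            forward_site=fwd_site,
                            reverse_site=rev_site,
                        )
                    )
    # the mirrored orientation can rediscover the same product span when a
    # primer pair is its own reverse complement; report each span once
    uniq: dict[tuple[str, int, int], AmpliconHit] = {}
    for h in hits:
        uniq.setdefault((h.seq_id, h.start, h.end), h)
    return sorted(uniq.values(), key=lambda h: (h.seq_id, h.start, h.end))


def physical_map(
    markers: Sequence,
    reference: Sequence[SequenceRecord],
    config: PipelineConfig | None = None,
) -> dict[str, tuple[str, str | None]]:
    """Map each marker onto the reference: unique / multi / none.

    Returns ``marker_id -> (status, seq_id-of-unique-hit-or-None)``.
    Compound-repeat markers are flagged "excluded_compound" and, like
    multi- and no-hit markers, do not proceed to transferability.
    """
    config = config or PipelineConfig()
    out: dict[str, tuple[str, str | None]] = {}
    for m in markers:
        if m.locus.is_compound:
            out[m.marker_id] = ("excluded_compound", None)
            continue
        if m.primer_pair is None or m.primer_pair.status != "designed":
            out[m.marker_id] = ("none", None)
            continue
        hits = epcr(
            m.primer_pair,
            reference,
            genome_id="reference",
            max_mismatches=config.epcr_max_mismatches,
            max_gaps=config.epcr_max_gaps,
            anchor3=config.epcr_anchor3,
            max_product=config.epcr_max_product,
        )
        if len(hits) == 1:
            out[m.marker_id] = ("unique", hits[0].seq_id)
        elif len(hits) == 0:
            out[m.marker_id] = ("none", None)
        else:
            out[m.marker_id] = ("multi", None)
    return out


def classify_polymorphism(
    expected: int, observed: Sequence[int], threshold: int = 10
) -> str:
    """polymorphic iff any observed amplicon differs from the expected size
    by at least ``threshold`` bp (boundary inclusive)."""
    if not observed:
        raise ValueError("no observed amplicon sizes")
    if any(abs(o - expected) >= threshold for o in observed):
        return "polymorphic"
    return "monomorphic"


@dataclass
class TransferabilityMatrix:
    """markers x genomes grid of transfer/polymorphism calls."""

    marker_ids: list[str]
    genome_ids: list[str]
    cells: dict[tuple[str, str], str] = field(default_factory=dict)

    def percent_transferable(self, genome_id: str) -> float:
        """Markers with >= 1 amplicon in this genome, as a percentage."""
        if not self.marker_ids:
            return 0.0
        hit = sum(
            1
            for mid in self.marker_ids
            if self.cells[(mid, genome_id)] != "no_hit"
        )
        return 100.0 * hit / len(self.marker_ids)

    def to_frame(self):
        import pandas as pd

        data = {
            g: [self.cells[(m, g)] for m in self.marker_ids]
            for g in self.genome_ids
        }
        return pd.DataFrame(data, index=self.marker_ids)


def transferability_matrix(
    markers: Sequence,
    genomes: dict[str, Sequence[SequenceRecord]],
    config: PipelineConfig | None = None,
) -> TransferabilityMatrix:
    """Cross-taxon ePCR of (uniquely mapped) markers against named genomes.

    Each cell is no_hit, multi_locus (>1 amplicon), polymorphic or
    monomorphic (size vs the marker's expected product, >= threshold bp).
    """
    config = config or PipelineConfig()
    matrix = TransferabilityMatrix(
        marker_ids=[m.marker_id for m in markers],
        genome_ids=list(genomes),
    )
    for m in markers:
        for gid, records in genomes.items():
            hits = epcr(
                m.primer_pair,
                records,
                genome_id=gid,
                max_mismatches=config.epcr_max_mismatches,
                max_gaps=config.epcr_max_gaps,
                anchor3=config.epcr_anchor3,
                max_product=config.epcr_max_product,
            )
            if not hits:
                cell = "no_hit"
            elif len(hits) > 1:
                cell = "multi_locus"
            else:
                cell = classify_polymorphism(
                    m.primer_pair.expected_product,
                    [h.product_size for h in hits],
                    config.polymorphism_threshold,
                )
            matrix.cells[(m.marker_id, gid)] = cell
    return matrix
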