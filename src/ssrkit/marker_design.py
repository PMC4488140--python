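"""Flank extraction, deterministic primer-pair design and redundancy filtering.

Primer design is a simplified, fully deterministic stand-in for a primer3
run: every window of the configured length range in each flank is scored,
compliance means Wallace-rule Tm and GC within range and product size
within range, and the best-scoring compliant pair wins. The score is the
summed distance of both primer Tms from the midpoint of the Tm range; ties
fall to the smaller product, then the leftmost forward window, then the
leftmost reverse window, so identical inputs always give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dna import revcomp
from .io_formats import PipelineConfig, SequenceRecord
from .repeat_scan import SSRLocus


@dataclass(frozen=True)
class FlankedLocus:
    """An SSR locus with its up/downstream flanks cut out of the source."""

    locus: SSRLocus
    left_flank: str
    right_flank: str
    tract: str = ""
    left_truncated: bool = False
    right_truncated: bool = False

    @property
    def region(self) -> str:
        """left flank + repeat tract + right flank as one string."""
        return self.left_flank + self.tract + self.right_flank


@dataclass(frozen=True)
class PrimerPair:
    """A designed (or failed) primer pair for one SSR locus.

    ``reverse`` is given 5'->3' on the opposite strand. ``expected_product``
    is the 5'-to-5' span on the source sequence, inclusive. ``forward_start``
    and ``reverse_end`` are 0-based source coordinates of the forward 5' end
    and one past the reverse 5' end.
    """

    locus_id: str
    status: str  # "designed" | "failed(<reason>)"
    forward: str = ""
    reverse: str = ""
    tm_forward: float = 0.0
    tm_reverse: float = 0.0
    gc_forward: float = 0.0
    gc_reverse: float = 0.0
    expected_product: int = 0
    forward_start: int = -1
    reverse_end: int = -1


def extract_flanks(
    locus: SSRLocus, record: SequenceRecord, flank_length: int = 200
) -> FlankedLocus:
    """Cut up to ``flank_length`` bp either side of the tract, truncating at ends."""
    if locus.seq_id != record.id:
        raise ValueError(f"locus {locus.locus_id} does not belong to {record.id}")
    left_start = max(0, locus.start - flank_length)
    left = record.seq[left_start : locus.start]
    right = record.seq[locus.end : locus.end + flank_length]
    return FlankedLocus(
        locus=locus,
        left_flank=left,
        right_flank=right,
        tract=record.seq[locus.start : locus.end],
        left_truncated=len(left) < flank_length,
        right_truncated=len(right) < flank_length,
    )


def primer_tm(primer: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    if len(primer) < 8:
        raise ValueError("primer shorter than 8 nt")
    if "N" in primer:
        raise ValueError("primer contains N")
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


def primer_gc(primer: str) -> float:
    """GC content of a primer in percent."""
    gc = primer.count("G") + primer.count("C")
    return 100.0 * gc / len(primer)


def _compliant_windows(flank: str, config: PipelineConfig) -> list[tuple[int, int]]:
    """All (start, length) windows in the flank passing Tm/GC/no-N constraints.

    Window Tm and GC come from cumulative base counts, so scanning is
    O(flank x lengths) instead of O(flank x lengths x primer length).
    """
    n = len(flank)
    if n < config.primer_min_len:
        return []
    arr = np.frombuffer(flank.encode(), dtype=np.uint8)
    is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(np.int32)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int32)
    is_n = (arr == ord("N")).astype(np.int32)
    cum_at = np.concatenate(([0], np.cumsum(is_at)))
    cum_gc = np.concatenate(([0], np.cumsum(is_gc)))
    cum_n = np.concatenate(([0], np.cumsum(is_n)))
    out: list[tuple[int, int]] = []
    for length in range(config.primer_min_len, config.primer_max_len + 1):
        if length > n:
            break
        starts = np.arange(0, n - length + 1)
        at = cum_at[starts + length] - cum_at[starts]
        gc = cum_gc[starts + length] - cum_gc[starts]
        nn = cum_n[starts + length] - cum_n[starts]
        tm = 2.0 * at + 4.0 * gc
        gc_pct = 100.0 * gc / length
        ok = (
            (nn == 0)
            & (tm >= config.tm_min)
            & (tm <= config.tm_max)
            & (gc_pct >= config.gc_min)
            & (gc_pct <= config.gc_max)
        )
        out.extend((int(s), length) for s in starts[ok])
    return out


def design_primer_pair(
    flanked: FlankedLocus, config: PipelineConfig | None = None
) -> PrimerPair:
    """Pick the best compliant forward/reverse window pair for one locus.

    Returns ``failed(insufficient_flank)`` when either flank is shorter
    than the minimum primer length, ``failed(no_compliant_pair)`` when no
    window combination satisfies all constraints. The repeat tract always
    lies strictly inside the product because the forward window sits
    entirely in the left flank and the reverse window entirely in the
    right flank.
    """
    config = config or PipelineConfig()
    loc = flanked.locus
    if (
        len(flanked.left_flank) < config.primer_min_len
        or len(flanked.right_flank) < config.primer_min_len
    ):
        return PrimerPair(locus_id=loc.locus_id, status="failed(insufficient_flank)")

    fwd_windows = _compliant_windows(flanked.left_flank, config)
    rev_windows = _compliant_windows(flanked.right_flank, config)
    if not fwd_windows or not rev_windows:
        return PrimerPair(locus_id=loc.locus_id, status="failed(no_compliant_pair)")

    tm_target = (config.tm_min + config.tm_max) / 2.0
    left_offset = loc.start - len(flanked.left_flank)  # source coord of flank[0]

    # absolute coordinates and Tm deviation per window
    fwd = []  # (abs_start, length, tm, dev)
    for s, length in fwd_windows:
        w = flanked.left_flank[s : s + length]
        tm = primer_tm(w)
        fwd.append((left_offset + s, length, tm, abs(tm - tm_target), w))
    rev = []  # (abs_end_of_window, abs_start, tm, dev, primer_seq)
    for s, length in rev_windows:
        w = flanked.right_flank[s : s + length]
        tm = primer_tm(w)  # Tm is strand-symmetric under Wallace
        abs_start = loc.end + s
        rev.append((abs_start + length, abs_start, tm, abs(tm - tm_target), w))

    best = None
    best_key = None
    for f_start, f_len, f_tm, f_dev, f_seq in fwd:
        for r_end, r_start, r_tm, r_dev, r_win in rev:
            product = r_end - f_start
            if product < config.product_min or product > config.product_max:
                continue
            key = (f_dev + r_dev, product, f_start, r_start)
            if best_key is None or key < best_key:
                best_key = key
                best = (f_start, f_seq, f_tm, r_end, r_win, r_tm, product)
    if best is None:
        return PrimerPair(locus_id=loc.locus_id, status="failed(no_compliant_pair)")

    f_start, f_seq, f_tm, r_end, r_win, r_tm, product = best
    r_seq = revcomp(r_win)
    return PrimerPair(
        locus_id=loc.locus_id,
        status="designed",
        forward=f_seq,
        reverse=r_seq,
        tm_forward=f_tm,
        tm_reverse=r_tm,
        gc_forward=primer_gc(f_seq),
        gc_reverse=primer_gc(r_seq),
        expected_product=product,
        forward_start=f_start,
        reverse_end=r_end,
    )


@dataclass
class RedundancyReport:
    input_count: int
    kept: int
    removed: int

    @property
    def retention_percent(self) -> int:
        from .ssr_classify import percent_of

        return percent_of(self.kept, self.input_count)


def _pair_key(pair: PrimerPair) -> tuple[str, str]:
    """Orientation-normalized identity key: forward/reverse swap is redundant."""
    return tuple(sorted((pair.forward, pair.reverse)))  # type: ignore[return-value]


def deduplicate_primers(
    pairs: Sequence[PrimerPair],
) -> tuple[list[PrimerPair], RedundancyReport]:
    """Drop primer pairs whose normalized (forward, reverse) strings repeat.

    First occurrence in input order is kept. Idempotent.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[PrimerPair] = []
    for p in pairs:
        if p.status != "designed":
            raise ValueError(f"{p.locus_id}: cannot deduplicate undesigned pair")
        key = _pair_key(p)
        if key not in seen:
            seen.add(key)
            kept.append(p)
    return kept, RedundancyReport(
        input_count=len(pairs), kept=len(kept), removed=len(pairs) - len(kept)
    )


def deduplicate_two_stage(
    pairs_by_dataset: dict[str, Sequence[PrimerPair]],
) -> tuple[list[PrimerPair], dict[str, RedundancyReport], RedundancyReport]:
    """Within-dataset filtering followed by filtering of the pooled set."""
    per_dataset: dict[str, RedundancyReport] = {}
    pooled: list[PrimerPair] = []
    for tag, pairs in pairs_by_dataset.items():
        kept, report = deduplicate_primers(pairs)
        per_dataset[tag] = report
        pooled.extend(kept)
    final, pooled_report = deduplicate_primers(pooled)
    return final, per_dataset, pooled_report
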