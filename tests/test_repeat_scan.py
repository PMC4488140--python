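from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_ssrs
from ssrkit import (
    SequenceRecord,
    canonical_motif,
    find_perfect_ssrs,
    merge_compound,
    summarize_density,
)
from ssrkit.dna import is_primitive, revcomp
from ssrkit.repeat_scan import SSRLocus, density_from_counts


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected",
        [("TC", "AG"), ("AT", "AT"), ("GGC", "CCG"), ("CT", "AG"), ("GA", "AG")],
    )
    def test_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_agrees_with_exhaustive_rotation_minimum(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = int(rng.integers(2, 7))
            motif = "".join("ACGT"[i] for i in rng.integers(0, 4, k))
            if not is_primitive(motif):
                continue
            rc = revcomp(motif)
            expected = min(
                [motif[i:] + motif[:i] for i in range(k)]
                + [rc[i:] + rc[:i] for i in range(k)]
            )
            assert canonical_motif(motif) == expected

    @given(st.text(alphabet="ACGT", min_size=2, max_size=6))
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_rotation_invariant(self, motif):
        if not is_primitive(motif):
            return
        canon = canonical_motif(motif)
        assert canonical_motif(canon) == canon
        for i in range(len(motif)):
            assert canonical_motif(motif[i:] + motif[:i]) == canon
        assert canonical_motif(revcomp(motif)) == canon

    def test_family_counts_by_exhaustive_enumeration(self):
        expected = {2: 4, 3: 10, 4: 33, 5: 102, 6: 350}
        for period, n_families in expected.items():
            families = {
                canonical_motif("".join(m))
                for m in product("ACGT", repeat=period)
                if is_primitive("".join(m))
            }
            assert len(families) == n_families

    def test_rejects_n_and_non_primitive(self):
        with pytest.raises(ValueError):
            canonical_motif("AN")
        with pytest.raises(ValueError):
            canonical_motif("ATAT")


class TestFindPerfectSsrs:
    def _scan(self, seq):
        return find_perfect_ssrs(SequenceRecord("s", seq))

    def test_dinucleotide_at_exact_threshold(self):
        loci = self._scan("ATATATATATAT")
        assert [(l.motif, l.repeat_units, l.tract_length) for l in loci] == [
            ("AT", 6, 12)
        ]

    def test_below_minimum_units_not_reported(self):
        assert self._scan("CACACACACA") == []

    def test_smallest_period_rule(self):
        loci = self._scan("ATATATATATATATAT")
        assert [(l.motif, l.repeat_units) for l in loci] == [("AT", 8)]

    def test_n_breaks_tract(self):
        assert self._scan("ATATATNATATAT") == []

    def test_maximality_with_flanking_background(self):
        loci = self._scan("GGC" + "AAG" * 6 + "CTT")
        assert [(l.start, l.end, l.motif) for l in loci] == [(3, 21, "AAG")]

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
            pos = int(rng.integers(50, 400))
            seq = seq[:pos] + "TA" * 8 + seq[pos:]
            fwd = find_perfect_ssrs(SequenceRecord("f", seq))
            rev = find_perfect_ssrs(SequenceRecord("r", revcomp(seq)))
            assert sorted((l.canonical_motif, l.tract_length) for l in fwd) == sorted(
                (l.canonical_motif, l.tract_length) for l in rev
            )

    def test_matches_bruteforce_on_repeat_seeded_sequences(self):
        rng = np.random.default_rng(11)
        motifs = ["AT", "AG", "AAG", "ACGT", "AAAAT", "AATAAG"]
        for _ in range(30):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
            for _ in range(4):
                motif = motifs[int(rng.integers(0, len(motifs)))]
                units = int(rng.integers(3, 12))
                pos = int(rng.integers(0, 700))
                seq = seq[:pos] + motif * units + seq[pos:]
            seq = seq[:1500]
            got = [
                (l.start, l.end, l.motif)
                for l in find_perfect_ssrs(SequenceRecord("s", seq))
            ]
            assert got == brute_force_ssrs(seq)


class TestMergeCompound:
    def test_zero_gap_neighbours_merge(self):
        loci = find_perfect_ssrs(SequenceRecord("s", "AT" * 6 + "GA" * 7))
        merged = merge_compound(loci)
        assert len(merged) == 1 and merged[0].is_compound
        assert [m.motif for m in merged[0].members] == ["AT", "GA"]
        assert (merged[0].start, merged[0].end) == (0, 26)

    def test_one_base_gap_stays_simple(self):
        loci = find_perfect_ssrs(SequenceRecord("s", "AT" * 6 + "C" + "GA" * 7))
        merged = merge_compound(loci)
        assert [l.is_compound for l in merged] == [False, False]

    def test_single_locus_unchanged(self):
        loci = find_perfect_ssrs(SequenceRecord("s", "G" * 5 + "AT" * 6 + "G" * 5))
        assert merge_compound(loci) == loci

    def test_overlapping_input_is_hard_error(self):
        a = SSRLocus.simple("a", "s", 0, 12, "AT", 6)
        b = SSRLocus.simple("b", "s", 10, 25, "AAG", 5)
        with pytest.raises(ValueError):
            merge_compound([a, b])


class TestDensity:
    def test_printed_scale_density(self):
        # 87396 loci over 473 Mbp of genome -> 5 kbp per SSR
        assert density_from_counts(473_000_000, 87_396) == 5

    def test_direct_arithmetic(self):
        assert density_from_counts(1_000_000, 10) == 100

    def test_zero_loci_density_absent(self):
        recs = [SequenceRecord("a", "ACGT" * 300)]
        stats = summarize_density([], recs, "other")
        assert stats.total_ssrs == 0
        assert stats.kbp_per_ssr is None
        assert stats.ssr_per_mbp is None

    def test_counts_filled_from_loci(self, small_fixture):
        from ssrkit import scan_dataset

        loci = scan_dataset([small_fixture.genome])
        stats = summarize_density(loci, [small_fixture.genome], "other")
        assert stats.total_ssrs == len(loci)
        assert stats.sequences_examined == 1
        assert stats.sequences_with_ssr == 1
        assert stats.sequences_with_multiple_ssr == 1
        assert stats.kbp_per_ssr == density_from_counts(60_000, len(loci))
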