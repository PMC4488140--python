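import numpy as np
import pytest

from _oracles import brute_force_candidate_ends
from ssrkit import (
    SequenceRecord,
    classify_polymorphism,
    epcr,
    find_binding_sites,
    physical_map,
)
from ssrkit.dna import revcomp
from ssrkit.marker_design import PrimerPair


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mutate(seq, positions):
    s = list(seq)
    for i in positions:
        s[i] = "A" if s[i] != "A" else "C"
    return "".join(s)


class TestFindBindingSites:
    def test_exact_site_found_on_both_strands(self):
        g = _random_seq(400, 1)
        primer = g[100:120]
        rec = SequenceRecord("g", g)
        plus = find_binding_sites(primer, rec, 3, 2)
        assert any(
            s.start == 100 and s.end == 120 and s.mismatches == 0 and s.strand == "+"
            for s in plus
        )
        rc_rec = SequenceRecord("rc", revcomp(g))
        minus = find_binding_sites(primer, rc_rec, 3, 2)
        assert any(
            s.start == 280 and s.end == 300 and s.strand == "-" for s in minus
        )

    @pytest.mark.parametrize("n_subs,expected", [(3, True), (4, False)])
    def test_mismatch_budget_boundary(self, n_subs, expected):
        g = _random_seq(400, 2)
        primer = _mutate(g[100:120], [3, 7, 11, 15][:n_subs])
        rec = SequenceRecord("g", g)
        found = [
            s for s in find_binding_sites(primer, rec, 3, 2) if 95 <= s.start <= 105
        ]
        assert bool(found) is expected
        if expected:
            assert found[0].mismatches == n_subs and found[0].gaps == 0

    def test_three_prime_anchor_mismatch_rejects_site(self):
        g = _random_seq(400, 3)
        primer = _mutate(g[100:120], [19])  # terminal 3' base
        rec = SequenceRecord("g", g)
        assert not [
            s
            for s in find_binding_sites(primer, rec, 3, 2)
            if 95 <= s.start <= 105 and s.strand == "+"
        ]

    def test_single_indel_site_accepted_with_gap_cost(self):
        g = _random_seq(400, 4)
        primer = g[100:120]
        bulged = g[:110] + "G" + g[110:]  # insertion inside the site
        rec = SequenceRecord("g", bulged)
        found = [
            s for s in find_binding_sites(primer, rec, 3, 2) if 95 <= s.start <= 105
        ]
        assert found and found[0].gaps == 1 and found[0].mismatches == 0

    def test_budget_monotonicity(self):
        g = _random_seq(2000, 5)
        primer = _mutate(g[500:520], [2, 9])
        rec = SequenceRecord("g", g)
        counts = [
            len(find_binding_sites(primer, rec, mm, gaps))
            for mm, gaps in [(0, 0), (1, 0), (2, 0), (3, 0), (3, 1), (3, 2)]
        ]
        assert counts == sorted(counts)

    def test_matches_exhaustive_alignment_oracle(self):
        """Site finding equals exhaustive per-offset DP on short texts."""
        for seed in range(8):
            g = _random_seq(600, 10 + seed)
            rng = np.random.default_rng(100 + seed)
            primer = g[50:68]
            # plant two degraded copies
            copy1 = _mutate(primer, [4, 9])
            copy2 = primer[:8] + primer[9:]  # one deletion
            g = g[:300] + copy1 + g[300:500] + copy2 + g[500:]
            rec = SequenceRecord("g", g)
            got = {
                (s.start, s.end, s.mismatches, s.gaps)
                for s in find_binding_sites(primer, rec, 3, 2)
                if s.strand == "+"
            }
            # oracle: candidate ends by enumeration, same collapse contract
            best = brute_force_candidate_ends(primer, g, 3, 2, 2)
            cands = sorted(
                (start, end, cost - 2 * gaps, gaps)
                for end, (cost, gaps, start) in best.items()
            )
            expected = set()
            cluster: list[tuple] = []
            for c in cands:
                if cluster and c[0] < max(x[1] for x in cluster):
                    cluster.append(c)
                else:
                    if cluster:
                        expected.add(
                            min(cluster, key=lambda x: (x[2] + 2 * x[3], x[3], x[0]))
                        )
                    cluster = [c]
            if cluster:
                expected.add(
                    min(cluster, key=lambda x: (x[2] + 2 * x[3], x[3], x[0]))
                )
            expected = {
                (s, e, mm, gg)
                for (s, e, mm, gg) in expected
                if mm <= 3 and gg <= 2
            }
            assert got == expected


def _pair_from(seq, f_at, r_at, plen=20):
    fwd = seq[f_at : f_at + plen]
    rev = revcomp(seq[r_at : r_at + plen])
    return PrimerPair(
        locus_id="m1",
        status="designed",
        forward=fwd,
        reverse=rev,
        expected_product=(r_at + plen) - f_at,
        forward_start=f_at,
        reverse_end=r_at + plen,
    )


class TestEpcr:
    def test_self_amplification_exact_product(self):
        g = _random_seq(1000, 20)
        pair = _pair_from(g, 100, 380)
        rec = SequenceRecord("g", g)
        hits = epcr(pair, [rec], max_mismatches=0, max_gaps=0)
        assert [h.product_size for h in hits] == [pair.expected_product]

    def test_divergent_orientation_yields_no_amplicon(self):
        g = _random_seq(1000, 21)
        # swap roles so the sites point away from each other
        pair = _pair_from(g, 100, 380)
        swapped = PrimerPair(
            locus_id="m1",
            status="designed",
            forward=revcomp(pair.forward),
            reverse=revcomp(pair.reverse),
            expected_product=pair.expected_product,
        )
        assert epcr(swapped, [SequenceRecord("g", g)], max_mismatches=0, max_gaps=0) == []

    def test_tandem_duplication_gives_two_amplicons(self):
        g = _random_seq(2000, 22)
        region = g[100:500]
        dup = g[:500] + region + g[500:]
        pair = _pair_from(g, 100, 380)
        # product cap below the cross-copy span isolates the two true copies
        hits = epcr(pair, [SequenceRecord("g", dup)], max_mismatches=0,
                    max_gaps=0, max_product=500)
        assert len(hits) == 2
        assert all(h.product_size == pair.expected_product for h in hits)
        # without the cap the forward site of copy one also pairs with the
        # reverse site of copy two
        assert len(epcr(pair, [SequenceRecord("g", dup)],
                        max_mismatches=0, max_gaps=0)) == 3

    def test_product_cap_excludes_distant_pairing(self):
        g = _random_seq(8000, 23)
        pair = _pair_from(g, 100, 6500)
        hits = epcr(pair, [SequenceRecord("g", g)], max_mismatches=0, max_gaps=0,
                    max_product=5000)
        assert hits == []

    def test_strand_symmetry_of_product_sizes(self):
        g = _random_seq(1500, 24)
        pair = _pair_from(g, 200, 600)
        rec_f = SequenceRecord("f", g)
        rec_r = SequenceRecord("r", revcomp(g))
        sizes_f = sorted(h.product_size for h in epcr(pair, [rec_f]))
        sizes_r = sorted(h.product_size for h in epcr(pair, [rec_r]))
        assert sizes_f == sizes_r


class TestPhysicalMap:
    def test_unique_multi_none_and_compound_excluded(self, small_fixture, small_markers):
        ref = [small_fixture.genome]
        designed = [
            m for m in small_markers if m.primer_pair.status == "designed"
        ][:5]
        mapping = physical_map(designed, ref)
        assert all(st == "unique" for st, _ in mapping.values())
        assert all(sid == small_fixture.genome.id for _, sid in mapping.values())

        # marker with no binding site anywhere
        import copy

        ghost = copy.deepcopy(designed[0])
        ghost.primer_pair = PrimerPair(
            locus_id=ghost.marker_id, status="designed",
            forward="G" * 9 + "CTA" * 4, reverse="C" * 9 + "GAT" * 4,
            expected_product=200,
        )
        assert physical_map([ghost], ref)[ghost.marker_id] == ("none", None)


class TestClassifyPolymorphism:
    @pytest.mark.parametrize(
        "observed,expected",
        [([212], "polymorphic"), ([205], "monomorphic"), ([210], "polymorphic"),
         ([200, 203], "monomorphic"), ([195, 215], "polymorphic")],
    )
    def test_threshold_boundary_at_10bp(self, observed, expected):
        assert classify_polymorphism(200, observed, 10) == expected

    def test_empty_observations_error(self):
        with pytest.raises(ValueError):
            classify_polymorphism(200, [], 10)
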