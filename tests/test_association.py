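import numpy as np
import pytest

from _oracles import hamming_hits, nussinov_count
from ssrkit import (
    categorize_annotation,
    mirna_association,
    te_association,
    translate_six_frames,
    validate_hairpin,
)
from ssrkit.association import nussinov_pairs, te_family_of
from ssrkit.dna import revcomp
from ssrkit.marker_design import FlankedLocus
from ssrkit.repeat_scan import SSRLocus
from ssrkit.synthetic_fixtures import (
    ProteinRecord,
    make_mature_mirnas,
    make_te_library,
    _CODON,
)


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _flanked(left, right, tract="AT" * 10):
    locus = SSRLocus.simple(
        "s.ssr1", "s", len(left), len(left) + len(tract), tract[:2], len(tract) // 2
    )
    return FlankedLocus(locus=locus, left_flank=left, right_flank=right, tract=tract)


class TestTranslateSixFrames:
    def test_codon_table_and_stops(self):
        assert translate_six_frames("ATGGCC")[1] == "MA"
        assert translate_six_frames("TAA")[1] == "*"

    def test_reverse_frames_equal_forward_of_revcomp(self):
        seq = _random_seq(120, 0)
        frames = translate_six_frames(seq)
        rc_frames = translate_six_frames(revcomp(seq))
        for off in (1, 2, 3):
            assert frames[-off] == rc_frames[off]


class TestTeAssociation:
    def test_planted_exact_copy_is_hit_with_full_identity(self):
        # the whole 60-codon library entry is planted, so the optimal local
        # alignment is exactly the planted segment
        lib = make_te_library(n=3, n_codons=60, seed=5)
        coding = "".join(_CODON[a] for a in lib[1].seq)
        left = _random_seq(60, 1) + coding + _random_seq(20, 2)
        right = _random_seq(200, 3)
        hit = te_association(_flanked(left, right), lib)
        assert hit is not None
        assert hit.identity == 100.0
        assert hit.library_id == lib[1].id
        assert hit.te_family == lib[1].description
        assert hit.e_value <= 1e-10

    def test_clean_flanks_are_not_flagged(self):
        lib = make_te_library(n=3, seed=5)
        hit = te_association(
            _flanked(_random_seq(200, 7), _random_seq(200, 8)), lib
        )
        assert hit is None

    def test_low_identity_alignment_rejected(self):
        lib = make_te_library(n=1, n_codons=60, seed=9)
        protein = lib[0].seq
        # mutate 40% of residues: long alignment, identity ~60% < 65%
        rng = np.random.default_rng(10)
        aa = "ARNDCQEGHILKMFPSTWYV"
        mutated = list(protein)
        for i in rng.choice(len(mutated), size=int(0.4 * len(mutated)), replace=False):
            mutated[i] = aa[(aa.index(mutated[i]) + 1) % len(aa)]
        coding = "".join(_CODON[a] for a in mutated)
        left = _random_seq(40, 11) + coding + _random_seq(20, 12)
        hit = te_association(_flanked(left, _random_seq(200, 13)), lib)
        if hit is not None:  # a short high-identity sub-alignment may remain
            assert hit.identity >= 65.0

    def test_empty_library_gives_none(self):
        assert te_association(_flanked(_random_seq(200, 1), _random_seq(200, 2)), []) is None

    def test_threshold_monotonicity(self):
        lib = make_te_library(n=3, n_codons=120, seed=5)
        coding = "".join(_CODON[a] for a in lib[0].seq[:60])
        fl = _flanked(_random_seq(60, 1) + coding + _random_seq(20, 2),
                      _random_seq(200, 3))
        assert te_association(fl, lib, min_identity=65) is not None
        # stricter thresholds can only lose the hit, never create one
        for ident, ev in [(100.0, 1e-10), (65.0, 1e-300)]:
            hit = te_association(fl, lib, min_identity=ident, max_evalue=ev)
            assert hit is None or (hit.identity >= ident and hit.e_value <= ev)

    def test_family_token_parsing(self):
        assert te_family_of("TE0001", "LTR/Copia something") == "LTR/Copia"
        assert te_family_of("plain", "no family token") == "unknown"


class TestMirnaAssociation:
    def test_exact_embedded_mature_hit_with_zero_mismatches(self):
        mirnas = make_mature_mirnas(n=2, seed=3)
        mature = str(mirnas[0].seq)
        left = _random_seq(100, 4) + mature + _random_seq(79, 5)
        hits = mirna_association(_flanked(left, _random_seq(200, 6)), mirnas)
        exact = [h for h in hits if h.mirna_id == mirnas[0].id and h.mismatches == 0]
        assert len(exact) == 1 and exact[0].offset == 100

    @pytest.mark.parametrize("n_subs,expected", [(4, True), (5, False)])
    def test_mismatch_boundary(self, n_subs, expected):
        mirnas = make_mature_mirnas(n=1, seed=3)
        mature = list(str(mirnas[0].seq))
        for i in range(n_subs):
            pos = 2 + 4 * i
            mature[pos] = "A" if mature[pos] != "A" else "C"
        left = _random_seq(100, 7) + "".join(mature) + _random_seq(79, 8)
        hits = mirna_association(_flanked(left, _random_seq(200, 9)), mirnas)
        assert any(h.offset == 100 for h in hits) is expected

    def test_agrees_with_bruteforce_hamming_scan(self):
        mirnas = make_mature_mirnas(n=3, seed=13)
        fl = _flanked(_random_seq(400, 14), _random_seq(400, 15))
        region = fl.region
        got = {(h.mirna_id, h.strand, h.offset, h.mismatches)
               for h in mirna_association(fl, mirnas, max_mismatches=8)}
        expected = set()
        for m in mirnas:
            mat = str(m.seq)
            for strand, pat in (("+", mat), ("-", revcomp(mat))):
                for off, mm in hamming_hits(pat, region, 8):
                    expected.add((m.id, strand, off, mm))
        assert got == expected

    def test_mature_length_outside_range_rejected(self):
        bad = [ProteinRecord(id="x", seq="ACGT" * 8)]  # 32 nt
        with pytest.raises(ValueError):
            mirna_association(_flanked(_random_seq(50, 1), _random_seq(50, 2)), bad)


class TestHairpin:
    def test_perfect_inverted_repeat_with_mature_in_arm_is_valid(self):
        rng = np.random.default_rng(17)
        arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        window = arm + "TTCA" + revcomp(arm)
        assert validate_hairpin(window, 2, 16) is True

    def test_nussinov_matches_recursive_oracle(self):
        rng = np.random.default_rng(18)
        for n in (20, 35, 50, 80):
            for _ in range(3):
                seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
                assert len(nussinov_pairs(seq)) == nussinov_count(seq)

    def test_planted_hairpin_pairs_more_than_its_shuffle(self):
        rng = np.random.default_rng(19)
        arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 25))
        window = arm + "GAAA" + revcomp(arm)
        shuffled = "".join(rng.permutation(list(window)))
        assert len(nussinov_pairs(shuffled)) < len(nussinov_pairs(window))

    def test_poly_a_window_is_invalid(self):
        assert validate_hairpin("A" * 60, 20, 21) is False

    def test_too_short_window_errors(self):
        with pytest.raises(ValueError):
            validate_hairpin("ACGT" * 4, 0, 10)


class TestCategorizeAnnotation:
    @pytest.mark.parametrize(
        "desc,expected",
        [
            ("hypothetical protein", "hypothetical_uncharacterized"),
            ("Putative membrane protein", "hypothetical_uncharacterized"),
            ("heat shock protein 70", "stress_related"),
            ("WRKY transcription factor 40", "transcription_factor"),
            ("60S ribosomal protein L7", "housekeeping"),
            ("cellulose binding protein", "other"),
            (None, "non_functional"),
            ("", "non_functional"),
        ],
    )
    def test_keyword_mapping(self, desc, expected):
        assert categorize_annotation(desc) == expected

    def test_custom_keywords_override(self):
        custom = {"stress_related": ["xyzzy"]}
        assert categorize_annotation("xyzzy factor", custom) == "stress_related"
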