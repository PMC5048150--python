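"""Protospacer scanning against brute-force oracles; cut and fragment maths."""

import numpy as np
import pytest
from Bio.Restriction import TfiI
from Bio.Seq import Seq

from ki_audit.ntrk1_study import (
    CLEAVAGE_TEMPLATE_LENGTHS,
    NTRK1_DONOR_SEQ,
    NTRK1_GUIDE,
    NTRK1_GUIDE_SEQ,
    TFII_SITE,
)
from ki_audit.offtarget_scan import (
    bulge_alignment,
    find_protospacers,
    find_restriction_sites,
    hamming_mismatches,
    predict_cut_site,
    predict_fragments,
    revcomp,
)

IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT", "W": "AT",
         "R": "AG", "Y": "CT", "S": "CG", "K": "GT", "M": "AC"}


def brute_scan(seq: str, guide: str, max_mm: int, pam: str = "NGG"):
    """Position-by-position scan, pure python; returns {(strand, start1, mm)}.

    Minus-strand starts are mirrored to the lowest + strand coordinate of
    the window, matching the scanner's reporting convention.
    """
    hits = set()
    n, p = len(guide), len(pam)

    def pam_ok(tri):
        return len(tri) == p and all(b in IUPAC[c] for b, c in zip(tri, pam))

    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(L - n - p + 1):
            if not pam_ok(s[i + n:i + n + p]):
                continue
            mm = sum(a != b for a, b in zip(guide, s[i:i + n]))
            if mm <= max_mm:
                start1 = i + 1 if strand == "+" else L - (i + n) + 1
                hits.add((strand, start1, mm))
    return hits


class TestHamming:
    def test_identity_is_zero(self):
        assert hamming_mismatches(NTRK1_GUIDE_SEQ, NTRK1_GUIDE_SEQ) == 0

    def test_complement_differs_everywhere(self):
        comp = str(Seq(NTRK1_GUIDE_SEQ).complement())
        assert hamming_mismatches(NTRK1_GUIDE_SEQ, comp) == 20

    def test_three_planted_substitutions(self):
        site = list(NTRK1_GUIDE_SEQ)
        for i in (2, 9, 17):
            site[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[i]]
        site = "".join(site)
        brute = sum(a != b for a, b in zip(NTRK1_GUIDE_SEQ, site))
        assert hamming_mismatches(NTRK1_GUIDE_SEQ, site) == brute == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_mismatches("ACGT", "ACG")


def brute_bulge(guide: str, window: str):
    """Independent enumeration of single-gap alignments (DP-free)."""
    cands = []
    if len(window) == len(guide):
        cands.append((0, sum(a != b for a, b in zip(guide, window))))
    for i in range(len(guide)):  # skip a guide base
        g = guide[:i] + guide[i + 1:]
        if len(g) == len(window):
            cands.append((1, sum(a != b for a, b in zip(g, window))))
    for i in range(len(window)):  # skip a window base
        w = window[:i] + window[i + 1:]
        if len(w) == len(guide):
            cands.append((1, sum(a != b for a, b in zip(guide, w))))
    b, m = min(cands)
    return m, b


class TestBulgeAlignment:
    def test_exact_20mer_no_gap(self):
        mm, b, span = bulge_alignment(NTRK1_GUIDE_SEQ, NTRK1_GUIDE_SEQ)
        assert (mm, b, span) == (0, 0, (1, 20))

    def test_single_deletion_gives_one_bulge(self):
        window = NTRK1_GUIDE_SEQ[:7] + NTRK1_GUIDE_SEQ[8:]  # drop base 8
        mm, b, _ = bulge_alignment(NTRK1_GUIDE_SEQ, window)
        assert (mm, b) == (0, 1)

    def test_single_insertion_gives_one_bulge(self):
        window = NTRK1_GUIDE_SEQ[:11] + "A" + NTRK1_GUIDE_SEQ[11:]
        mm, b, _ = bulge_alignment(NTRK1_GUIDE_SEQ, window)
        assert b == 1 and mm <= 1

    @pytest.mark.parametrize("wlen", [19, 20, 21])
    def test_random_windows_match_enumeration_oracle(self, wlen):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            window = "".join(bases[rng.integers(0, 4, size=wlen)])
            mm, b, _ = bulge_alignment(NTRK1_GUIDE_SEQ, window)
            assert (mm, b) == brute_bulge(NTRK1_GUIDE_SEQ, window)

    def test_window_length_bounds(self):
        with pytest.raises(ValueError):
            bulge_alignment(NTRK1_GUIDE_SEQ, "ACGT")


class TestFindProtospacers:
    def test_planted_exact_site_found_once(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=300)])
        seq = seq[:100] + NTRK1_GUIDE_SEQ + "AGG" + seq[123:]
        hits = find_protospacers(seq, NTRK1_GUIDE, max_mismatch=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.strand, h.protospacer_start, h.mismatches) == ("+", 101, 0)
        assert h.pam_seq == "AGG"

    def test_strand_involution(self):
        rng = np.random.default_rng(1)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=500)])
        seq = seq[:200] + NTRK1_GUIDE_SEQ + "TGG" + seq[223:]
        fwd = find_protospacers(seq, NTRK1_GUIDE, max_mismatch=3)
        rev = find_protospacers(revcomp(seq), NTRK1_GUIDE, max_mismatch=3)
        L = len(seq)
        mirrored = {
            ("-" if h.strand == "+" else "+",
             L - (h.protospacer_start + len(h.protospacer_seq) - 1) + 1,
             h.mismatches)
            for h in rev
        }
        assert {(h.strand, h.protospacer_start, h.mismatches) for h in fwd} == mirrored

    @pytest.mark.parametrize("max_mm", [0, 2, 4, 6])
    def test_equals_brute_force_on_random_sequence(self, max_mm):
        rng = np.random.default_rng(7 + max_mm)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=2000)])
        got = {
            (h.strand, h.protospacer_start, h.mismatches)
            for h in find_protospacers(seq, NTRK1_GUIDE, max_mm)
        }
        assert got == brute_scan(seq, NTRK1_GUIDE_SEQ, max_mm)

    def test_adversarial_sequence_has_no_hit(self):
        # windows of a fixed non-guide letter differ from the guide at >max_mm
        # positions everywhere; append PAMs to make the scan non-trivial
        seq = ("T" * 60) + "AGGAGG" + ("T" * 60)
        hits = find_protospacers(seq, NTRK1_GUIDE, max_mismatch=4)
        assert hits == []

    def test_bad_max_mismatch_rejected(self):
        with pytest.raises(ValueError):
            find_protospacers("A" * 50, NTRK1_GUIDE, max_mismatch=21)

    def test_bulge_hit_reported_when_enabled(self):
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=300)])
        window = NTRK1_GUIDE_SEQ[:10] + NTRK1_GUIDE_SEQ[11:]  # 19-nt, one bulge
        planted = seq[:100] + window + "CGG" + seq[122:]
        assert find_protospacers(planted, NTRK1_GUIDE, 0, allow_bulge=False) == []
        hits = find_protospacers(planted, NTRK1_GUIDE, 0, allow_bulge=True)
        assert any(h.bulges == 1 and h.mismatches == 0 for h in hits)


class TestCutAndFragments:
    def test_plus_strand_cut_arithmetic(self):
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=300)])
        seq = seq[:100] + NTRK1_GUIDE_SEQ + "AGG" + seq[123:]
        (hit,) = find_protospacers(seq, NTRK1_GUIDE, 0)
        assert predict_cut_site(hit, NTRK1_GUIDE) == 117  # between 117 and 118

    def test_minus_strand_cut_mirrored(self):
        rng = np.random.default_rng(6)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=300)])
        plus = seq[:100] + NTRK1_GUIDE_SEQ + "AGG" + seq[123:]
        minus = revcomp(plus)
        (hit,) = find_protospacers(minus, NTRK1_GUIDE, 0)
        assert hit.strand == "-"
        # plus coord x mirrors to L+1-x; the base 5' of the cut on the
        # protospacer strand was 117, so here it is L+1-117
        L = len(minus)
        assert predict_cut_site(hit, NTRK1_GUIDE) == L + 1 - 117

    def test_cut_offset_one(self):
        from ki_audit.variant_model import GuideDesign

        guide1 = GuideDesign(guide_seq=NTRK1_GUIDE_SEQ, cut_offset=1)
        seq = "A" * 100 + NTRK1_GUIDE_SEQ + "AGG" + "A" * 100
        (hit,) = find_protospacers(seq, guide1, 0)
        assert predict_cut_site(hit, guide1) == 119

    @pytest.mark.parametrize("name,length", sorted(CLEAVAGE_TEMPLATE_LENGTHS.items()))
    def test_fragments_conserve_template_length(self, name, length):
        rng = np.random.default_rng(abs(hash(name)) % 2**31)
        for cut in rng.integers(1, length, size=20):
            left, right = predict_fragments(length, int(cut))
            assert left + right == length

    def test_ntrk1_template_example(self):
        left, right = predict_fragments(CLEAVAGE_TEMPLATE_LENGTHS["Ntrk1"], 1200)
        assert (left, right) == (1200, 749)

    def test_boundary_cut(self):
        assert predict_fragments(1907, 1) == (1, 1906)
        with pytest.raises(ValueError):
            predict_fragments(1907, 1907)


class TestRestrictionSites:
    def test_too_short_sequence(self):
        assert find_restriction_sites("GAT", TFII_SITE) == []

    def test_w_degeneracy(self):
        assert find_restriction_sites("GAATC", "GAWTC") == [1]
        assert find_restriction_sites("GATTC", "GAWTC") == [1]
        assert find_restriction_sites("GACTC", "GAWTC") == []

    def test_overlapping_matches_reported(self):
        assert find_restriction_sites("AAAA", "AA") == [1, 2, 3]

    def test_donor_contains_tfii_site_matching_brute_scan(self):
        brute = [
            i + 1
            for i in range(len(NTRK1_DONOR_SEQ) - 4)
            if NTRK1_DONOR_SEQ[i] == "G" and NTRK1_DONOR_SEQ[i + 1] == "A"
            and NTRK1_DONOR_SEQ[i + 2] in "AT"
            and NTRK1_DONOR_SEQ[i + 3:i + 5] == "TC"
        ]
        got = find_restriction_sites(NTRK1_DONOR_SEQ, TFII_SITE)
        assert got == brute
        assert len(got) >= 1  # the donor plants a genotyping site

    def test_agrees_with_biopython_tfii(self):
        # independent cross-check: Biopython's TfiI site finder
        positions = TfiI.search(Seq(NTRK1_DONOR_SEQ))
        # Bio.Restriction reports cut positions; map back to site starts
        ours = find_restriction_sites(NTRK1_DONOR_SEQ, TFII_SITE)
        assert len(positions) == len(ours)

    def test_invalid_iupac_code(self):
        with pytest.raises(ValueError):
            find_restriction_sites("ACGT", "GAQTC")
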