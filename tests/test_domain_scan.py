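"""Profile construction, window scanning, null calibration and HMMER interop."""

import json
import math

import numpy as np
import pytest

from genefamkit.domain_scan import (
    DomainHit,
    build_profile,
    calibrate_threshold,
    filter_hits,
    fit_null_calibration,
    load_bundled_profile,
    read_domtblout,
    scan_protein,
)


class TestBuildProfile:
    def test_observed_vs_unobserved_residue(self):
        profile = build_profile(["ACD", "ACD"])
        # column 0: A observed twice, W never
        assert profile.scores[0, 0] > 0  # A
        assert profile.scores[0, 18] < 0  # W

    def test_hand_arithmetic_with_pseudocount(self):
        # column with residues A,A,A,C; uniform background; pseudocount 1
        profile = build_profile(["A", "A", "A", "C"], pseudocount=1.0)
        expected = math.log2((3 + 0.05) / ((4 + 1) * 0.05))
        assert profile.scores[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_huge_pseudocount_flattens_scores(self):
        profile = build_profile(["ACD", "ACD"], pseudocount=1e9)
        assert np.abs(profile.scores).max() < 1e-6

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["ACD", "AC"])

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["AXD", "ACD"])


class TestScanProtein:
    def test_recovers_planted_domain_at_exact_position(self, ap2_profile):
        rng = np.random.default_rng(0)
        from genefamkit.domain_scan import AA_ALPHABET

        domain = ap2_profile.consensus
        flank = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 40))
        protein = flank + domain + flank
        hits = scan_protein(protein, ap2_profile, threshold=50.0, gene_id="g")
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (40, 40 + ap2_profile.length)
        assert hits[0].coverage == 1.0

    def test_score_additivity_full_coverage(self, ap2_profile):
        """A full-coverage hit's score equals the sum of its per-column scores."""
        from genefamkit.domain_scan import AA_INDEX

        domain = ap2_profile.consensus
        protein = "M" * 20 + domain + "M" * 20
        hits = scan_protein(protein, ap2_profile, threshold=50.0)
        expected = sum(
            ap2_profile.scores[c, AA_INDEX[a]] for c, a in enumerate(domain)
        )
        assert hits[0].score == pytest.approx(expected, abs=1e-9)

    def test_shift_equivariance(self, ap2_profile):
        """Prepending k background residues shifts every hit by exactly k."""
        rng = np.random.default_rng(3)
        from genefamkit.domain_scan import AA_ALPHABET

        domain = ap2_profile.consensus
        protein = domain + "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 30))
        prefix = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 13))
        base = scan_protein(protein, ap2_profile, threshold=50.0)
        shifted = scan_protein(prefix + protein, ap2_profile, threshold=50.0)
        assert [(h.start + 13, h.end + 13) for h in base] == [
            (h.start, h.end) for h in shifted
        ]

    def test_two_domain_protein_yields_two_hits(self, ap2_profile):
        domain = ap2_profile.consensus
        protein = "M" * 15 + domain + "L" * 25 + domain + "M" * 15
        hits = scan_protein(protein, ap2_profile, threshold=50.0)
        assert len(hits) == 2
        assert hits[0].end <= hits[1].start

    def test_truncated_window_reduces_coverage(self, ap2_profile):
        # domain cut at the N-terminus: only the last 30 columns remain
        domain = ap2_profile.consensus
        protein = domain[-30:] + "M" * 60
        hits = scan_protein(protein, ap2_profile, threshold=30.0)
        partial = [h for h in hits if h.start == 0]
        assert partial and partial[0].coverage < 1.0
        assert partial[0].profile_start == ap2_profile.length - 30

    def test_short_protein_gives_empty_result(self, ap2_profile):
        assert scan_protein("MKLFGV", ap2_profile, threshold=0.0) == []


class TestCalibration:
    def test_threshold_monotone_in_target_evalue(self, ap2_profile):
        t_strict = calibrate_threshold(ap2_profile, target_evalue=1e-6, seed=5)
        t_loose = calibrate_threshold(ap2_profile, target_evalue=1e-3, seed=5)
        assert t_strict > t_loose

    def test_same_seed_same_threshold(self, ap2_profile):
        a = calibrate_threshold(ap2_profile, target_evalue=1e-5, seed=11)
        b = calibrate_threshold(ap2_profile, target_evalue=1e-5, seed=11)
        assert a == b

    def test_false_hit_rate_matches_target(self, ap2_profile):
        """At target E-value 1e-3, 1000 fresh null sequences should yield
        few false hits (expected ~1)."""
        threshold = calibrate_threshold(
            ap2_profile, n_shuffles=500, protein_length=300, target_evalue=1e-3, seed=21
        )
        rng = np.random.default_rng(99)
        false_hits = 0
        for _ in range(1000):
            protein = "".join(
                "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 300)
            )
            false_hits += len(scan_protein(protein, ap2_profile, threshold))
        assert false_hits <= 5

    def test_too_few_shuffles_rejected(self, ap2_profile):
        with pytest.raises(ValueError):
            fit_null_calibration(ap2_profile, n_shuffles=50)


class TestDomtblout:
    HEADER = "#                                                               --- full sequence --- -------------- this domain -------------\n"
    ROW = ("gene1 - 200 AP2 PF00847.1 58 1.2e-30 101.0 0.1 1 3 1e-12 2.2e-10 "
           "40.0 0.1 1 58 5 64 5 64 0.95 desc\n")

    def test_coordinates_and_evalue(self, tmp_path):
        path = tmp_path / "hits.domtblout"
        path.write_text(self.HEADER + self.ROW)
        hits = read_domtblout(path)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (4, 64)  # env 5..64, 1-based inclusive
        assert h.evalue == pytest.approx(2.2e-10)
        assert h.gene_id == "gene1" and h.profile_name == "AP2"
        assert h.coverage == pytest.approx(1.0)

    def test_multiple_domains_same_gene_and_comments(self, tmp_path):
        path = tmp_path / "hits.domtblout"
        path.write_text(self.HEADER + self.ROW * 3)
        hits = read_domtblout(path)
        assert len(hits) == 3 and {h.gene_id for h in hits} == {"gene1"}

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.domtblout"
        path.write_text(self.ROW + "broken line\n")
        with pytest.raises(ValueError, match="line 2"):
            read_domtblout(path)


class TestFilterHits:
    @staticmethod
    def hit(evalue, coverage):
        return DomainHit("g", "AP2", 0, 58, 100.0, evalue, coverage)

    def test_evalue_and_coverage_rules(self):
        kept = filter_hits(
            [self.hit(1e-6, 0.9), self.hit(1e-4, 0.9), self.hit(1e-6, 0.5)],
            max_evalue=1e-5,
            min_coverage=0.7,
        )
        assert len(kept) == 1 and kept[0].evalue == 1e-6

    def test_empty_input(self):
        assert filter_hits([]) == []
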