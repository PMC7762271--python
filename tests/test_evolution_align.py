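"""Needleman-Wunsch affine-gap alignment against a brute-force oracle, and
duplicate-pair detection semantics."""

import itertools
import math

import numpy as np
import pytest

from genefamkit.evolution import find_duplicates, global_align


def brute_force_best_score(a, b, match=2.0, mismatch=-1.0, gap_open=-5.0,
                           gap_extend=-1.0):
    """Exhaustive enumeration of all global alignments (tiny inputs only)."""
    best = -math.inf

    def rec(i, j, score, prev):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            pen = gap_extend + (gap_open if prev != "F" else 0.0)
            rec(i + 1, j, score + pen, "F")
        if j < len(b):
            pen = gap_extend + (gap_open if prev != "E" else 0.0)
            rec(i, j + 1, score + pen, "E")

    rec(0, 0, 0.0, None)
    return best


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.identity == 1.0
        assert "-" not in aln.aligned_a + aln.aligned_b
        assert aln.score == 8.0

    def test_single_deletion(self):
        aln = global_align("ACGT", "ACT")
        assert len(aln.aligned_a) == 4
        assert (aln.aligned_a + aln.aligned_b).count("-") == 1
        assert aln.identity == pytest.approx(3 / 4)

    def test_gap_removal_recovers_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 40)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 40)))
            aln = global_align(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b
            assert len(aln.aligned_a) == len(aln.aligned_b)

    def test_score_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        cases = [("A", "A"), ("A", "T"), ("AC", "CA"), ("ACGT", "ACT")]
        cases += [
            ("".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 7))),
             "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 7))))
            for _ in range(30)
        ]
        for a, b in cases:
            aln = global_align(a, b)
            assert aln.score == pytest.approx(brute_force_best_score(a, b)), (a, b)

    def test_traceback_score_consistency(self):
        """The emitted alignment re-scores to the reported optimum."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, 25))
            aln = global_align(a, b)
            score, in_gap_a, in_gap_b = 0.0, False, False
            for x, y in zip(aln.aligned_a, aln.aligned_b):
                if x == "-":
                    score += -1.0 + (0.0 if in_gap_a else -5.0)
                    in_gap_a, in_gap_b = True, False
                elif y == "-":
                    score += -1.0 + (0.0 if in_gap_b else -5.0)
                    in_gap_a, in_gap_b = False, True
                else:
                    score += 2.0 if x == y else -1.0
                    in_gap_a = in_gap_b = False
            assert score == pytest.approx(aln.score)


class TestFindDuplicates:
    def test_boundary_identity_strictly_excluded(self):
        rng = np.random.default_rng(13)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        exact = list(a)
        for pos in rng.choice(100, size=15, replace=False):
            exact[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[exact[pos]]
        b_085 = "".join(exact)  # identity exactly 0.85
        retained, _ = find_duplicates({"a": a, "b": b_085})
        assert retained == []

        above = list(a)
        for pos in rng.choice(100, size=14, replace=False):
            above[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[above[pos]]
        retained, clusters = find_duplicates({"a": a, "b": "".join(above)})
        assert len(retained) == 1 and clusters == {"a": 1, "b": 1}

    def test_planted_duplicate_at_low_ks_retained(self):
        from genefamkit.synthetic_data import back_translate, mutate_duplicate

        rng = np.random.default_rng(2)
        protein = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 150))
        cds = back_translate(protein, rng)[:-3]
        mutated, _, _ = mutate_duplicate(cds, omega=0.5, ks_target=0.05, seed=1)
        unrelated = back_translate(
            "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 150)), rng
        )[:-3]
        retained, clusters = find_duplicates({"a": cds, "b": mutated, "c": unrelated})
        assert {frozenset((p.seq_a_id, p.seq_b_id)) for p in retained} == {
            frozenset(("a", "b"))
        }
        assert "c" not in clusters

    def test_mutually_similar_trio_forms_one_cluster(self):
        from genefamkit.synthetic_data import back_translate, mutate_duplicate

        rng = np.random.default_rng(9)
        protein = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 120))
        cds = back_translate(protein, rng)[:-3]
        m1, _, _ = mutate_duplicate(cds, 0.3, 0.03, seed=2)
        m2, _, _ = mutate_duplicate(cds, 0.3, 0.03, seed=3)
        retained, clusters = find_duplicates({"x": cds, "y": m1, "z": m2})
        assert set(clusters) == {"x", "y", "z"}
        assert len(set(clusters.values())) == 1

    def test_retained_set_matches_independent_recomputation(self):
        """Retained pairs are exactly the all-pairs identity > threshold set."""
        rng = np.random.default_rng(21)
        seqs = {}
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
        for k in range(6):
            s = list(base)
            for pos in rng.choice(90, size=rng.integers(0, 40), replace=False):
                s[pos] = "ACGT"[rng.integers(4)]
            seqs[f"s{k}"] = "".join(s)
        retained, _ = find_duplicates(seqs, identity_threshold=0.85)
        got = {frozenset((p.seq_a_id, p.seq_b_id)) for p in retained}
        expected = set()
        for x, y in itertools.combinations(sorted(seqs), 2):
            if global_align(seqs[x], seqs[y]).identity > 0.85:
                expected.add(frozenset((x, y)))
        assert got == expected
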