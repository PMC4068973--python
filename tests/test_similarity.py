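"""Alignment, JC69 distance against its closed form, matrix invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miningabs.io_formats import Platform, Probe
from miningabs.similarity import (
    align_pair,
    build_similarity_matrix,
    evolutionary_distance,
    similarity,
    summarize_similarity,
)

BASES = "ACGT"


def mutate(seq, positions, rng):
    """Substitute the given positions with a different base each."""
    s = list(seq)
    for i in positions:
        s[i] = rng.choice([b for b in BASES if b != s[i]])
    return "".join(s)


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


class TestAlignPair:
    def test_identical_sequences_align_fully(self):
        a = align_pair("ACGT", "ACGT")
        assert a.overlap == 4 and a.mismatches == 0

    def test_internal_substring_aligns_with_free_end_gaps(self):
        a = align_pair("ACGTACGTAC", "GTAC")
        assert a.overlap == 4 and a.mismatches == 0

    def test_substitution_count_is_recovered(self):
        rng = np.random.default_rng(42)
        seq = random_seq(rng, 100)
        positions = rng.choice(100, size=10, replace=False)
        mutated = mutate(seq, positions, rng)
        a = align_pair(seq, mutated)
        assert a.overlap == 100 and a.mismatches == 10

    def test_n_never_matches(self):
        # the flanking matches force the N column into the alignment,
        # where it must count as a mismatch even against another N
        a = align_pair("AANAA", "AANAA")
        assert a.overlap == 5
        assert a.matches == 4 and a.mismatches == 1

    def test_equal_length_dissimilar_pair_is_forced_end_to_end(self):
        # the shorter sequence pays for trimmed ends, so it cannot escape
        # into a tiny overlap: all four columns align and mismatch
        a = align_pair("AAAA", "TTTT")
        assert a.overlap == 4 and a.mismatches == 4

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestEvolutionaryDistance:
    def test_identical_sequences_have_zero_distance(self):
        assert evolutionary_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_matches_closed_form_at_ten_percent_mismatch(self):
        # 100 columns, 10 mismatches: d = -0.75*ln(1 - 0.4/3)
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 100)
        mutated = mutate(seq, rng.choice(100, size=10, replace=False), rng)
        expected = -0.75 * np.log(1 - 0.4 / 3)
        assert evolutionary_distance(seq, mutated) == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(0.10732, abs=1e-5)

    def test_saturated_mismatch_clamps_to_one(self):
        from miningabs.similarity import jc69_distance

        assert jc69_distance(0.75) == 1.0
        assert jc69_distance(0.9) == 1.0
        # the log is defined just below saturation but exceeds 1: still clamped
        assert jc69_distance(0.74) == 1.0

    def test_saturated_pair_has_maximal_distance_and_zero_similarity(self):
        assert evolutionary_distance("AAAA", "TTTT") == 1.0
        assert similarity("AAAA", "TTTT") == 0.0

    def test_agrees_with_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(40, 120))
            seq = random_seq(rng, n)
            n_mut = int(rng.integers(0, n // 4))
            mutated = mutate(seq, rng.choice(n, size=n_mut, replace=False), rng)
            a = align_pair(seq, mutated)
            p = a.mismatch_proportion
            expected = 1.0 if p >= 0.75 else min(
                1.0, -0.75 * np.log(1 - 4 * p / 3)
            )
            assert evolutionary_distance(seq, mutated) == pytest.approx(
                expected, abs=1e-9
            )


class TestSimilarity:
    def test_complements_distance(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 80)
        mutated = mutate(seq, rng.choice(80, size=8, replace=False), rng)
        assert similarity(seq, mutated) == pytest.approx(
            1 - evolutionary_distance(seq, mutated), abs=1e-12
        )

    def test_is_symmetric(self):
        rng = np.random.default_rng(6)
        a, b = random_seq(rng, 60), random_seq(rng, 200)
        assert similarity(a, b) == pytest.approx(similarity(b, a), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n_muts=st.lists(st.integers(min_value=0, max_value=40), min_size=2,
                        max_size=6),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_similarity_non_increasing_in_substitution_count(self, n_muts, seed):
        # nested variants: replacement bases are drawn once per position, so
        # the m-substitution copy is a sub-mutation of the (m+1)-copy
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 120)
        positions = rng.choice(120, size=max(n_muts), replace=False)
        fully_mutated = mutate(seq, positions, rng)
        scores = []
        for m in sorted(n_muts):
            variant = list(seq)
            for i in positions[:m]:
                variant[i] = fully_mutated[i]
            scores.append(similarity(seq, "".join(variant)))
        assert all(b <= a + 1e-12 for a, b in zip(scores, scores[1:]))


def _platforms_from_sequences(layout):
    """layout: {platform_id: [(probe_id, gene_id, sequence), ...]}"""
    return [
        Platform(pf, [Probe(pid, gid, seq) for pid, gid, seq in probes])
        for pf, probes in layout.items()
    ]


class TestBuildMatrix:
    def test_structure_on_toy_layout(self):
        rng = np.random.default_rng(0)
        platforms = _platforms_from_sequences(
            {
                "PF1": [("P1", "G1", random_seq(rng, 50)),
                        ("P2", "G1", random_seq(rng, 50)),
                        ("P3", "G3", random_seq(rng, 50))],
                "PF2": [("P1", "G1", random_seq(rng, 50)),
                        ("P2", "G2", random_seq(rng, 50))],
                "PF3": [("P1", "G2", random_seq(rng, 30)),
                        ("P2", "G3", random_seq(rng, 30))],
            }
        )
        M = build_similarity_matrix(platforms)
        assert M.values.shape == (7, 7)
        np.testing.assert_allclose(M.values, M.values.T, atol=1e-12)
        assert np.all(np.diag(M.values) == 1.0)
        assert M.values.min() >= 0.0 and M.values.max() <= 1.0

    def test_identical_cross_platform_sequence_scores_one(self):
        rng = np.random.default_rng(1)
        shared = random_seq(rng, 60)
        platforms = _platforms_from_sequences(
            {
                "PF1": [("P1", "G1", shared)],
                "PF2": [("P1", "G1", shared),
                        ("P2", "G2", random_seq(rng, 60))],
            }
        )
        M = build_similarity_matrix(platforms)
        assert M.entry("PF1", "P1", "PF2", "P1") == 1.0

    def test_recomputation_is_deterministic(self):
        rng = np.random.default_rng(2)
        platforms = _platforms_from_sequences(
            {"PF1": [("P1", "G1", random_seq(rng, 40))],
             "PF2": [("P1", "G2", random_seq(rng, 40))]}
        )
        M1 = build_similarity_matrix(platforms)
        M2 = build_similarity_matrix(platforms)
        np.testing.assert_array_equal(M1.values, M2.values)


class TestSummarize:
    def test_same_gene_probes_score_higher_than_random(self):
        rng = np.random.default_rng(9)
        n_genes = 100
        refs = [random_seq(rng, 80) for _ in range(n_genes)]
        layout = {}
        for pf_i in range(2):
            probes = []
            for g, ref in enumerate(refs):
                muts = rng.choice(80, size=2, replace=False)  # rate ~0.02
                probes.append((f"P{g + 1}", f"G{g + 1}", mutate(ref, muts, rng)))
            layout[f"PF{pf_i + 1}"] = probes
        platforms = _platforms_from_sequences(layout)
        M = build_similarity_matrix(platforms)
        summary = summarize_similarity(M, platforms)
        intra, inter = summary["intra"], summary["inter"]
        assert intra.averages()["max"] > inter.averages()["max"]
        assert np.all(intra.max_scores >= intra.mean_scores)
        assert np.all(intra.mean_scores >= intra.min_scores)
        assert summary["best_partner_same_gene_fraction"] > 0.9

    def test_single_shared_identical_gene_has_unit_intra_max(self):
        rng = np.random.default_rng(10)
        shared = random_seq(rng, 60)
        platforms = _platforms_from_sequences(
            {"PF1": [("P1", "G1", shared)], "PF2": [("P1", "G1", shared)]}
        )
        M = build_similarity_matrix(platforms)
        summary = summarize_similarity(M, platforms)
        assert np.all(summary["intra"].max_scores == 1.0)

    def test_disjoint_gene_sets_leave_intra_empty(self):
        rng = np.random.default_rng(11)
        platforms = _platforms_from_sequences(
            {"PF1": [("P1", "G1", random_seq(rng, 40))],
             "PF2": [("P1", "G2", random_seq(rng, 40))]}
        )
        M = build_similarity_matrix(platforms)
        summary = summarize_similarity(M, platforms)
        assert summary["intra"].n_probes == 0
        assert len(summary["no_partner"]) == 2
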