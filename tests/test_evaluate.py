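"""Greedy matching, accuracy, paired t-tests, Bonferroni, scoring."""

import numpy as np
import pytest
from scipy import stats

from fndecomp import evaluate
from fndecomp.datatypes import DecompositionResults, GroundTruth
from fndecomp.decomp import zscore_maps


def _greedy_oracle(S):
    """Literal loop implementation of the greedy rule."""
    S = S.copy().astype(float)
    pairs = []
    for _ in range(min(S.shape)):
        best, bi, bj = -np.inf, None, None
        for i in range(S.shape[0]):
            for j in range(S.shape[1]):
                if S[i, j] > best:
                    best, bi, bj = S[i, j], i, j
        pairs.append((bi, bj))
        S[bi, :] = -np.inf
        S[:, bj] = -np.inf
    return pairs


class TestGreedyMatch:
    def test_identity_dominant(self):
        S = np.full((3, 3), 0.1)
        np.fill_diagonal(S, 0.9)
        table = evaluate.greedy_match(S)
        assert sorted((e, t) for e, t, _ in table.pairs) == [(0, 0), (1, 1), (2, 2)]

    def test_greedy_differs_from_optimal_assignment(self):
        S = np.array([[0.9, 0.8], [0.85, 0.1]])
        table = evaluate.greedy_match(S)
        assert table.pairs == [(0, 0, 0.9), (1, 1, 0.1)]
        total = sum(s for _, _, s in table.pairs)
        assert total == pytest.approx(1.0)  # optimal pairing would give 1.65

    def test_rectangular_leaves_unmatched(self):
        S = np.random.default_rng(0).uniform(size=(3, 2))
        table = evaluate.greedy_match(S)
        assert len(table.pairs) == 2
        assert len(table.unmatched_estimates) == 1
        assert table.unmatched_templates == []

    def test_empty(self):
        table = evaluate.greedy_match(np.empty((0, 0)))
        assert table.pairs == []

    def test_matches_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            S = rng.uniform(size=(6, 6))
            got = [(e, t) for e, t, _ in evaluate.greedy_match(S).pairs]
            assert got == _greedy_oracle(S)


class TestAccuracy:
    def test_perfect_and_sign_invariant(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        assert evaluate.accuracy(x, x) == pytest.approx(1.0)
        assert evaluate.accuracy(-x, x) == pytest.approx(1.0)

    def test_known_value(self):
        assert evaluate.accuracy(
            np.array([1, 2, 3, 4]), np.array([1, 2, 3, 5])
        ) == pytest.approx(0.98270763, abs=1e-7)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            evaluate.accuracy(np.ones(5), np.arange(5.0))


class TestPairedTTest:
    def test_hand_computed_example(self):
        t, p = evaluate.paired_ttest(
            np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 5, 7])
        )
        assert t == pytest.approx(-3.6556, abs=1e-3)

    def test_shift_direction(self):
        rng = np.random.default_rng(2)
        b = rng.standard_normal(20) * 0.01
        t, p = evaluate.paired_ttest(b + 5.0 + 0.001 * rng.standard_normal(20), b)
        assert t > 50

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        t1, _ = evaluate.paired_ttest(a, b)
        t2, _ = evaluate.paired_ttest(b, a)
        assert t1 == -t2

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b = rng.standard_normal((2, 12))
            t, p = evaluate.paired_ttest(a, b)
            ref = stats.ttest_rel(a, b)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            evaluate.paired_ttest(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))


class TestBonferroni:
    def test_examples(self):
        assert evaluate.bonferroni([0.004, 0.2], 0.05) == [True, False]
        assert evaluate.bonferroni([0.049], 0.05) == [True]
        assert evaluate.bonferroni([0.006] * 10, 0.05) == [False] * 10
        assert evaluate.bonferroni([], 0.05) == []


def _results_from_truth(truths, method):
    maps = [zscore_maps(gt.maps) for gt in truths]
    tcs = [gt.tcs.copy() for gt in truths]
    return DecompositionResults(
        method=method,
        n_components=truths[0].n_sources,
        subject_maps=maps,
        subject_tcs=tcs,
        group_maps=zscore_maps(np.mean([m for m in maps], axis=0)),
    )


class TestScoreExperiment:
    @pytest.fixture(scope="class")
    def truths(self, small_sim):
        _, _, truths = small_sim
        return truths

    def test_truth_as_estimates_scores_one_and_reports_no_difference(self, truths):
        results = {
            "iva_gl": _results_from_truth(truths, "iva_gl"),
            "gigica": _results_from_truth(truths, "gigica"),
        }
        score = evaluate.score_experiment(results, truths)
        for table in score.tables.values():
            np.testing.assert_allclose(table.spatial.to_numpy(), 1.0, atol=1e-8)
        row = score.ttests[score.ttests.domain == "spatial"].iloc[0]
        assert row.t == 0.0 and row.p == 1.0

    def test_component_shuffle_invariance(self, truths):
        base = _results_from_truth(truths, "iva_gl")
        perm = [2, 0, 3, 1]
        shuffled = DecompositionResults(
            method="iva_gl",
            n_components=base.n_components,
            subject_maps=[m[perm] for m in base.subject_maps],
            subject_tcs=[t[:, perm] for t in base.subject_tcs],
            group_maps=base.group_maps[perm],
        )
        a = evaluate.score_method(base, truths)
        b = evaluate.score_method(shuffled, truths)
        np.testing.assert_allclose(
            a.spatial.to_numpy(), b.spatial.to_numpy(), atol=1e-12
        )

    def test_unique_source_matching_leaves_one_component(self):
        # 3 common templates + 1 unique source per subject; 4 estimates.
        rng = np.random.default_rng(5)
        truths, maps = [], []
        common = rng.standard_normal((3, 500))
        for m in range(4):
            unique = rng.standard_normal(500)
            gm = np.vstack([common + 0.05 * rng.standard_normal((3, 500)), unique])
            tcs = rng.standard_normal((30, 4))
            truths.append(
                GroundTruth(
                    maps=gm,
                    tcs=tcs,
                    labels=["common"] * 3 + ["unique"],
                    source_ids=[0, 1, 2, -1],
                )
            )
        res = _results_from_truth(truths, "iva_gl")
        table = evaluate.score_method(res, truths)
        assert "unique" in table.spatial.columns
        assert len(table.match.pairs) == 3
        assert len(table.match.unmatched_estimates) == 1
        np.testing.assert_allclose(table.spatial["unique"], 1.0, atol=1e-8)


def test_optimal_match_is_a_diagnostic_upper_bound():
    S = np.array([[0.9, 0.8], [0.85, 0.1]])
    greedy_total = sum(s for _, _, s in evaluate.greedy_match(S).pairs)
    optimal_total = sum(s for _, _, s in evaluate.optimal_match(S).pairs)
    assert optimal_total == pytest.approx(1.65)
    assert optimal_total >= greedy_total
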