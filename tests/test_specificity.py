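"""Specificity scoring, activity calls and co-factor rank statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from coregrn.specificity import (
    ExpressionCompendium,
    activation_probability,
    activity_pvalue,
    calibrate_correlation_cutoff,
    cofactor_rank_zscore,
    filter_correlated_samples,
    select_identity_tfs,
    specificity_score,
)


def make_compendium(values: np.ndarray, genes, samples) -> ExpressionCompendium:
    return ExpressionCompendium(
        values=pd.DataFrame(values, index=genes, columns=samples)
    )


class TestSpecificity:
    def test_query_exclusive_tf_scores_one(self):
        comp = make_compendium(np.zeros((1, 3)), ["A"], ["s1", "s2", "s3"])
        q = pd.Series({"A": 50.0})
        assert specificity_score("A", q, comp) == pytest.approx(1.0)

    def test_uniform_tf_matches_direct_jsd_evaluation(self):
        comp = make_compendium(np.full((1, 3), 10.0), ["A"], ["s1", "s2", "s3"])
        q = pd.Series({"A": 10.0})
        # independent oracle: explicit sqrt(JSD) of delta vs uniform over 4
        ideal = np.array([1.0, 0, 0, 0])
        uniform = np.full(4, 0.25)
        expected = 1.0 - jensenshannon(uniform, ideal, base=2)
        assert specificity_score("A", q, comp) == pytest.approx(expected)

    def test_off_query_expression_minimizes_specificity(self):
        # mass on one background sample scores below any placement with
        # query mass, exhaustively over placements
        scores = []
        for pos in range(4):
            row = np.zeros(3)
            qval = 0.0
            if pos == 0:
                qval = 10.0
            else:
                row[pos - 1] = 10.0
            comp = make_compendium(row[None, :], ["A"], ["s1", "s2", "s3"])
            scores.append(specificity_score("A", pd.Series({"A": qval}), comp))
        assert scores[0] == max(scores)
        assert all(s == pytest.approx(scores[1]) for s in scores[1:])
        assert scores[1] == min(scores)

    def test_all_zero_expression_is_an_error(self):
        comp = make_compendium(np.zeros((1, 3)), ["A"], ["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            specificity_score("A", pd.Series({"A": 0.0}), comp)

    def test_specificity_strictly_decreases_as_mass_moves_off_query(self):
        prev = np.inf
        for off in np.linspace(0.0, 0.9, 10):
            comp = make_compendium(
                np.array([[off * 100, 0.0]]), ["A"], ["s1", "s2"]
            )
            s = specificity_score("A", pd.Series({"A": (1 - off) * 100}), comp)
            assert s < prev or off == 0.0
            prev = s


class TestIdentitySelection:
    def test_planted_specific_tfs_are_selected_with_tie_break(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i:02d}" for i in range(20)]
        vals = rng.uniform(5, 50, size=(20, 10))
        vals[:5] = 0.0  # planted: silent in background
        comp = make_compendium(vals, genes, [f"s{j}" for j in range(10)])
        q = pd.Series(0.0, index=genes)
        q[genes[:5]] = 100.0
        top = select_identity_tfs(q, comp, n=5)
        assert [r.tf for r in top] == genes[:5]  # equal scores -> lexicographic
        assert [r.rank for r in top] == [1, 2, 3, 4, 5]

    def test_selection_invariant_to_sample_order(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(8)]
        samples = [f"s{j}" for j in range(6)]
        vals = rng.uniform(0, 30, size=(8, 6))
        comp = make_compendium(vals, genes, samples)
        q = pd.Series(rng.uniform(0, 30, 8), index=genes)
        shuffled = comp.subset_samples(list(reversed(samples)))
        a = [r.tf for r in select_identity_tfs(q, comp, n=4)]
        b = [r.tf for r in select_identity_tfs(q, shuffled, n=4)]
        assert a == b

    def test_oversized_request_returns_all_with_warning(self):
        comp = make_compendium(np.ones((2, 3)), ["A", "B"], ["s1", "s2", "s3"])
        q = pd.Series({"A": 1.0, "B": 2.0})
        with pytest.warns(UserWarning):
            res = select_identity_tfs(q, comp, n=10)
        assert len(res) == 2


class TestCorrelationFilter:
    def test_planted_near_duplicates_are_removed_exactly(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(50)]
        q = pd.Series(rng.uniform(0, 100, 50), index=genes)
        cols = {}
        for j in range(100):
            if j < 10:  # planted near-duplicates of the query
                cols[f"dup{j}"] = q.values * rng.uniform(0.95, 1.05, 50)
            else:
                cols[f"bg{j}"] = rng.uniform(0, 100, 50)
        comp = ExpressionCompendium(values=pd.DataFrame(cols, index=genes))
        kept = filter_correlated_samples(q, comp, cutoff=0.75)
        removed = set(comp.samples) - set(kept.samples)
        assert removed == {f"dup{j}" for j in range(10)}

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(20)]
        comp = make_compendium(
            rng.uniform(0, 50, (20, 15)), genes, [f"s{j}" for j in range(15)]
        )
        q = pd.Series(rng.uniform(0, 50, 20), index=genes)
        once = filter_correlated_samples(q, comp, cutoff=0.5)
        twice = filter_correlated_samples(q, once, cutoff=0.5)
        assert once.samples == twice.samples

    def test_too_few_shared_genes_is_an_error(self):
        comp = make_compendium(np.ones((2, 3)), ["A", "B"], ["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            filter_correlated_samples(pd.Series({"A": 1.0}), comp, 0.75)


class TestCutoffCalibration:
    def test_separable_classes_give_perfect_f1_cutoff(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(40)]
        proto = rng.uniform(10, 100, 40)
        cols, labels = {}, {}
        for j in range(12):
            cols[f"p{j}"] = proto * rng.uniform(0.98, 1.02, 40)
            labels[f"p{j}"] = True
        for j in range(12):
            cols[f"n{j}"] = rng.uniform(0, 100, 40)
            labels[f"n{j}"] = False
        comp = ExpressionCompendium(values=pd.DataFrame(cols, index=genes))
        cut = calibrate_correlation_cutoff(comp, labels)
        # ties go to the larger cutoff: the largest grid value with F1 = 1,
        # which must still separate the diffuse negatives from the positives
        assert 0.5 < cut <= 1.0

    def test_single_class_labels_rejected(self):
        comp = make_compendium(np.ones((3, 4)), list("ABC"), list("wxyz"))
        with pytest.raises(ValueError):
            calibrate_correlation_cutoff(comp, {s: True for s in "wxyz"})


class TestActivity:
    def test_pvalue_counting_formula(self):
        bg = np.arange(99, dtype=float)
        assert activity_pvalue(1000.0, bg) == pytest.approx(1 / 100)
        # at the median of an odd-sized background, p ~ 0.5 -> inactive
        assert activity_pvalue(49.0, bg) == pytest.approx(51 / 100)

    def test_activation_probability_is_empirical_cdf(self):
        bg = np.arange(40, dtype=float)
        assert activation_probability(-1.0, bg) == 0.0
        assert activation_probability(1000.0, bg) == 1.0
        assert activation_probability(30.0, bg) == pytest.approx(0.75)

    def test_monotonicity_in_expression(self):
        rng = np.random.default_rng(5)
        bg = rng.uniform(0, 100, 60)
        xs = np.linspace(-10, 110, 50)
        ps = [activity_pvalue(x, bg) for x in xs]
        cdfs = [activation_probability(x, bg) for x in xs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(a <= b for a, b in zip(cdfs, cdfs[1:]))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            activity_pvalue(1.0, np.array([]))
        with pytest.raises(ValueError):
            activation_probability(1.0, np.array([]))


class TestCofactorZscore:
    def test_boundary_and_degenerate_cases(self):
        z = cofactor_rank_zscore("A", 5, np.array([20, 80]))  # mean 50, sd 30
        assert z.z == pytest.approx(-1.5)
        assert z.eligible
        flat = cofactor_rank_zscore("A", 7, np.array([7, 7, 7]))
        assert flat.z == 0.0 and not flat.eligible
        below = cofactor_rank_zscore("A", 3, np.array([7, 7, 7]))
        assert below.z == float("-inf") and below.eligible
        above = cofactor_rank_zscore("A", 90, np.array([20, 80]))
        assert above.z > 0 and not above.eligible

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            cofactor_rank_zscore("A", 1, np.array([5]))
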