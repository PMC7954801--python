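"""Boolean-DTMC dynamics, priors, scores and ranking concordance."""

import itertools
import math

import numpy as np
import pytest

from coregrn.fixtures import random_boolean_model
from coregrn.intervals import GenomicInterval
from coregrn.logic import LogicRule, RegionClause
from coregrn.regions import RegulatoryRegion
from coregrn.scoring import (
    PriorModel,
    combined_score,
    compile_model,
    distance_to_full_activation,
    epigenetic_score,
    ranking_concordance_pvalue,
    reachability_distances,
    state_prior,
    synchronous_successor,
    transcriptional_score,
)


def two_node_swap(clamp=None):
    """X := Y, Y := X."""
    rules = {
        "X": LogicRule("X", RegionClause("pX", [frozenset({"Y"})]), []),
        "Y": LogicRule("Y", RegionClause("pY", [frozenset({"X"})]), []),
    }
    return compile_model(["X", "Y"], rules, clamp=clamp)


def oracle_distance(state, model, cap=None):
    """Independent distance oracle: step-by-step simulation with a seen-set."""
    cap = cap or (1 << model.n) + 1
    seen, s = set(), state
    for step in range(cap + 1):
        if s == model.all_active:
            return step
        if s in seen:
            return math.inf
        seen.add(s)
        s = synchronous_successor(s, model)
    return math.inf


class TestDynamics:
    def test_swap_rules(self):
        m = two_node_swap()
        assert synchronous_successor(0b01, m) == 0b10  # (1,0) -> (0,1)

    def test_clamp_holds_tf_active(self):
        m = two_node_swap(clamp={"X"})
        assert synchronous_successor(0b01, m) == 0b11

    def test_all_active_is_fixed_point(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = random_boolean_model(int(rng.integers(3, 9)), rng)
            assert synchronous_successor(m.all_active, m) == m.all_active

    def test_distance_examples(self):
        m = two_node_swap(clamp={"X"})
        assert distance_to_full_activation(m.all_active, m) == 0
        assert distance_to_full_activation(0b01, m) == 1
        free = two_node_swap()
        assert distance_to_full_activation(0b01, free) == math.inf  # 2-cycle

    def test_memoized_distances_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = random_boolean_model(int(rng.integers(3, 9)), rng)
            dist = reachability_distances(m)
            for s in range(1 << m.n):
                assert dist[s] == oracle_distance(s, m)


class TestPrior:
    def test_product_rule(self):
        prior = PriorModel(marginals={"X": 0.5, "Y": 0.5})
        for s in range(4):
            assert state_prior(s, prior, ["X", "Y"]) == pytest.approx(0.25)

    def test_perturbed_tf_forces_active(self):
        prior = PriorModel(marginals={"X": 0.2, "Y": 0.5}, perturbation=frozenset({"X"}))
        assert state_prior(0b00, prior, ["X", "Y"]) == 0.0
        assert state_prior(0b01, prior, ["X", "Y"]) == pytest.approx(0.5)

    def test_normalization_over_all_states(self):
        rng = np.random.default_rng(2)
        for n in [3, 6, 9, 12]:
            tfs = [f"T{i}" for i in range(n)]
            prior = PriorModel(marginals=dict(zip(tfs, rng.random(n))))
            total = sum(state_prior(s, prior, tfs) for s in range(1 << n))
            assert total == pytest.approx(1.0)


class TestTranscriptionalScore:
    def brute_force_T(self, model, prior):
        return sum(
            state_prior(s, prior, model.tfs)
            for s in range(1 << model.n)
            if math.isfinite(oracle_distance(s, model))
        )

    def test_exact_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            n = int(rng.integers(3, 9))
            m = random_boolean_model(n, rng)
            clamped = m.with_clamp({m.tfs[0]})
            prior = PriorModel(
                marginals=dict(zip(m.tfs, rng.random(n))),
                perturbation=frozenset({m.tfs[0]}),
            )
            exact = transcriptional_score(clamped, prior, mode="exact")
            assert exact == pytest.approx(self.brute_force_T(clamped, prior))

    def test_monte_carlo_within_three_se_of_exact(self):
        rng = np.random.default_rng(4)
        m = random_boolean_model(8, rng)
        clamped = m.with_clamp({m.tfs[0]})
        prior = PriorModel(
            marginals=dict(zip(m.tfs, rng.random(8))),
            perturbation=frozenset({m.tfs[0]}),
        )
        exact = transcriptional_score(clamped, prior, mode="exact")
        n_samples = 10_000
        mc = transcriptional_score(
            clamped, prior, mode="monte_carlo", n_samples=n_samples, seed=5
        )
        se = math.sqrt(max(exact * (1 - exact), 1e-12) / n_samples)
        assert abs(mc - exact) <= 3 * se + 1e-9

    def test_all_mass_on_target_scores_one(self):
        m = two_node_swap()
        prior = PriorModel(marginals={"X": 1.0, "Y": 1.0})
        for variant in ("reachability", "distance_weighted"):
            assert transcriptional_score(m, prior, variant=variant) == pytest.approx(1.0)

    def test_unreachable_scores_zero(self):
        m = two_node_swap()  # no clamp: only the all-active state reaches
        prior = PriorModel(marginals={"X": 1.0, "Y": 0.0})  # all mass on (1,0)
        assert transcriptional_score(m, prior) == 0.0

    def test_distance_weighted_discounts_slow_states(self):
        m = two_node_swap(clamp={"X"})
        prior = PriorModel(marginals={"X": 1.0, "Y": 0.0}, perturbation=frozenset({"X"}))
        # single initial state (1,0) at distance 1; d_max = 1 -> weight 1/2
        assert transcriptional_score(m, prior, variant="distance_weighted") == pytest.approx(0.5)

    def test_exact_mode_size_guard(self):
        tfs = [f"T{i}" for i in range(23)]
        m = compile_model(tfs, {})
        prior = PriorModel(marginals={t: 0.5 for t in tfs})
        with pytest.raises(ValueError, match="monte_carlo"):
            transcriptional_score(m, prior, mode="exact")


def reg(rid, element, gene, lo, hi, kind="enhancer", active=True):
    return RegulatoryRegion(
        region_id=rid, gene=gene, kind=kind,
        interval=GenomicInterval("chrT", lo, hi), active=active, element_id=element,
    )


class TestEpigeneticScore:
    def target_regions(self):
        return {
            "A": [reg(f"eA{i}", f"elA{i}", "A", 1000 * i, 1000 * i + 500) for i in range(4)],
            "B": [reg(f"eB{i}", f"elB{i}", "B", 9000 + 1000 * i, 9000 + 1000 * i + 500) for i in range(4)],
        }

    def test_fraction_counting(self):
        target = self.target_regions()
        initial = {
            "A": target["A"][:2],  # 2 of 4 shared
            "B": target["B"][:2],
        }
        e, f = epigenetic_score(initial, target, perturbation=set())
        assert f == {"A": 0.5, "B": 0.5}
        assert e == pytest.approx(0.25)

    def test_perturbed_tf_bypasses_remodeling(self):
        target = self.target_regions()
        e, f = epigenetic_score({}, target, perturbation={"A", "B"})
        assert e == 1.0

    def test_identical_epigenomes_score_one(self):
        target = self.target_regions()
        e, _ = epigenetic_score(target, target, perturbation=set())
        assert e == 1.0

    def test_matching_needs_element_and_coordinate_overlap(self):
        target = {"A": [reg("t0", "el0", "A", 100, 300)]}
        # same element, overlapping segment -> shared
        init_ok = {"A": [reg("i0", "el0", "A", 250, 400)]}
        assert epigenetic_score(init_ok, target, set())[0] == 1.0
        # same element, disjoint segment -> not shared
        init_disjoint = {"A": [reg("i1", "el0", "A", 400, 500)]}
        assert epigenetic_score(init_disjoint, target, set())[0] == 0.0
        # overlapping coordinates, different element -> not shared
        init_other = {"A": [reg("i2", "other", "A", 100, 300)]}
        assert epigenetic_score(init_other, target, set())[0] == 0.0

    def test_adding_tf_to_perturbation_never_decreases_E(self):
        rng = np.random.default_rng(6)
        target = self.target_regions()
        initial = {"A": target["A"][:1], "B": target["B"][:3]}
        for _ in range(20):
            pert = set(np.array(["A", "B"])[rng.random(2) < 0.5])
            e0, _ = epigenetic_score(initial, target, pert)
            for extra in {"A", "B"} - pert:
                e1, _ = epigenetic_score(initial, target, pert | {extra})
                assert e1 >= e0


class TestCombinedScore:
    def test_arithmetic_mean_and_bounds(self):
        assert combined_score(1.0, 0.25) == pytest.approx(0.625)
        assert combined_score(0.4, 0.4) == pytest.approx(0.4)
        assert combined_score(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            combined_score(1.2, 0.0)


class TestConcordance:
    def exhaustive_p(self, pred, exp):
        k = len(pred)
        d = np.linalg.norm(np.array(pred) - np.array(exp))
        count = sum(
            1
            for perm in itertools.permutations(range(1, k + 1))
            if np.linalg.norm(np.array(perm) - np.array(exp)) <= d + 1e-9
        )
        return count / math.factorial(k)

    def test_identity_ranking(self):
        assert ranking_concordance_pvalue([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1 / 24)

    def test_reversed_ranking(self):
        assert ranking_concordance_pvalue([4, 3, 2, 1], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_singleton(self):
        assert ranking_concordance_pvalue([1], [1]) == 1.0

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        for k in (3, 4, 5, 6):
            for _ in range(5):
                pred = list(rng.permutation(np.arange(1, k + 1)))
                exp = list(rng.permutation(np.arange(1, k + 1)))
                assert ranking_concordance_pvalue(pred, exp) == pytest.approx(
                    self.exhaustive_p(pred, exp)
                )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ranking_concordance_pvalue([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            ranking_concordance_pvalue([1, 1], [1, 2])
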