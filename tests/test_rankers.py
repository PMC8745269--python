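"""Likelihood scoring closed forms, ranking vs an exhaustive oracle, kNN
dedup semantics, the frequency null model, and network training smoke tests."""

import math

import numpy as np
import pytest

from condrank.conditions import (
    BINS,
    ConditionCombination,
    ConditionVocabulary,
    enumerate_combinations,
)
from condrank.rankers import (
    KNNIndex,
    LikelihoodRankingModel,
    LRMConfig,
    rank_knn,
    rank_null,
    rank_probabilities,
    score_all,
    score_combination,
)

ONE_CAT = ConditionVocabulary(catalysts=("pd-c",))


def probs_for(vocab, t=0.5, p=0.5, cat=0.5, acid=0.5, base=0.5, poison=0.5):
    v = np.full(vocab.n_bits, 0.5)
    v[0:3] = t
    v[3:6] = p
    v[6], v[7], v[8] = acid, base, poison
    v[9:] = cat
    return v


class TestScoreClosedForms:
    def test_perfect_confidence_scores_zero(self):
        combo = ConditionCombination("low", "low", 0, True, True, True)
        probs = probs_for(ONE_CAT, t=1.0, p=1.0, cat=1.0, acid=1.0, base=1.0, poison=1.0)
        assert score_combination(probs, combo, ONE_CAT) == pytest.approx(0.0, abs=1e-12)

    def test_all_half_scores_ln2(self):
        # with every probability 0.5, both additive states give q = 0.5
        combo = ConditionCombination("medium", "high", 0, False, True, False)
        probs = probs_for(ONE_CAT)
        assert score_combination(probs, combo, ONE_CAT) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_hand_evaluated_case(self):
        """q = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4) selected by a combination with
        all three additives on."""
        combo = ConditionCombination("medium", "low", 0, True, True, True)
        probs = np.full(ONE_CAT.n_bits, 0.01)
        probs[1] = 0.9      # medium temperature
        probs[3] = 0.8      # low pressure
        probs[9] = 0.7      # the catalyst
        probs[6] = 0.6      # acid selected -> q = P
        probs[7] = 0.5
        probs[8] = 0.4
        expected = -sum(math.log(q) for q in (0.9, 0.8, 0.7, 0.6, 0.5, 0.4)) / 6
        assert score_combination(probs, combo, ONE_CAT) == pytest.approx(
            expected, abs=1e-12
        )

    def test_unselected_additive_uses_complement(self):
        combo = ConditionCombination("medium", "low", 0, False, False, False)
        probs = probs_for(ONE_CAT, t=1.0, p=1.0, cat=1.0, acid=0.3, base=1.0, poison=1.0)
        # q = (1, 1, 1, 0.7, ~0, ~0) -> only acid term differs from clip floor
        got = score_combination(probs, combo, ONE_CAT)
        # base & poison probabilities are 1.0, complement clipped to EPS
        assert got > 1.0  # dominated by the two log(EPS) terms

    def test_zero_probability_is_clipped_not_fatal(self):
        combo = ConditionCombination("low", "low", 0)
        probs = np.zeros(ONE_CAT.n_bits)
        assert np.isfinite(score_combination(probs, combo, ONE_CAT))

    def test_monotone_in_selected_probability(self):
        combo = ConditionCombination("medium", "low", 0)
        lo = probs_for(ONE_CAT, cat=0.4)
        hi = probs_for(ONE_CAT, cat=0.9)
        assert score_combination(hi, combo, ONE_CAT) < score_combination(
            lo, combo, ONE_CAT
        )


def exhaustive_rank_oracle(probs, combos, vocab):
    """Independent scorer: per-combination likelihood via math.log, sorted by
    (score, bit vector) with Python's sort."""
    scored = []
    for c in combos:
        q = [
            probs[BINS.index(c.temperature_bin)],
            probs[3 + BINS.index(c.pressure_bin)],
            probs[9 + c.catalyst],
            probs[6] if c.acid else 1 - probs[6],
            probs[7] if c.base else 1 - probs[7],
            probs[8] if c.poison else 1 - probs[8],
        ]
        L = -sum(math.log(max(min(x, 1.0), 1e-9)) for x in q) / 6
        scored.append((L, c.bits_key(vocab), c))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [c for _, _, c in scored]


class TestRanking:
    def test_matches_exhaustive_oracle(self):
        combos = enumerate_combinations(ONE_CAT)
        rng = np.random.default_rng(11)
        for _ in range(20):
            probs = rng.uniform(0.05, 0.95, ONE_CAT.n_bits)
            ranked = rank_probabilities(probs, combos, ONE_CAT)
            assert ranked.combinations == exhaustive_rank_oracle(probs, combos, ONE_CAT)

    def test_scores_sorted_ascending(self):
        combos = enumerate_combinations(ONE_CAT)
        probs = np.random.default_rng(3).uniform(0.1, 0.9, ONE_CAT.n_bits)
        ranked = rank_probabilities(probs, combos, ONE_CAT)
        assert (np.diff(ranked.scores) >= 0).all()
        assert len(ranked) == 72

    def test_uniform_probabilities_fall_back_to_bit_order(self):
        combos = enumerate_combinations(ONE_CAT)
        ranked = rank_probabilities(probs_for(ONE_CAT), combos, ONE_CAT)
        assert np.allclose(ranked.scores, math.log(2))
        keys = [c.bits_key(ONE_CAT) for c in ranked.combinations]
        assert keys == sorted(keys)

    def test_dominant_bits_win(self):
        """One dominant bit per block -> top-1 is the combination of dominant
        bins with no additives whose probability is below 0.5."""
        probs = probs_for(ONE_CAT, t=0.05, p=0.05, cat=0.9,
                          acid=0.9, base=0.1, poison=0.1)
        probs[2] = 0.95  # high temperature dominant
        probs[4] = 0.95  # medium pressure dominant
        combos = enumerate_combinations(ONE_CAT)
        top = rank_probabilities(probs, combos, ONE_CAT).combinations[0]
        assert top == ConditionCombination("high", "medium", 0, True, False, False)

    def test_vectorized_scores_match_scalar(self):
        combos = enumerate_combinations(ONE_CAT)
        probs = np.random.default_rng(5).uniform(0.01, 0.99, ONE_CAT.n_bits)
        L = score_all(probs, combos, ONE_CAT)
        for i in range(0, 72, 7):
            assert L[i] == pytest.approx(
                score_combination(probs, combos[i], ONE_CAT), abs=1e-12
            )


def combo(cat=0, t="medium", p="low", **kw):
    return ConditionCombination(t, p, cat, **kw)


class TestKNN:
    def test_self_retrieval_at_distance_zero(self):
        X = np.array([[0.0], [5.0], [9.0]])
        conds = [combo(0), combo(1), combo(2)]
        ranked = rank_knn(KNNIndex(X, conds, k=2), np.array([5.0]))
        assert ranked.combinations[0] == combo(1)
        assert ranked.scores[0] == 0.0

    def test_duplicate_at_farther_neighbor_is_dropped(self):
        """Neighbors at distances (1, 2, 3) with conditions (A, B, A) yield
        the ranked list [A, B] with A scored at distance 1."""
        A, B = combo(0), combo(1)
        X = np.array([[1.0], [2.0], [3.0], [50.0]])
        index = KNNIndex(X, [A, B, A, combo(2)], k=3)
        ranked = rank_knn(index, np.array([0.0]))
        assert ranked.combinations == [A, B]
        assert list(ranked.scores) == [1.0, 2.0]

    def test_full_dedup_single_condition(self):
        A = combo(0)
        X = np.arange(5, dtype=float).reshape(-1, 1)
        ranked = rank_knn(KNNIndex(X, [A] * 5, k=5), np.array([0.0]))
        assert len(ranked) == 1

    def test_k_truncated_with_warning(self):
        X = np.array([[0.0], [1.0]])
        index = KNNIndex(X, [combo(0), combo(1)], k=10)
        with pytest.warns(UserWarning, match="truncating"):
            ranked = rank_knn(index, np.array([0.0]))
        assert len(ranked) == 2

    def test_scores_nondecreasing_and_distinct(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        conds = [combo(int(i)) for i in rng.integers(0, 4, 30)]
        ranked = rank_knn(KNNIndex(X, conds, k=15), rng.normal(size=3))
        assert (np.diff(ranked.scores) >= 0).all()
        assert len(set(ranked.combinations)) == len(ranked)

    def test_empty_index_rejected(self):
        with pytest.raises(ValueError):
            KNNIndex(np.zeros((0, 2)), [], k=1)


class TestNullModel:
    def test_frequency_sort(self, vocab):
        A, B = combo(0), combo(1)
        ranked = rank_null([A, A, A, B], vocab)
        assert ranked.combinations == [A, B]

    def test_tie_break_by_bit_vector(self, vocab):
        A, B = combo(1), combo(0)
        ranked = rank_null([A, B], vocab)
        assert [c.bits_key(vocab) for c in ranked.combinations] == sorted(
            c.bits_key(vocab) for c in (A, B)
        )

    def test_query_independence(self, benchmark):
        r1, _ = benchmark.bundle.rank(benchmark.test_lines[0], "null")
        r2, _ = benchmark.bundle.rank(benchmark.test_lines[1], "null")
        assert r1.combinations == r2.combinations

    def test_empty_training_rejected(self, vocab):
        with pytest.raises(ValueError):
            rank_null([], vocab)


class TestTraining:
    def test_zero_epochs_still_produces_valid_probabilities(self):
        model = LikelihoodRankingModel(4, 38, LRMConfig(hidden_size=8, epochs=0))
        model.fit(np.zeros((3, 4)), np.zeros((3, 38)))
        p = model.predict_proba(np.ones(4))
        assert p.shape == (1, 38)
        assert ((p >= 0) & (p <= 1)).all()

    def test_single_sample_training_runs(self):
        model = LikelihoodRankingModel(4, 10, LRMConfig(hidden_size=8, epochs=5))
        X = np.ones((1, 4))
        Y = np.zeros((1, 10))
        Y[0, 0] = 1
        model.fit(X, Y)
        assert ((model.predict_proba(X) >= 0) & (model.predict_proba(X) <= 1)).all()

    def test_loss_decreases_on_average(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(64, 6))
        Y = (X[:, :1] > 0).astype(float) @ np.ones((1, 5))
        model = LikelihoodRankingModel(6, 5, LRMConfig(hidden_size=16, epochs=40, seed=0))
        model.fit(X, Y)
        first = np.mean(model.loss_history[:5])
        last = np.mean(model.loss_history[-5:])
        assert last < first

    def test_dimension_mismatch_rejected(self):
        model = LikelihoodRankingModel(4, 10, LRMConfig(hidden_size=8, epochs=1))
        with pytest.raises(ValueError):
            model.fit(np.zeros((3, 5)), np.zeros((3, 10)))
        with pytest.raises(ValueError):
            model.fit(np.zeros((3, 4)), np.zeros((2, 10)))

    def test_seed_controls_initialization(self):
        a = LikelihoodRankingModel(4, 6, LRMConfig(hidden_size=8, seed=1))
        b = LikelihoodRankingModel(4, 6, LRMConfig(hidden_size=8, seed=1))
        c = LikelihoodRankingModel(4, 6, LRMConfig(hidden_size=8, seed=2))
        assert np.array_equal(a.W1, b.W1)
        assert not np.array_equal(a.W1, c.W1)

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        model = LikelihoodRankingModel(5, 7, LRMConfig(hidden_size=8, epochs=3, seed=2))
        model.fit(rng.normal(size=(10, 5)), rng.integers(0, 2, (10, 7)).astype(float))
        model.save(tmp_path / "m.npz")
        back = LikelihoodRankingModel.load(tmp_path / "m.npz")
        X = rng.normal(size=(4, 5))
        assert np.allclose(back.predict_proba(X), model.predict_proba(X))
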