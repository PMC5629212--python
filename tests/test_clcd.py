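"""Trio mining: pooling, six-test pattern, replicate support, ranking."""

import numpy as np
import pytest

import cytocausal as cc
from cytocausal.ci_tests import DecisionThresholds
from cytocausal.clcd import (
    CLCDPrediction,
    TrioLabel,
    TrioOutcome,
    UndersizedTableError,
    aggregate_replicates,
    evaluate_trio,
    pool_activation,
    rank_predictions,
    run_clcd,
    threshold_sensitivity,
)
from cytocausal.synthetic import CellTable, ConditionKey


def _table(values, labels, activator="act1", n0=None):
    key = ConditionKey("pop1", activator, "inh01", 0, 0)
    return CellTable(values=values, labels=labels, meta=key)


def _pooled_from_model(model, n=2000, seed=0):
    rng = np.random.default_rng(seed)
    ref = cc.simulate_condition(model, n=n // 2, seed=rng, activation_on=False)
    act = cc.simulate_condition(model, n=n // 2, seed=rng, activation_on=True)
    return pool_activation(ref, act)


class TestPooling:
    def test_counts_and_activation_fraction(self):
        rng = np.random.default_rng(0)
        ref = _table(rng.standard_normal((100, 2)), ("a", "b"), "reference")
        act = _table(rng.standard_normal((150, 2)), ("a", "b"))
        pooled = pool_activation(ref, act)
        assert pooled.n == 250
        assert pooled.activation.mean() == pytest.approx(0.6)

    def test_undersized_table_skipped(self):
        rng = np.random.default_rng(1)
        ref = _table(rng.standard_normal((15, 2)), ("a", "b"), "reference")
        act = _table(rng.standard_normal((100, 2)), ("a", "b"))
        with pytest.raises(UndersizedTableError):
            pool_activation(ref, act)

    def test_marker_order_aligned_by_label(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((30, 2))
        ref = _table(vals[:, ::-1], ("b", "a"), "reference")
        act = _table(vals, ("a", "b"))
        pooled = pool_activation(ref, act)
        np.testing.assert_array_equal(pooled.column("a")[:30], vals[:, 0])


class TestEvaluateTrio:
    def test_chain_detected(self):
        # per-replicate hit rate is ~1 - beta = 0.85 (the required
        # A _||_ T | S acceptance is the binding step); 12/20 is the
        # 3-sigma lower bound
        model = cc.make_chain_model(p=2, chain_coef=0.8, activator_effect=1.0)
        hits = sum(
            evaluate_trio(_pooled_from_model(model, seed=s), "pP01", "pP02").label
            is TrioLabel.CHAIN_S_TO_T
            for s in range(20)
        )
        assert hits >= 12

    def test_common_effect_of_activator_is_no_pattern(self):
        # A -> S and A -> T with no S-T edge: S _||_ T | A accepted
        model = cc.CausalModel(
            np.zeros((2, 2)), np.eye(2), np.array([1.0, 1.0]), ("pP01", "pP02")
        )
        labels = [
            evaluate_trio(_pooled_from_model(model, seed=s), "pP01", "pP02").label
            for s in range(10)
        ]
        assert labels.count(TrioLabel.NO_PATTERN) + labels.count(TrioLabel.UNCERTAIN) == 10
        assert labels.count(TrioLabel.NO_PATTERN) >= 6

    def test_latent_confounder_yields_no_chain(self):
        # A -> S, S <- H -> T: no directed S-T path; A _||_ T marginally
        Sigma = np.array([[1.0, 0.7], [0.7, 1.0]])
        model = cc.CausalModel(
            np.zeros((2, 2)), Sigma, np.array([1.0, 0.0]), ("pP01", "pP02")
        )
        for s in range(10):
            out = evaluate_trio(_pooled_from_model(model, seed=s), "pP01", "pP02")
            assert out.label not in (TrioLabel.CHAIN_S_TO_T, TrioLabel.CHAIN_T_TO_S)

    def test_reverse_orientation_symmetry(self):
        # evaluating (T, S) instead of (S, T) flips the chain label
        model = cc.make_chain_model(p=2)
        pooled = _pooled_from_model(model, seed=3)
        fwd = evaluate_trio(pooled, "pP01", "pP02")
        rev = evaluate_trio(pooled, "pP02", "pP01")
        if fwd.label is TrioLabel.CHAIN_S_TO_T:
            assert rev.label is TrioLabel.CHAIN_T_TO_S


class TestAggregate:
    def _outcomes(self, n_s2t, n_t2s, total=27):
        labels = (
            [TrioLabel.CHAIN_S_TO_T] * n_s2t
            + [TrioLabel.CHAIN_T_TO_S] * n_t2s
            + [TrioLabel.NO_PATTERN] * (total - n_s2t - n_t2s)
        )
        return [TrioOutcome("S", "T", lab, {}) for lab in labels]

    def test_support_above_threshold_emits(self):
        pred = aggregate_replicates(self._outcomes(12, 0), 10, "act1", "pop1")
        assert pred == CLCDPrediction("S", "T", "act1", "pop1", 12, 27)

    def test_support_below_threshold_silent(self):
        assert aggregate_replicates(self._outcomes(9, 0), 10) is None

    def test_bidirectional_conflict_suppressed(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cytocausal.clcd"):
            pred = aggregate_replicates(self._outcomes(10, 10), 10, "act1", "pop1")
        assert pred is None
        assert any("conflict" in r.message for r in caplog.records)

    def test_empty_outcomes_error(self):
        with pytest.raises(ValueError):
            aggregate_replicates([], 10)


class TestRunCLCD:
    def test_chain_bundle_recovers_true_pair(self, chain_bundle):
        preds = run_clcd(chain_bundle)
        assert [(p.cause, p.effect) for p in preds] == [("pP01", "pP02")]
        assert preds[0].support >= 10

    def test_deterministic_output(self, chain_bundle):
        assert run_clcd(chain_bundle) == run_clcd(chain_bundle)

    def test_pair_space_bound(self):
        labels = [f"p{i}" for i in range(14)]
        assert len(labels) * (len(labels) - 1) == 182


class TestRanking:
    def test_frequency_then_lexicographic(self):
        preds = [
            CLCDPrediction("a", "b", f"act{i}", "pop1", 10, 27) for i in range(5)
        ] + [CLCDPrediction("c", "d", f"act{i}", "pop1", 10, 27) for i in range(2)] + [
            CLCDPrediction("a", "c", "actX", "pop1", 10, 27),
            CLCDPrediction("a", "a2", "actY", "pop1", 10, 27),
        ]
        ranked = rank_predictions(preds)
        assert ranked[0] == (("a", "b"), 5)
        assert ranked[1] == (("c", "d"), 2)
        assert [pair for pair, _ in ranked[2:]] == [("a", "a2"), ("a", "c")]

    def test_empty_input(self):
        assert rank_predictions([]) == []


class TestThresholdSensitivity:
    def test_default_row_overlaps_itself_and_alpha_monotone(self, chain_bundle):
        table = threshold_sensitivity(
            chain_bundle, alpha_grid=[1e-5, 1e-3], beta_grid=[0.05, 0.15]
        )
        default_row = table[(table.alpha == 1e-3) & (table.beta == 0.15)]
        assert default_row.jaccard_vs_default.iloc[0] == 1.0
        # stricter alpha can only lose predictions, at every beta
        for beta in (0.05, 0.15):
            sub = table[table.beta == beta].sort_values("alpha")
            assert sub.n_predictions.is_monotonic_increasing
        # stricter (larger) beta can only lose predictions, at every alpha
        for alpha in (1e-5, 1e-3):
            sub = table[table.alpha == alpha].sort_values("beta")
            assert sub.n_predictions.is_monotonic_decreasing or (
                sub.n_predictions.nunique() == 1
            )

    def test_invalid_grid(self, chain_bundle):
        with pytest.raises(ValueError, match="alpha.*below.*beta"):
            threshold_sensitivity(chain_bundle, alpha_grid=[0.2], beta_grid=[0.1])
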