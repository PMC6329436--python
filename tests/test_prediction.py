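"""AUROC oracle, tree tuning, repeated CV, and paired comparison behavior."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from missig.lasso import CVScheme
from missig.prediction import (
    DEFAULT_CP_GRID,
    ModelSpec,
    auroc,
    compare_input_sets,
    repeated_cv,
    tune_tree_cp,
)
from missig.simulate import SimulationConfig, generate_cohort


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_three_of_four_concordant_pairs(self):
        assert auroc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_trapezoidal_roc_integration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestTuneTreeCp:
    def test_noise_outcome_prefers_pruning(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X = rng.standard_normal((200, 5))
            y = rng.integers(0, 2, 200)
            if tune_tree_cp(X, y, DEFAULT_CP_GRID, inner_folds=3, seed=seed) > 0:
                wins += 1
        assert wins >= 16  # pruning wins on pure noise in >= 80% of runs

    def test_tie_breaks_to_largest_cp(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 120)
        X = x.reshape(-1, 1).astype(float)
        y = x  # one perfectly splitting binary feature: every CP ties
        assert tune_tree_cp(X, y, DEFAULT_CP_GRID, inner_folds=3, seed=0) == 0.02

    def test_single_value_grid(self):
        X = np.zeros((20, 1))
        y = np.array([0, 1] * 10)
        assert tune_tree_cp(X, y, (0.007,), inner_folds=2, seed=0) == 0.007


class TestRepeatedCv:
    def test_null_features_score_near_chance(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((800, 6)))
        y = rng.integers(0, 2, 800)
        vals = repeated_cv(ModelSpec("logistic"), X, y, CVScheme(10, 2), seed=3)
        assert len(vals) == 20
        # Monte-Carlo band for the mean of 20 fold AUROCs under the null
        assert abs(vals.mean() - 0.5) < 0.05

    def test_learnable_signal_is_learned(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 400)
        X = pd.DataFrame({"f": y.astype(float), "g": rng.standard_normal(400)})
        for family in ("logistic", "decision_tree"):
            vals = repeated_cv(ModelSpec(family), X, y, CVScheme(5, 1), seed=4)
            assert vals.mean() > 0.95

    def test_same_seed_reproduces_vector(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((300, 4)))
        y = rng.integers(0, 2, 300)
        a = repeated_cv(ModelSpec("logistic"), X, y, CVScheme(5, 2), seed=7)
        b = repeated_cv(ModelSpec("logistic"), X, y, CVScheme(5, 2), seed=7)
        np.testing.assert_array_equal(a, b)

    def test_shuffled_holdout_labels_collapse_to_chance(self):
        """Leakage canary: with labels shuffled after the split, no fitted
        transformation can beat chance."""
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((600, 5)))
        y_signal = (X[0] > 0).astype(int).to_numpy()
        y_shuffled = rng.permutation(y_signal)
        vals = repeated_cv(ModelSpec("logistic"), X, y_shuffled, CVScheme(10, 2), seed=6)
        assert abs(vals.mean() - 0.5) < 0.05


@pytest.fixture(scope="module")
def day1():
    return generate_cohort(sim=SimulationConfig(n_patients=400), seed=23).day(1)


class TestCompareInputSets:

    def test_shape_and_paired_design(self, day1):
        comp = compare_input_sets(
            day1, "in_hospital", models=[ModelSpec("logistic")],
            cv=CVScheme(4, 2), seed=1,
            input_sets=("indicators_only", "severity_only"),
        )
        assert len(comp.folds) == 2 * 8
        by_set = comp.folds.groupby("input_set")
        for _, grp in by_set:
            assert sorted(zip(grp["repeat"], grp["fold"])) == sorted(
                (r, f) for r in range(2) for f in range(4)
            )

    def test_identical_input_set_has_zero_delta(self, day1):
        comp = compare_input_sets(
            day1, "in_hospital", models=[ModelSpec("logistic")],
            cv=CVScheme(4, 1), seed=2,
            input_sets=("severity_only", "severity_plus_indicators"),
        )
        a = comp.fold_aurocs("logistic", "severity_only")
        b = comp.fold_aurocs("logistic", "severity_only")
        np.testing.assert_array_equal(a, b)

    def test_unknown_input_set_rejected(self, day1):
        with pytest.raises(ValueError, match="unknown input set"):
            compare_input_sets(day1, "in_hospital", models=[ModelSpec("logistic")],
                               input_sets=("bogus",))

    def test_augmented_uses_values_plus_indicators(self, day1):
        comp = compare_input_sets(
            day1, "day30", models=[ModelSpec("logistic")],
            cv=CVScheme(3, 1), seed=3,
            input_sets=("imputed_only", "augmented"),
            impute_once=True,
        )
        assert set(comp.deltas["pair"]) == {"augmented-imputed_only"}
        assert len(comp.fold_aurocs("logistic", "augmented")) == 3
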