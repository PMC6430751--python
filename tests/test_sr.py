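import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import biogapfill as bg
from biogapfill.sr import eval_tree, tree_depth, _random_tree, SRConfig


@pytest.fixture(scope="module")
def xy36():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(36, 8)), columns=list("ABCDEFGH"))
    y = 2.0 * X["D"] - 1.5 * X["G"] + 0.1 * rng.normal(size=36)
    return X, y


class TestSplit:
    def test_study_split_arithmetic(self):
        train, test = bg.split_train_test(range(36), 0.67, seed=0)
        assert len(train) == 24 and len(test) == 12

    def test_two_rows_half(self):
        train, test = bg.split_train_test([0, 1], 0.5, seed=0)
        assert len(train) == 1 and len(test) == 1

    def test_disjoint_exhaustive_and_deterministic(self):
        a = bg.split_train_test(range(50), 0.7, seed=3)
        b = bg.split_train_test(range(50), 0.7, seed=3)
        assert a == b
        assert sorted(a[0] + a[1]) == list(range(50))
        assert not set(a[0]) & set(a[1])

    @pytest.mark.parametrize("fraction", [0.001, 0.999])
    def test_degenerate_split_rejected(self, fraction):
        with pytest.raises(ValueError):
            bg.split_train_test(range(10), fraction, seed=0)


class TestTreeMachinery:
    @given(seed=st.integers(0, 10_000), depth=st.integers(1, 6))
    @settings(max_examples=100, deadline=None)
    def test_random_trees_respect_depth(self, seed, depth):
        rng = np.random.default_rng(seed)
        cfg = SRConfig(max_depth=depth)
        tree = _random_tree(rng, 5, depth, cfg)
        assert 1 <= tree_depth(tree) <= depth

    def test_protected_division(self):
        X = np.array([[1.0, 0.0], [6.0, 2.0]])
        tree = ("div", ("var", 0), ("var", 1))
        np.testing.assert_allclose(eval_tree(tree, X), [1.0, 3.0])

    def test_depth_one_is_bare_terminal(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tree = _random_tree(rng, 3, 1, SRConfig(max_depth=1))
            assert tree[0] in ("var", "const")


class TestTraining:
    def test_single_parameter_target_recovered(self, xy36):
        X, _ = xy36
        y = X["D"].copy()
        hits = 0
        for seed in range(5):
            cfg = SRConfig(population_size=500, n_generations=50, max_genes=2,
                           max_depth=3, seed=seed)
            model = bg.train_sr(X, y, cfg)
            hits += bg.evaluate(model, X, y) < 1e-6
        assert hits >= 4

    def test_depth1_gene1_matches_enumeration_oracle(self, xy36):
        X, y = xy36
        # oracle: best single-terminal linear regression over all columns
        best = np.inf
        for col in X.columns:
            A = np.column_stack([np.ones(len(y)), X[col]])
            w, *_ = np.linalg.lstsq(A, y, rcond=None)
            best = min(best, float(np.sqrt(np.mean((A @ w - y) ** 2))))
        cfg = SRConfig(population_size=200, n_generations=30, max_genes=1, max_depth=1, seed=1)
        res = bg.SymbolicRegression(X, y, cfg).fit()
        assert res.TRE == pytest.approx(best, abs=1e-8)

    def test_zero_target_gives_zero_error(self, xy36):
        X, _ = xy36
        y = pd.Series(np.zeros(len(X)), index=X.index)
        cfg = SRConfig(population_size=50, n_generations=5, seed=0)
        res = bg.SymbolicRegression(X, y, cfg).fit()
        assert res.TRE == pytest.approx(0.0, abs=1e-10)
        assert res.model.used_parameters == set()

    def test_elitism_fitness_non_increasing(self, xy36):
        X, y = xy36
        for seed in range(5):
            cfg = SRConfig(population_size=60, n_generations=25, seed=seed)
            res = bg.SymbolicRegression(X, y, cfg).fit()
            assert np.all(np.diff(res.fitness_history) <= 1e-12)

    def test_constraints_respected_by_final_model(self, xy36):
        X, y = xy36
        cfg = SRConfig(population_size=80, n_generations=15, max_genes=3, max_depth=4, seed=2)
        model = bg.train_sr(X, y, cfg)
        assert len(model.genes) <= 3
        assert all(tree_depth(g) <= 4 for g in model.genes)

    def test_full_determinism(self, xy36):
        X, y = xy36
        tr, te = bg.split_train_test(list(X.index), 0.67, seed=5)
        cfg = SRConfig(population_size=60, n_generations=10, seed=9)
        r1 = bg.run_sr(X, y, tr, te, cfg)
        r2 = bg.run_sr(X, y, tr, te, cfg)
        assert r1.model.genes == r2.model.genes
        assert r1.TRE == r2.TRE and r1.TEE == r2.TEE

    def test_evaluate_reproduces_tre_and_overfit_identity(self, xy36):
        X, y = xy36
        tr, te = bg.split_train_test(list(X.index), 0.67, seed=5)
        res = bg.run_sr(X, y, tr, te, SRConfig(population_size=60, n_generations=10, seed=3))
        assert bg.evaluate(res.model, X.loc[tr], y.loc[tr]) == pytest.approx(res.TRE)
        assert res.overfit == res.TEE - res.TRE


class TestEvaluate:
    def test_perfect_predictions(self, xy36):
        X, _ = xy36
        model = bg.SRModel((("var", 0),), np.array([0.0, 1.0]), list(X.columns))
        assert bg.evaluate(model, X, X["A"]) == 0.0

    def test_hand_computed_rmse(self):
        # constant prediction 2 on y = [1, 3]: sqrt(((2-1)^2 + (2-3)^2)/2) = 1
        X = pd.DataFrame({"A": [0.0, 0.0]})
        model = bg.SRModel((("const", 2.0),), np.array([2.0, 0.0]), ["A"])
        assert bg.evaluate(model, X, pd.Series([1.0, 3.0])) == pytest.approx(1.0)

    def test_missing_columns_rejected(self, xy36):
        X, _ = xy36
        model = bg.SRModel((("var", 0),), np.array([0.0, 1.0]), ["NOPE"])
        with pytest.raises(ValueError):
            model.predict(X)


class TestGridSearch:
    def test_grid_has_480_points(self):
        total = len(list(itertools.product(*bg.GRID_DOMAIN.values())))
        assert total == 480

    def test_sampled_configs_distinct(self):
        for seed in range(50):
            configs = bg.sample_grid_configs(38, seed=seed)
            points = {c.grid_point() for c in configs}
            assert len(points) == 38

    def test_full_enumeration(self):
        configs = bg.sample_grid_configs(480, seed=0)
        assert len({c.grid_point() for c in configs}) == 480

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            bg.sample_grid_configs(481, seed=0)

    def test_results_ordered_by_overfit(self, xy36):
        X, y = xy36
        tr, te = bg.split_train_test(list(X.index), 0.67, seed=1)
        domain = {"population_size": (10, 20), "n_generations": (5,),
                  "max_genes": (1, 2), "max_depth": (1, 2)}
        results = bg.grid_search(X, y, tr, te, n_settings=6, seed=2, grid_domain=domain)
        overfits = [r.overfit for r in results]
        assert overfits == sorted(overfits)


class TestOverfitDelta:
    def test_identical_runs_give_zero(self, xy36):
        X, y = xy36
        tr, te = bg.split_train_test(list(X.index), 0.67, seed=1)
        cfg = SRConfig(population_size=30, n_generations=5, seed=4)
        r1 = bg.run_sr(X, y, tr, te, cfg)
        r2 = bg.run_sr(X, y, tr, te, cfg)
        assert bg.overfit_delta(r1, r2) == 0.0

    def test_hand_value(self, xy36):
        X, y = xy36
        tr, te = bg.split_train_test(list(X.index), 0.67, seed=1)
        cfg = SRConfig(population_size=30, n_generations=5, seed=4)
        r1 = bg.run_sr(X, y, tr, te, cfg)
        r2 = bg.run_sr(X, y, tr, te, cfg)
        r1.TEE, r1.TRE = 0.7, 0.2  # overfit 0.5
        r2.TEE, r2.TRE = 0.5, 0.3  # overfit 0.2
        assert bg.overfit_delta(r1, r2) == pytest.approx(0.3)

    def test_mismatched_config_rejected(self, xy36):
        X, y = xy36
        tr, te = bg.split_train_test(list(X.index), 0.67, seed=1)
        r1 = bg.run_sr(X, y, tr, te, SRConfig(population_size=30, n_generations=5, seed=4))
        r2 = bg.run_sr(X, y, tr, te, SRConfig(population_size=40, n_generations=5, seed=4))
        with pytest.raises(ValueError):
            bg.overfit_delta(r1, r2)


class TestRepeatedRuns:
    def test_counts_bounded_and_drivers_recur(self, xy36):
        X, y = xy36  # y built from D and G only
        tr, te = bg.split_train_test(list(X.index), 0.67, seed=2)
        cfg = SRConfig(population_size=100, n_generations=20, max_genes=3, max_depth=2)
        results, rec = bg.repeated_runs(X, y, tr, te, cfg, n_runs=10, seed=0)
        assert len(results) == 10 and rec.n_runs == 10
        assert all(0 <= c <= 10 for c in rec.counts.values())
        ranked = [p for p, _ in rec.ranked()]
        assert set(ranked[:4]) >= {"D", "G"}


class TestPressCV:
    def test_perfect_target_gives_unit_r2(self, xy36):
        X, _ = xy36
        y = X["A"].copy()
        cfg = SRConfig(population_size=100, n_generations=20, max_genes=1, max_depth=1, seed=0)
        out = bg.press_cv({"a": (X, y), "b": (X, y)}, cfg, n_splits=4, seed=1)
        assert out.loc["a", "PRESS"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["a", "adjusted_r2"] == pytest.approx(1.0, abs=1e-9)

    def test_adjusted_r2_matches_formula(self, xy36):
        X, y = xy36
        cfg = SRConfig(population_size=30, n_generations=5, max_genes=2, seed=0)
        out = bg.press_cv({"a": (X, y), "b": (X, y + 1)}, cfg, n_splits=3, seed=2)
        for _, row in out.iterrows():
            n = len(X)
            p = row["mean_genes"] + 1
            expected = 1 - (1 - row["r2"]) * (n - 1) / (n - p - 1)
            assert row["adjusted_r2"] == pytest.approx(expected, rel=1e-12)

    def test_single_variant_rejected(self, xy36):
        X, y = xy36
        with pytest.raises(ValueError):
            bg.press_cv({"a": (X, y)}, SRConfig(), n_splits=2)
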