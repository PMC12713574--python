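import numpy as np
import pytest

from gwadl._utils import kfold_indices, pearson_r2
from gwadl.network import (ACTIVATIONS, NetConfig, TrainedNetwork,
                           crossval_gwadl, default_grid, gedeon_importance,
                           grid_search, random_grid, should_stop,
                           train_network)


def _linear_problem(rng, n=200, m=20, noise=0.0):
    X = rng.normal(0, 1, (n, m))
    w = rng.normal(0, 1, m)
    y = X @ w + rng.normal(0, noise, n)
    return X, y


class TestTraining:
    def test_noiseless_linear_target_fits(self, rng):
        X, y = _linear_problem(rng)
        cfg = NetConfig(h1=40, h2=40, activation="relu", l1=0, l2=0,
                        dropout=0.0, seed=5)
        net = train_network(X, y, cfg)
        assert net.training_r2(X, y) > 0.99

    @pytest.mark.parametrize("activation", ACTIVATIONS)
    def test_all_activations_train(self, rng, activation):
        X, y = _linear_problem(rng, n=150, m=10)
        cfg = NetConfig(h1=40, h2=40, activation=activation, l1=1e-5, l2=1e-5,
                        dropout=0.1, seed=2)
        net = train_network(X, y, cfg)
        assert net.training_r2(X, y) > 0.8

    def test_constant_trait_converges_to_constant(self, rng):
        X = rng.normal(0, 1, (100, 8))
        net = train_network(X, np.full(100, 3.0), NetConfig(seed=1, dropout=0.0))
        assert net.history[-1] < 1e-4

    def test_same_seed_identical_history(self, rng):
        X, y = _linear_problem(rng, noise=0.5)
        cfg = NetConfig(h1=64, h2=40, activation="tanh", dropout=0.2, seed=9)
        a = train_network(X, y, cfg)
        b = train_network(X, y, cfg)
        assert a.history == b.history  # bitwise
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_early_stop_rule_replays(self, rng):
        X, y = _linear_problem(rng, noise=1.0)
        cfg = NetConfig(h1=40, h2=40, seed=3, dropout=0.0)
        net = train_network(X, y, cfg)
        h = net.history
        assert net.stopped_epoch == len(h)
        if net.stopped_epoch < cfg.max_epochs:
            assert should_stop(h, cfg.stop_window, cfg.stop_tol)
            # and the rule did not hold at any earlier epoch
            for t in range(2 * cfg.stop_window, len(h)):
                assert not should_stop(h[:t], cfg.stop_window, cfg.stop_tol)

    def test_plain_mlp_close_to_ols_on_linear_target(self, rng):
        X, y = _linear_problem(rng, n=600, m=15, noise=0.5)
        tr, te = np.arange(400), np.arange(400, 600)
        cfg = NetConfig(h1=40, h2=40, activation="relu", l1=0, l2=0,
                        dropout=0.0, seed=4)
        net = train_network(X[tr], y[tr], cfg)
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(400), X[tr]]), y[tr], rcond=None)
        ols_pred = np.column_stack([np.ones(200), X[te]]) @ beta
        r2_net = pearson_r2(y[te], net.predict(X[te]))
        r2_ols = pearson_r2(y[te], ols_pred)
        assert abs(r2_net - r2_ols) < 0.05

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_exploding_gradient_raises_helpful_error(self, rng):
        X, y = _linear_problem(rng, n=60, m=10)
        cfg = NetConfig(h1=300, h2=300, activation="relu", learning_rate=50.0,
                        clip_grad_norm=0.0, dropout=0.0, seed=0)
        with pytest.raises(FloatingPointError, match="learning rate"):
            train_network(X, 1e3 * y, cfg)


class TestGedeonImportance:
    def _net(self, W1, W2, W3):
        cfg = NetConfig(h1=max(W1.shape[1], 40), h2=max(W2.shape[1], 40), seed=0)
        return TrainedNetwork(cfg, [W1, W2, W3],
                              [np.zeros(W1.shape[1]), np.zeros(W2.shape[1]),
                               np.zeros(1)],
                              np.zeros(W1.shape[0]), np.ones(W1.shape[0]),
                              0.0, 1.0, [], 0)

    def test_single_path_input_scores_one(self):
        W1 = np.zeros((4, 3))
        W1[1, :] = 2.0  # only input 1 feeds the first layer
        net = self._net(W1, np.ones((3, 2)), np.ones((2, 1)))
        s = gedeon_importance(net).scores
        assert s[1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.delete(s, 1), 0.0)

    def test_symmetric_inputs_equal_scores(self, rng):
        W1 = rng.normal(0, 1, (5, 4))
        W1[2] = W1[0]
        net = self._net(W1, rng.normal(0, 1, (4, 3)), rng.normal(0, 1, (3, 1)))
        s = gedeon_importance(net).scores
        assert s[0] == pytest.approx(s[2], abs=1e-12)

    def test_scores_sum_to_one_and_nonnegative(self, rng):
        X, y = _linear_problem(rng, n=120, m=12, noise=0.3)
        net = train_network(X, y, NetConfig(seed=8, dropout=0.1))
        s = gedeon_importance(net).scores
        assert s.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(s >= 0)

    def test_invariant_to_hidden_unit_relabeling(self, rng):
        X, y = _linear_problem(rng, n=120, m=10, noise=0.3)
        net = train_network(X, y, NetConfig(h1=40, h2=40, seed=8, dropout=0.0))
        base = gedeon_importance(net).scores
        perm = rng.permutation(net.weights[0].shape[1])
        net.weights[0] = net.weights[0][:, perm]
        net.weights[1] = net.weights[1][perm, :]
        np.testing.assert_allclose(gedeon_importance(net).scores, base,
                                   atol=1e-12)

    def test_agrees_with_permutation_importance_on_dominant_input(self, rng):
        """The Gedeon top input is also the input whose shuffling degrades
        the fit the most (independent permutation-importance oracle)."""
        n, m = 250, 15
        X = rng.normal(0, 1, (n, m))
        y = 2.0 * X[:, 4] + 0.2 * X @ rng.normal(0, 0.1, m) + rng.normal(0, 0.3, n)
        net = train_network(X, y, NetConfig(h1=40, h2=40, l1=1e-5, l2=1e-5,
                                            dropout=0.04, seed=3))
        gedeon_top = int(np.argmax(gedeon_importance(net).scores))
        base_mse = float(np.mean((net.predict(X) - y) ** 2))
        deltas = []
        for j in range(m):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(float(np.mean((net.predict(Xp) - y) ** 2)) - base_mse)
        assert gedeon_top == int(np.argmax(deltas)) == 4


class TestGridSearch:
    def test_default_grid_cardinality(self):
        assert len(default_grid()) == 3840

    def test_random_grid_subsamples(self):
        sub = random_grid(48, seed=1)
        assert len(sub) == 48
        assert len(set(sub)) == 48

    def test_single_config_returned(self, rng):
        X, y = _linear_problem(rng, n=80, m=6, noise=0.5)
        cfg = NetConfig(h1=40, h2=40, seed=1)
        best, table = grid_search(X, y, [cfg], folds=4, seed=2)
        assert best == cfg
        assert len(table) == 1

    def test_sharp_signal_prefers_low_dropout(self, rng):
        X = rng.normal(0, 1, (200, 10))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.1, 200)
        grid = [NetConfig(h1=40, h2=40, activation="relu", dropout=d, seed=3)
                for d in (0.04, 0.5)]
        best, _ = grid_search(X, y, grid, folds=4, seed=7)
        assert best.dropout == 0.04

    def test_best_config_not_worse_than_worst(self, rng):
        X, y = _linear_problem(rng, n=150, m=10, noise=1.0)
        grid = [NetConfig(h1=40, h2=40, dropout=0.04, seed=1),
                NetConfig(h1=300, h2=300, dropout=0.5, l1=1e-4, seed=1)]
        best, table = grid_search(X, y, grid, folds=4, seed=5)
        assert table.cv_r2[table.cv_mse.idxmin()] >= table.cv_r2.min() - 1e-12


class TestCrossval:
    def test_folds_shared_with_gblup_protocol(self, rng):
        from gwadl.gblup import crossval_gblup

        n, m = 60, 50
        D = rng.binomial(2, 0.5, (n, m)).astype(float)
        y = rng.normal(0, 1, n)
        a = crossval_gwadl(D, y, NetConfig(seed=1, max_epochs=6), folds=5, seed=99)
        b = crossval_gblup(D, y, folds=5, seed=99)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_both_r2_definitions_reported(self, rng):
        X, y = _linear_problem(rng, n=80, m=8, noise=0.5)
        res = crossval_gwadl(X, y, NetConfig(seed=2, max_epochs=10), folds=4, seed=1)
        assert res.fold_r2.size == 4
        assert res.fold_r2_alt.size == 4


def test_network_serialization_round_trip(tmp_path, rng):
    X, y = _linear_problem(rng, n=100, m=8, noise=0.3)
    net = train_network(X, y, NetConfig(activation="maxout", dropout=0.1, seed=6))
    path = tmp_path / "net.npz"
    net.save(path)
    net2 = TrainedNetwork.load(path)
    np.testing.assert_array_equal(net.predict(X), net2.predict(X))
    assert net2.config == net.config
    assert net2.history == net.history


def test_kfold_partition_properties():
    parts = kfold_indices(23, 5, seed=0)
    allidx = np.sort(np.concatenate(parts))
    np.testing.assert_array_equal(allidx, np.arange(23))
    sizes = [p.size for p in parts]
    assert max(sizes) - min(sizes) <= 1
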