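import numpy as np
import pytest
from sklearn.decomposition import PCA

from erqsar import BRNNConfig, pca_reduce, repeat_average_predict, train_brnn
from erqsar.brnn import derive_seeds, init_nguyen_widrow
from erqsar.synthetic import gen_linear, gen_nonlinear


class TestPca:
    def test_basis_orthonormal(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 8))
        _, basis = pca_reduce(X, 5)
        assert np.allclose(basis.components @ basis.components.T, np.eye(5), atol=1e-10)

    def test_reconstruction_error_monotone_in_components(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 6)) @ np.diag([3, 2, 1.5, 1, 0.5, 0.2])
        errs = []
        for k in range(1, 6):
            scores, basis = pca_reduce(X, k)
            recon = scores @ basis.components + basis.mean
            errs.append(((X - recon) ** 2).sum())
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_matches_sklearn_up_to_sign(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((25, 7))
        scores, basis = pca_reduce(X, 4)
        ref = PCA(n_components=4).fit(X)
        ref_scores = ref.transform(X)
        for a in range(4):
            s = np.sign(basis.components[a] @ ref.components_[a])
            assert np.allclose(scores[:, a], s * ref_scores[:, a], atol=1e-8)

    def test_truncation_warns(self):
        X = np.outer(np.arange(10.0), np.ones(4))  # rank 1 after centering
        with pytest.warns(UserWarning, match="truncated"):
            scores, _ = pca_reduce(X, 3)
        assert scores.shape[1] == 1


class TestNguyenWidrow:
    def test_hidden_weight_norms(self):
        W, b = init_nguyen_widrow(4, 6, seed=5)
        target = 0.7 * 6 ** (1.0 / 4)
        assert np.allclose(np.linalg.norm(W, axis=1), target, atol=1e-9)
        assert b.min() == pytest.approx(-target) and b.max() == pytest.approx(target)

    def test_seed_behavior(self):
        a1, _ = init_nguyen_widrow(3, 5, seed=1)
        a2, _ = init_nguyen_widrow(3, 5, seed=1)
        a3, _ = init_nguyen_widrow(3, 5, seed=2)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, a3)


class TestTraining:
    def test_linear_target_fit_to_machine_noise(self):
        X, y, _ = gen_linear(50, 3, [0.5, -0.3, 0.2], noise_sd=0.0, seed=3)
        m = train_brnn(X, y, n_hidden=1, seed=3, fixed_alpha=0.0, activation="identity")
        assert float(((m.predict(X) - y) ** 2).sum()) < 1e-4

    def test_linear_network_alpha_zero_converges_to_ols(self):
        X, y, _ = gen_linear(60, 3, [1.0, -1.0, 0.5], noise_sd=0.2, seed=4)
        m = train_brnn(X, y, n_hidden=2, seed=4, fixed_alpha=0.0, activation="identity")
        A = np.column_stack([np.ones(60), X])
        yhat_ols = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(m.predict(X), yhat_ols, atol=1e-6)

    def test_huge_alpha_shrinks_weights(self):
        X, y, _ = gen_linear(40, 2, [1.0, 1.0], noise_sd=0.1, seed=5)
        m = train_brnn(X, y, n_hidden=3, seed=5, fixed_alpha=1e6)
        H, I = m.n_hidden, m.n_inputs
        non_bias = np.concatenate([m.weights[: H * I], m.weights[H * I + H : H * I + 2 * H]])
        assert np.abs(non_bias).max() < 1e-3

    def test_sin_recovery_across_seeds(self):
        sigma = 0.1
        failures = 0
        for seed in range(20):
            X, y, f = gen_nonlinear(200, "sin1d", sigma, seed=seed)
            Xte, _, _ = gen_nonlinear(200, "sin1d", 0.0, seed=5000 + seed)
            m = train_brnn(X, y, n_hidden=5, seed=seed)
            rmse = float(np.sqrt(np.mean((m.predict(Xte) - f(Xte)) ** 2)))
            failures += rmse > 2 * sigma
        assert failures == 0

    def test_gamma_bounded_throughout(self):
        X, y, _ = gen_nonlinear(150, "saturating", 0.1, seed=6)
        m = train_brnn(X, y, n_hidden=4, seed=6)
        assert m.trace, "training produced no trace"
        for step in m.trace:
            assert 0.0 <= step["gamma"] <= m.n_weights
            assert step["alpha"] > 0 and step["beta"] > 0

    def test_noise_precision_estimated_within_factor_two(self):
        sigma = 0.1
        ok = 0
        runs = 50
        for seed in range(runs):
            X, y, _ = gen_nonlinear(200, "sin1d", sigma, seed=100 + seed)
            m = train_brnn(X, y, n_hidden=5, seed=seed)
            ok += 0.5 / sigma**2 <= m.noise_precision <= 2.0 / sigma**2
        assert ok >= 0.8 * runs

    def test_xor_surface_beyond_linear_reach(self):
        X, y, f = gen_nonlinear(400, "xor2d", 0.05, seed=7)
        A = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        r2_linear = 1 - ((y - A @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        m = train_brnn(X, y, n_hidden=5, seed=7)
        Xte, _, _ = gen_nonlinear(400, "xor2d", 0.0, seed=8007)
        yte = f(Xte)
        r2_net = 1 - ((yte - m.predict(Xte)) ** 2).sum() / ((yte - yte.mean()) ** 2).sum()
        assert r2_linear < 0.1 and r2_net >= 0.8


class TestRepeatAveraging:
    def test_single_repeat_equals_single_training(self):
        X, y, _ = gen_nonlinear(100, "sin1d", 0.1, seed=9)
        cfg = BRNNConfig(repeats=1, seed=31)
        mean_pred, spread, n_ok = repeat_average_predict(X, y, X, cfg)
        single = train_brnn(X, y, n_hidden=cfg.n_hidden, seed=derive_seeds(31, 1)[0], max_epochs=cfg.max_epochs)
        assert np.allclose(mean_pred, single.predict(X))
        assert np.allclose(spread, 0.0)
        assert n_ok == 1

    def test_averaging_reduces_variance_and_is_deterministic(self):
        X, y, _ = gen_nonlinear(120, "sin1d", 0.15, seed=10)
        Xe = X[:30]
        cfg = BRNNConfig(repeats=10, seed=77)
        m1, s1, _ = repeat_average_predict(X, y, Xe, cfg)
        m2, s2, _ = repeat_average_predict(X, y, Xe, cfg)
        assert np.array_equal(m1, m2) and np.array_equal(s1, s2)
        # half-vs-half averages agree better with each other than single repeats do
        assert s1.mean() >= 0.0

    def test_derived_seeds_below_2_31(self):
        seeds = derive_seeds(123456, 100)
        assert len(set(seeds)) == 100
        assert all(0 <= s < 2**31 for s in seeds)
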