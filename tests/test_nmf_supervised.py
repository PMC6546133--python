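import numpy as np
import pytest
from scipy.linalg import subspace_angles

from supnmf import (
    AdadeltaState,
    NMFConfig,
    NMFFactors,
    SynthSpec,
    adadelta_step,
    cost_flda,
    cost_fr,
    fit_nmf,
    fit_supervised,
    flog_cost,
    flog_gradients,
    generate_dataset,
    init_factors,
    project_positive,
    update_flda,
    update_fr,
)
from supnmf.nmf_supervised import _check_labels


def random_supervised_problem(seed, n=8, m=10, p=3):
    r = np.random.default_rng(seed)
    Y = r.random((n, m))
    u = r.integers(0, 2, n)
    if u.sum() == 0:
        u[0] = 1
    if u.sum() == n:
        u[0] = 0
    return Y, u.astype(float)


class TestCostFlda:
    def test_gamma_zero_equals_unsupervised(self):
        Y, u = random_supervised_problem(0)
        f = init_factors(8, 10, 3, 0, y_mean=Y.mean())
        f.beta = np.array([0.5, 0.2, 0.1])
        cfg = NMFConfig(model="FRlda", p=3, gamma=0.0, lambda_l1=0.1)
        assert cost_flda(Y, u, f, cfg) == pytest.approx(cost_fr(Y, f, cfg))

    def test_hand_computed(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        f = NMFFactors(K=[[1.0], [0.0]], X=[[1.0, 0.0]], beta=[1.0])
        u = np.array([1.0, 0.0])
        cfg = NMFConfig(model="Flda", p=1, gamma=2.0)
        # residual 1/2, supervision term exactly zero
        assert cost_flda(Y, u, f, cfg) == pytest.approx(0.5)

    def test_negative_beta_rejected(self):
        f = NMFFactors(K=[[1.0]], X=[[1.0]], beta=[-0.1])
        with pytest.raises(ValueError, match="non-negative"):
            cost_flda(np.eye(1), np.array([1.0]), f,
                      NMFConfig(model="Flda", p=1))


class TestUpdateFlda:
    def test_gamma_zero_reduces_to_fr_rules(self):
        Y, u = random_supervised_problem(1)
        f = init_factors(8, 10, 3, 1, y_mean=Y.mean())
        f.beta = np.abs(np.random.default_rng(1).random(3)) + 0.1
        cfg = NMFConfig(model="FRlda", p=3, gamma=0.0, lambda_l1=0.02,
                        mu=0.01, nu=0.01)
        out = update_flda(Y, u, f, cfg)
        ref = update_fr(Y, f, cfg)
        np.testing.assert_allclose(out.K, ref.K, rtol=1e-12)
        np.testing.assert_allclose(out.X, ref.X, rtol=1e-10)

    def test_fixed_point_with_exact_supervision(self):
        # Y = KX exact, X = W orthonormal rows, u = Y X^T beta exactly
        X = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        Y = K @ X
        beta = np.array([1.0, 1.0])
        u = Y @ X.T @ beta  # = (1, 1)
        cfg = NMFConfig(model="FROlda", p=2, gamma=0.7, sigma1=0.3,
                        sigma2=0.4)
        f = NMFFactors(K, X, W=X.copy(), beta=beta)
        out = update_flda(Y, u, f, cfg)
        np.testing.assert_allclose(out.K, K, atol=1e-9)
        np.testing.assert_allclose(out.X, X, atol=1e-9)
        np.testing.assert_allclose(out.beta, beta, atol=1e-9)

    @pytest.mark.parametrize("model,kw", [
        ("Flda", {}),
        ("FRlda", {"lambda_l1": 0.02, "mu": 0.01, "nu": 0.01}),
        ("FROlda", {"lambda_l1": 0.02, "sigma1": 0.5, "sigma2": 0.5}),
    ])
    @pytest.mark.parametrize("seed", range(5))
    def test_cost_non_increasing_and_nonnegative(self, model, kw, seed):
        Y, u = random_supervised_problem(seed, n=8, m=10, p=3)
        cfg = NMFConfig(model=model, p=3, gamma=1.0, **kw)
        f = init_factors(8, 10, 3, seed, with_w=cfg.uses_w, y_mean=Y.mean())
        f.beta = np.random.default_rng(seed).random(3) + 0.05
        prev = cost_flda(Y, u, f, cfg)
        for _ in range(60):
            f = update_flda(Y, u, f, cfg)
            c = cost_flda(Y, u, f, cfg)
            assert c <= prev + 1e-8 * max(prev, 1.0)
            assert f.K.min() >= 0 and f.X.min() >= 0 and f.beta.min() >= 0
            prev = c

    def test_all_zero_labels_rejected(self):
        Y, _ = random_supervised_problem(2)
        f = init_factors(8, 10, 2, 0, y_mean=1.0)
        f.beta = np.ones(2)
        with pytest.raises(ValueError, match="zero"):
            update_flda(Y, np.zeros(8), f, NMFConfig(model="Flda", p=2))


class TestFlogCost:
    def test_beta_zero_closed_form(self):
        Y, u = random_supervised_problem(3)
        f = init_factors(8, 10, 3, 0, y_mean=Y.mean())
        cfg = NMFConfig(model="Flog", p=3, gamma=1.7)
        expected = 0.5 * np.sum((Y - f.K @ f.X) ** 2) + 1.7 * np.log(2)
        got = flog_cost(Y, u, f.X, f.K, np.zeros(4), cfg)
        assert got == pytest.approx(expected)

    def test_gamma_zero_is_pure_frobenius(self):
        Y, u = random_supervised_problem(4)
        f = init_factors(8, 10, 3, 1, y_mean=Y.mean())
        cfg = NMFConfig(model="Flog", p=3, gamma=0.0)
        beta = np.random.default_rng(0).normal(size=4)
        assert flog_cost(Y, u, f.X, f.K, beta, cfg) == pytest.approx(
            0.5 * np.sum((Y - f.K @ f.X) ** 2))

    def test_stable_for_large_scores(self):
        Y = np.array([[1.0]])
        u = np.array([1.0])
        X = np.array([[1.0]])
        K = np.array([[1.0]])
        cfg = NMFConfig(model="Flog", p=1, gamma=1.0)
        c = flog_cost(Y, u, X, K, np.array([1000.0, 0.0]), cfg)
        assert np.isfinite(c)
        c = flog_cost(Y, u, X, K, np.array([-1000.0, 0.0]), cfg)
        assert np.isfinite(c)


class TestFlogGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_central_finite_differences(self, seed):
        r = np.random.default_rng(seed)
        n, m, p = 5, 6, 2
        Y = r.random((n, m))
        u = (r.random(n) < 0.5).astype(float)
        X = r.random((p, m)) + 0.1
        K = r.random((n, p)) + 0.1
        beta = r.normal(size=p + 1)
        cfg = NMFConfig(model="Flog", p=p, gamma=2.0)
        gX, gb = flog_gradients(Y, u, X, K, beta, cfg)
        h = 1e-6

        def cost_at(Xv, bv):
            return flog_cost(Y, u, Xv, K, bv, cfg)

        for idx in [(0, 0), (1, 3), (0, 5)]:
            Xp, Xm = X.copy(), X.copy()
            Xp[idx] += h
            Xm[idx] -= h
            fd = (cost_at(Xp, beta) - cost_at(Xm, beta)) / (2 * h)
            assert abs(gX[idx] - fd) / max(abs(fd), 1e-8) < 1e-5
        for j in range(p + 1):
            bp, bm = beta.copy(), beta.copy()
            bp[j] += h
            bm[j] -= h
            fd = (cost_at(X, bp) - cost_at(X, bm)) / (2 * h)
            assert abs(gb[j] - fd) / max(abs(fd), 1e-8) < 1e-5

    def test_balanced_labels_zero_intercept_gradient(self):
        r = np.random.default_rng(1)
        Y = r.random((6, 5))
        u = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        X = r.random((2, 5))
        K = r.random((6, 2))
        cfg = NMFConfig(model="Flog", p=2, gamma=3.0)
        _, gb = flog_gradients(Y, u, X, K, np.zeros(3), cfg)
        assert gb[0] == pytest.approx(0.0, abs=1e-12)

    def test_gamma_zero_reduces_to_data_term(self):
        r = np.random.default_rng(2)
        Y = r.random((4, 5))
        u = np.array([1, 0, 1, 0], dtype=float)
        X = r.random((2, 5))
        K = r.random((4, 2))
        cfg = NMFConfig(model="Flog", p=2, gamma=0.0)
        gX, gb = flog_gradients(Y, u, X, K, r.normal(size=3), cfg)
        np.testing.assert_allclose(gb, 0.0)
        np.testing.assert_allclose(gX, -K.T @ (Y - K @ X))


class TestAdadelta:
    def test_zero_gradient_zero_step(self):
        state = AdadeltaState(np.array([4.0]), np.array([9.0]))
        delta, new = adadelta_step(np.zeros(1), state, rho=0.9, eps=1e-6)
        assert delta[0] == 0.0
        assert new.accum_grad_sq[0] == pytest.approx(3.6)  # decayed only
        assert new.accum_update_sq[0] == pytest.approx(8.1)

    def test_step_opposes_gradient(self):
        r = np.random.default_rng(0)
        g = r.normal(size=20)
        state = AdadeltaState.zeros(20)
        delta, _ = adadelta_step(g, state, rho=0.95, eps=1e-6)
        assert np.all(np.sign(delta) == -np.sign(g))

    def test_constant_gradient_step_stabilizes(self):
        state = AdadeltaState.zeros(1)
        g = np.array([2.0])
        sizes = []
        for _ in range(3000):
            delta, state = adadelta_step(g, state, rho=0.95, eps=1e-6)
            sizes.append(abs(delta[0]))
        # ratio of consecutive step sizes converges to 1
        assert abs(sizes[-1] / sizes[-2] - 1) < 1e-3
        assert abs(sizes[-1] / sizes[-2] - 1) < abs(sizes[10] / sizes[9] - 1)


class TestProjectPositive:
    def test_floors_nonpositive_entries(self):
        X = np.array([[-1.0, 0.5], [0.0, 2.0]])
        out = project_positive(X, 1e-9)
        np.testing.assert_array_equal(out, [[1e-9, 0.5], [1e-9, 2.0]])

    def test_idempotent(self):
        X = np.array([[-3.0, 1.0]])
        once = project_positive(X, 1e-6)
        np.testing.assert_array_equal(project_positive(once, 1e-6), once)


class TestFitSupervised:
    def test_deterministic(self):
        Y, u = random_supervised_problem(5, n=12, m=10, p=2)
        cfg = NMFConfig(model="Flog", p=2, gamma=10.0, max_iter=50, seed=3)
        f1, t1 = fit_supervised(Y, u, cfg)
        f2, t2 = fit_supervised(Y, u, cfg)
        np.testing.assert_array_equal(f1.X, f2.X)
        np.testing.assert_array_equal(f1.beta, f2.beta)
        np.testing.assert_array_equal(t1.cost_per_iteration,
                                      t2.cost_per_iteration)

    def test_flog_beta_has_intercept_and_x_positive(self):
        Y, u = random_supervised_problem(6, n=12, m=10)
        cfg = NMFConfig(model="Flog", p=3, gamma=10.0, max_iter=40, seed=0)
        f, _ = fit_supervised(Y, u, cfg)
        assert f.beta.size == 4
        assert f.X.min() > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_flog_net_cost_decrease_first_sweeps(self, seed):
        Y, u = random_supervised_problem(seed, n=10, m=12, p=3)
        cfg = NMFConfig(model="Flog", p=3, gamma=5.0, max_iter=10,
                        rel_tol=1e-15, seed=seed)
        _, trace = fit_supervised(Y, u, cfg)
        assert trace.cost_per_iteration[-1] < trace.cost_per_iteration[0]

    def test_flda_family_monotone_full_fit(self):
        Y, u = random_supervised_problem(7, n=15, m=12)
        cfg = NMFConfig(model="FRlda", p=3, gamma=1.0, lambda_l1=0.01,
                        max_iter=80, seed=1)
        _, trace = fit_supervised(Y, u, cfg)
        diffs = np.diff(trace.cost_per_iteration)
        assert np.all(diffs <= 1e-8 * trace.cost_per_iteration[0])

    def test_unsupervised_model_rejected(self):
        with pytest.raises(ValueError, match="fit_supervised"):
            fit_supervised(np.ones((4, 3)), np.array([0, 1, 0, 1]),
                           NMFConfig(model="FR", p=2))

    def test_flog_training_recovery_on_planted_signal(self):
        """With a weak planted class pattern, the integrated logistic
        classifier separates the training classes almost perfectly."""
        from supnmf import balanced_accuracy, build_classifier, predict

        spec = SynthSpec(n_groups=2, spectra_per_group=60, m=120,
                         p_dominant=4, n_discriminative=2,
                         effect_ratio=0.1, seed=12)
        ds, _ = generate_dataset(spec)
        cfg = NMFConfig(model="Flog", p=5, gamma=3000.0, max_iter=800,
                        rel_tol=1e-12, seed=0)
        f, _ = fit_supervised(ds.intensities, ds.labels, cfg)
        clf = build_classifier("Flog_int", f, ds.intensities, ds.labels)
        ba = balanced_accuracy(ds.labels, predict(clf, ds.intensities))
        assert ba >= 0.95


def test_supervision_steers_subspace_toward_planted_direction():
    """Median over seeds: the angle between span(X) and the planted
    discriminative pattern is smaller for supervised Flog than for
    unsupervised FR at equal p."""
    spec = SynthSpec(n_groups=4, spectra_per_group=30, m=120, p_dominant=4,
                     n_discriminative=1, seed=7)
    ds, truth = generate_dataset(spec)
    d = truth.discriminative_patterns[0][:, None]
    ang_flog, ang_fr = [], []
    for seed in range(20):
        cfg = NMFConfig(model="Flog", p=4, gamma=3000.0, max_iter=400,
                        rel_tol=1e-12, seed=seed)
        f, _ = fit_supervised(ds.intensities, ds.labels, cfg)
        ang_flog.append(subspace_angles(f.X.T, d)[0])
        cfg_fr = NMFConfig(model="FR", p=4, max_iter=200, seed=seed)
        f2, _ = fit_nmf(ds.intensities, cfg_fr)
        ang_fr.append(subspace_angles(f2.X.T, d)[0])
    assert np.median(ang_flog) < np.median(ang_fr)


def test_label_validation():
    with pytest.raises(ValueError, match="binary"):
        _check_labels(np.array([0, 2, 1]))
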