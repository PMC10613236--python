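import numpy as np
import pytest

from motifnet.glm import (
    build_design_matrix,
    coupling_edges,
    enet_poisson_path,
    fit_poisson_glm,
    pseudo_ev,
    raised_cosine_basis,
    reconstruct,
    significant_predictors,
    summarize_weights,
)
from motifnet.glm.fit import GLMFit, poisson_deviance
from motifnet.glm.solver import kkt_violation, lambda_path

from conftest import make_session


def brute_force_pseudo_ev(y, y_hat):
    """Oracle via raw Poisson log-likelihoods (saturated-model deviances)."""

    def loglik(y, mu):
        out = 0.0
        for yi, mi in zip(y, mu):
            out += yi * np.log(mi) if mi > 0 else (0.0 if yi == 0 else -np.inf)
            out -= mi
        return out

    ll_sat = loglik(y, np.where(y > 0, y, 1.0) * (y > 0) + (y == 0) * 1e-300)
    # saturated: mu = y, with 0*log(0) treated as 0
    ll_sat = sum((yi * np.log(yi) - yi) if yi > 0 else 0.0 for yi in y)
    d_model = ll_sat - loglik(y, y_hat)
    d_null = ll_sat - loglik(y, np.full_like(y, np.mean(y)))
    return 1.0 - d_model / d_null


class TestRaisedCosineBasis:
    def test_single_basis_peak_at_center(self):
        b = raised_cosine_basis(1, 1.0, 9.35)
        assert b.matrix.shape == (9, 1)
        assert b.matrix.max() == pytest.approx(1.0)
        assert np.argmax(b.matrix[:, 0]) == 4

    def test_three_over_one_second(self):
        b = raised_cosine_basis(3, 1.0, 9.35)
        assert b.matrix.shape == (9, 3)
        peaks = [np.argmax(b.matrix[:, j]) for j in range(3)]
        assert peaks == [0, 4, 8]
        assert (b.matrix >= 0).all()

    def test_interior_tiling_near_constant(self):
        b = raised_cosine_basis(5, 3.0, 20.0)
        total = b.matrix.sum(axis=1)
        interior = total[10:-10]
        assert interior.max() / interior.min() < 1.1

    def test_too_short_span(self):
        with pytest.raises(ValueError):
            raised_cosine_basis(3, 0.01, 9.35)


class TestDesignMatrix:
    def test_column_counts(self, sim_session):
        sess, _ = sim_session
        d = build_design_matrix(sess, target_neuron=0)
        n_coupling = sum(g.startswith("coupling:") for g in d.column_groups)
        assert n_coupling == (sess.n_neurons - 1) * 2
        task = [g for g in d.column_groups if not g.startswith("coupling:")]
        # 2*3 stim + 2*5 delay + 2*5 resp + 3 reward = 29 (no movement given)
        assert len(task) + len([x for x in d.dropped
                                if not x.startswith("coupling:")]) == 29

    def test_with_movement_35_task_columns(self, sim_session):
        sess, _ = sim_session
        speed = {"L": np.abs(np.sin(np.arange(sess.n_frames))),
                 "R": np.abs(np.cos(np.arange(sess.n_frames)))}
        d = build_design_matrix(sess, target_neuron=0, movement_speed=speed)
        task = [g for g in d.column_groups if not g.startswith("coupling:")]
        assert len(task) + len([x for x in d.dropped
                                if not x.startswith("coupling:")]) == 35

    def test_zscored_columns(self, sim_session):
        sess, _ = sim_session
        d = build_design_matrix(sess, target_neuron=3)
        np.testing.assert_allclose(d.X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(d.X.std(axis=0), 1.0, atol=1e-10)

    def test_target_not_own_predictor(self, sim_session):
        sess, _ = sim_session
        d = build_design_matrix(sess, target_neuron=5)
        assert all(f"coupling:5:" not in g for g in d.column_groups)
        with pytest.raises(ValueError):
            build_design_matrix(sess, target_neuron=5, source_neurons=[5, 6])

    def test_coupling_columns_are_lags(self, sim_session):
        sess, _ = sim_session
        d = build_design_matrix(sess, target_neuron=0, zscore=False)
        j = d.column_names.index("coupling:3:2")
        row = int(np.flatnonzero(sess.neuron_ids == 3)[0])
        np.testing.assert_allclose(d.X[2:, j], sess.activity[row][:-2])
        np.testing.assert_allclose(d.X[:2, j], 0.0)


class TestPseudoEV:
    def test_saturated_is_one(self):
        y = np.array([1.0, 0.0, 2.0, 3.0])
        y_hat = np.where(y > 0, y, 1e-9)
        assert pseudo_ev(y, y_hat) == pytest.approx(1.0, abs=1e-6)

    def test_null_is_zero(self):
        y = np.array([1.0, 0.0, 2.0])
        assert pseudo_ev(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_worked_example(self):
        y = np.array([1.0, 0.0, 2.0])
        y_hat = np.array([0.5, 0.5, 2.0])
        assert pseudo_ev(y, y_hat) == pytest.approx(0.5)
        assert poisson_deviance(y, y_hat) == pytest.approx(2 * np.log(2))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 12)
            y = rng.poisson(1.5, n).astype(float)
            if np.ptp(y) == 0:
                continue
            y_hat = rng.gamma(2.0, 1.0, n)
            assert pseudo_ev(y, y_hat) == pytest.approx(
                brute_force_pseudo_ev(y, y_hat), abs=1e-10
            )

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            pseudo_ev(np.ones(5), np.ones(5))


class TestSolver:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(2.0, 200).astype(float)
        X = np.empty((200, 0))
        B, b0, lams = enet_poisson_path(X, y, n_lambda=3)
        assert b0[-1] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_unpenalized_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 4))
        beta_true = np.array([0.4, -0.3, 0.0, 0.2])
        y = rng.poisson(np.exp(X @ beta_true - 0.5))
        lams = np.array([1e-8])
        B, b0, _ = enet_poisson_path(X, y.astype(float), alpha=0.95,
                                     lambdas=lams, tol=1e-9)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(b0[0], ref.params[0], atol=1e-4)
        np.testing.assert_allclose(B[:, 0], ref.params[1:], atol=1e-4)

    def test_kkt_conditions_along_path(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 10))
        y = rng.poisson(np.exp(0.5 * X[:, 0] - 0.3 * X[:, 3] - 0.7))
        B, b0, lams = enet_poisson_path(X, y.astype(float), alpha=0.95,
                                        n_lambda=20, tol=1e-7)
        for li in (0, 5, 10, 19):
            assert kkt_violation(X, y.astype(float), B[:, li], b0[li],
                                 0.95, lams[li]) < 1e-4

    def test_cd_and_fista_agree(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(250, 8))
        y = rng.poisson(np.exp(0.6 * X[:, 1] - 0.6)).astype(float)
        lams = lambda_path(X, y, 0.95, 10, 1e-2)
        B1, b1, _ = enet_poisson_path(X, y, lambdas=lams, tol=1e-8, method="cd")
        B2, b2, _ = enet_poisson_path(X, y, lambdas=lams, tol=1e-8,
                                      method="fista")
        np.testing.assert_allclose(B1, B2, atol=2e-4)

    def test_negative_y_rejected(self):
        with pytest.raises(ValueError):
            enet_poisson_path(np.ones((5, 1)), np.array([1.0, -1, 0, 0, 0]))


@pytest.fixture(scope="module")
def fitted(sim_session):
    sess, truth = sim_session
    target = 2
    design = build_design_matrix(sess, target_neuron=target)
    fit = fit_poisson_glm(design, sess.activity[target], n_lambda=20,
                          lambda_min_ratio=1e-2)
    return sess, truth, target, design, fit


class TestFit:
    def test_split_and_selection(self, fitted):
        sess, _, target, design, fit = fitted
        assert len(fit.train_idx) == int(round(0.7 * sess.n_frames))
        assert fit.test_idx[0] == fit.train_idx[-1] + 1
        assert 0 <= fit.selected_lambda_index < len(fit.lambdas)

    def test_pseudo_ev_positive_on_structured_data(self, fitted):
        *_, fit = fitted
        assert fit.pseudo_ev_test > 0.0

    def test_column_order_invariance(self, sim_session):
        sess, _ = sim_session
        target = 1
        design = build_design_matrix(sess, target_neuron=target)
        fit1 = fit_poisson_glm(design, sess.activity[target], n_lambda=12,
                               lambda_min_ratio=1e-2)
        rng = np.random.default_rng(5)
        perm = rng.permutation(design.X.shape[1])
        import copy

        d2 = copy.copy(design)
        d2.X = design.X[:, perm]
        d2.column_names = [design.column_names[i] for i in perm]
        d2.column_groups = [design.column_groups[i] for i in perm]
        fit2 = fit_poisson_glm(d2, sess.activity[target], n_lambda=12,
                               lambda_min_ratio=1e-2)
        back = np.empty_like(fit2.beta)
        back[perm] = fit2.beta
        np.testing.assert_allclose(fit1.beta, back, atol=2e-4)

    def test_null_data_low_ev(self):
        sess = make_session(n_neurons=8, n_trials=30, seed=42)
        design = build_design_matrix(sess, target_neuron=0)
        rng = np.random.default_rng(6)
        y = rng.poisson(0.5, sess.n_frames).astype(float)  # independent of X
        fit = fit_poisson_glm(design, y, n_lambda=10, lambda_min_ratio=1e-2)
        assert fit.pseudo_ev_test <= 0.02


class TestReconstruct:
    def test_full_subset_identity(self, fitted):
        *_, design, fit = fitted
        full = reconstruct(fit, design.X, "full")
        eta = design.X @ fit.beta + fit.beta0
        np.testing.assert_allclose(full, np.exp(eta), rtol=1e-12)

    def test_empty_subset_constant(self, fitted):
        *_, design, fit = fitted
        out = reconstruct(fit, design.X, [])
        np.testing.assert_allclose(out, np.exp(fit.beta0))

    def test_log_linear_factorization(self, fitted):
        *_, design, fit = fitted
        full = reconstruct(fit, design.X, "full")
        task = reconstruct(fit, design.X, "task_only")
        coup = reconstruct(fit, design.X, "coupling_only")
        np.testing.assert_allclose(full, task * coup / np.exp(fit.beta0),
                                   rtol=1e-9)

    def test_unknown_subset_rejected(self, fitted):
        *_, design, fit = fitted
        with pytest.raises(KeyError):
            reconstruct(fit, design.X, ["not_a_group"])


class TestSummarizeWeights:
    def test_signed_maximum(self, fitted):
        *_, fit = fitted
        cols = [i for i, g in enumerate(fit.column_groups) if g == "stimR"]
        fit2 = GLMFit(**{**fit.__dict__})
        fit2.beta = fit.beta.copy()
        fit2.beta[cols] = [-0.5, -0.1, -0.3][: len(cols)]
        assert summarize_weights(fit2, "stimR") == pytest.approx(-0.1)

    def test_zero_group(self, fitted):
        *_, fit = fitted
        fit2 = GLMFit(**{**fit.__dict__})
        fit2.beta = np.zeros_like(fit.beta)
        assert summarize_weights(fit2, "delayL") == 0.0


class TestSignificance:
    def test_zero_beta_group_never_significant(self, fitted):
        sess, _, target, design, fit = fitted
        sig = significant_predictors(fit, design, sess.activity[target],
                                     n_shuffles=50, seed=0)
        zero_groups = {
            g for g in dict.fromkeys(fit.column_groups)
            if not np.any(fit.beta[[i for i, gg in enumerate(fit.column_groups)
                                    if gg == g]])
        }
        t = sig.table.set_index("group")
        for g in zero_groups:
            assert t.loc[g, "delta_ev"] == 0.0
            assert not t.loc[g, "significant"]

    def test_planted_coupling_significant(self, sim_session):
        sess, truth = sim_session
        targets_with_edges = truth.coupling["target"].value_counts()
        target = int(targets_with_edges.index[0])
        design = build_design_matrix(sess, target_neuron=target)
        fit = fit_poisson_glm(design, sess.activity[target], n_lambda=20,
                              lambda_min_ratio=1e-2)
        sig = significant_predictors(fit, design, sess.activity[target],
                                     n_shuffles=500, seed=1)
        edges = coupling_edges(fit, sig)
        found = set(edges.loc[edges["significant"], "source"])
        planted = set(truth.coupling.loc[truth.coupling["target"] == target,
                                         "source"])
        assert len(found & planted) >= max(1, len(planted) // 2)

    def test_negative_delta_ev_tolerated(self, fitted):
        sess, _, target, design, fit = fitted
        sig = significant_predictors(fit, design, sess.activity[target],
                                     n_shuffles=30, seed=2)
        assert np.isfinite(sig.table["delta_ev"]).all()
        assert ((sig.table["p"] > 0) & (sig.table["p"] <= 1)).all()

    def test_too_few_blocks_rejected(self, fitted):
        sess, _, target, design, fit = fitted
        with pytest.raises(ValueError, match="blocks"):
            significant_predictors(fit, design, sess.activity[target],
                                   block_s=1e5)
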