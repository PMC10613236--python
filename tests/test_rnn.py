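import numpy as np
import pytest

from motifnet import rnn
from motifnet.rnn import (
    RNNModel,
    TargetSet,
    choice_readout,
    decision_switch_fraction,
    force_train,
    init_rnn,
    inverse_sigmoid,
    make_attractor_targets,
    make_innate_targets,
    mse_filter,
    prepare_targets,
    run_trials,
    trial_clock_inputs,
)


class TestInit:
    def test_weight_statistics(self):
        m = init_rnn(400, g=1.2, seed=0)
        assert m.J.std() == pytest.approx(1.2 / np.sqrt(400), rel=0.1)
        assert m.W_stimulus.std() == pytest.approx(1.0, rel=0.15)
        assert m.W_cue.std() == pytest.approx(0.1, rel=0.15)

    def test_p_initialization_paper_convention(self):
        m = init_rnn(10, seed=1)
        np.testing.assert_allclose(m.P, 0.01 * np.eye(10))

    def test_p_initialization_inverse_convention(self):
        m = init_rnn(10, seed=1, p_inverse=True)
        np.testing.assert_allclose(m.P, 100.0 * np.eye(10))

    def test_same_seed_identical(self):
        m1 = init_rnn(30, seed=5)
        m2 = init_rnn(30, seed=5)
        np.testing.assert_array_equal(m1.J, m2.J)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            init_rnn(1)


class TestDynamics:
    def test_zero_input_geometric_decay(self):
        # J=0, no input, no noise: x decays by exactly (1 - dt/tau) = 0.9
        n = 5
        m = init_rnn(n, seed=0)
        m.J = np.zeros((n, n))
        x0 = np.full(n, 1.0) + m.theta  # arbitrary start above theta
        from motifnet.rnn import _run_trial

        drive = np.zeros((2, 50))
        noise = np.zeros((n, 50))
        out_r = _run_trial(m.J, np.zeros(n), np.zeros(n), x0 - m.theta + m.theta,
                           drive, noise, 0.1, m.beta, m.theta, 1)
        # reconstruct x from r and verify the closed form
        x = m.theta + np.log(out_r / (1 - out_r)) / m.beta
        expected = (x0[:, None]) * (0.9 ** np.arange(1, 51))[None, :]
        np.testing.assert_allclose(x, expected, rtol=1e-9)

    def test_sigmoid_midpoint_and_saturation(self):
        from motifnet.rnn import _sigmoid

        assert _sigmoid(np.array([3.0]), 0.8, 3.0)[0] == pytest.approx(0.5)
        assert _sigmoid(np.array([100.0]), 0.8, 3.0)[0] == pytest.approx(1.0)

    def test_trial_inputs_supports(self):
        drive = trial_clock_inputs(3500, stim_peak=1.0, distractor_amp=0.3)
        stim, cue = drive
        assert stim[:490].sum() == 0  # before stimulus onset
        assert stim[500:1500].max() == pytest.approx(1.0)
        assert cue[1400:1500].max() == pytest.approx(1.0)
        assert cue[1501:].sum() == 0
        assert stim[1750:2250].max() == pytest.approx(0.3)
        assert stim[2260:].sum() == 0


class TestPrepareTargets:
    def test_inverse_sigmoid_midpoint(self):
        assert inverse_sigmoid(np.array([0.5]))[0] == pytest.approx(3.0)

    def test_clipping_keeps_targets_finite(self):
        rng = np.random.default_rng(0)
        act = rng.uniform(0, 7.0, size=(6, 33))  # exceeds the max of 5
        tgt = prepare_targets(act, act * 0.5, seed=0)
        assert np.isfinite(tgt.f_right).all()
        assert np.isfinite(tgt.f_left).all()

    def test_upsampling_factor_ten(self):
        rng = np.random.default_rng(1)
        act = rng.uniform(0.5, 3.0, size=(4, 33))
        tgt = prepare_targets(act, act, seed=0)
        assert tgt.n_samples == 330

    def test_quiet_units_excluded(self):
        rng = np.random.default_rng(2)
        act = rng.uniform(1.0, 4.0, size=(5, 30))
        act[2] = 0.0  # never reaches 1 SD of normalized activity
        tgt = prepare_targets(act, act, seed=0)
        assert tgt.n_principal == 4

    def test_external_sampled_with_replacement(self):
        rng = np.random.default_rng(3)
        act = rng.uniform(1.0, 4.0, size=(4, 30))
        ext = rng.uniform(1.0, 4.0, size=(3, 30))
        tgt = prepare_targets(act, act, ext, ext, n_external=8, seed=0)
        assert tgt.n_units == 4 + 8


class TestMSEFilter:
    def test_worked_example(self):
        models = [(None, 1.0), (None, 1.0), (None, 10.0)]
        kept = mse_filter(models)
        assert [m for _, m in kept] == [1.0, 1.0]

    def test_all_equal_retained(self):
        models = [(None, 2.0)] * 4
        assert len(mse_filter(models)) == 4

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            mse_filter([(None, 1.0)])


@pytest.fixture(scope="module")
def trained_small():
    """A quickly trained 24-unit net on engineered attractor targets."""
    model = init_rnn(24, g=1.2, seed=3, n_external=6, p_inverse=True)
    targets = make_attractor_targets(model)
    trained, mse = force_train(model, targets, epochs=40, a_learn=0.2, seed=3)
    return model, targets, trained, mse


class TestForceTraining:
    def test_p_stays_symmetric(self, trained_small):
        _, _, trained, _ = trained_small
        np.testing.assert_allclose(trained.P, trained.P.T, atol=1e-8)

    def test_training_reduces_error(self, trained_small):
        model, targets, trained, mse = trained_small
        untrained_mse = rnn.evaluate_mse(model, targets, seed=9)
        assert mse < untrained_mse

    def test_same_seed_reproducible(self):
        model = init_rnn(16, seed=4, n_external=4, p_inverse=True)
        targets = make_innate_targets(model)
        t1, m1 = force_train(model, targets, epochs=5, seed=0)
        t2, m2 = force_train(model, targets, epochs=5, seed=0)
        np.testing.assert_array_equal(t1.J, t2.J)
        assert m1 == m2

    def test_initial_j_shared_across_target_sets(self):
        # pairwise design: same weight-init seed, different targets
        m1 = init_rnn(16, seed=7, n_external=4, p_inverse=True)
        m2 = init_rnn(16, seed=7, n_external=4, p_inverse=True)
        t1 = make_innate_targets(m1)
        t2 = make_attractor_targets(m2)
        tr1, _ = force_train(m1, t1, epochs=3, seed=0)
        tr2, _ = force_train(m2, t2, epochs=3, seed=0)
        np.testing.assert_array_equal(m1.J, m2.J)  # initial J identical
        assert not np.array_equal(tr1.J, tr2.J)  # training differs

    def test_dimension_mismatch_rejected(self, trained_small):
        model, targets, *_ = trained_small
        bad = TargetSet(f_right=targets.f_right[:3], f_left=targets.f_left[:3],
                        n_principal=3)
        with pytest.raises(ValueError):
            force_train(model, bad, epochs=1)


class TestTrials:
    def test_same_seed_identical_trials(self, trained_small):
        _, targets, trained, _ = trained_small
        x0 = targets.start_state()
        a = run_trials(trained, "left", n_trials=3, seed=5, x0=x0)
        b = run_trials(trained, "left", n_trials=3, seed=5, x0=x0)
        np.testing.assert_array_equal(a, b)

    def test_bad_trial_type(self, trained_small):
        _, _, trained, _ = trained_small
        with pytest.raises(ValueError):
            run_trials(trained, "up", n_trials=1)

    def test_output_shape(self, trained_small):
        _, targets, trained, _ = trained_small
        out = run_trials(trained, "right", n_trials=2, seed=0,
                         x0=targets.start_state())
        assert out.shape == (2, trained.n_total, 350)


class TestAblationValidation:
    def test_fraction_bounds(self, trained_small):
        _, targets, trained, _ = trained_small
        ro = None
        with pytest.raises(ValueError):
            rnn.ablate_external(trained, ro, fraction=1.5)

    def test_no_external_units_rejected(self):
        m = init_rnn(10, seed=0)  # n_external = 0
        with pytest.raises(ValueError, match="external"):
            rnn.ablate_external(m, None, fraction=0.5)

    def test_full_ablation_zeroes_blocks(self, trained_small):
        _, targets, trained, _ = trained_small
        npr, nex = trained.n_principal, trained.n_external
        m = trained.copy()
        rng = np.random.default_rng(0)
        for block in ((slice(0, npr), slice(npr, npr + nex)),
                      (slice(npr, npr + nex), slice(0, npr))):
            sub = m.J[block]
            sub[rng.random(sub.shape) < 1.0] = 0.0
            m.J[block] = sub
        assert np.all(m.J[:npr, npr:] == 0)
        assert np.all(m.J[npr:, :npr] == 0)


def test_model_checkpoint_roundtrip(tmp_path, trained_small):
    _, _, trained, _ = trained_small
    path = str(tmp_path / "model.h5")
    rnn.save_model(trained, path)
    back = rnn.load_model(path)
    np.testing.assert_array_equal(back.J, trained.J)
    np.testing.assert_array_equal(back.P, trained.P)
    assert back.n_principal == trained.n_principal
    assert back.g == trained.g
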