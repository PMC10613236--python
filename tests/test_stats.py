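import numpy as np
import pytest
from scipy import stats as sps

from motifnet.stats import (
    auc,
    bh_fdr,
    bootstrap_increase,
    classify_encoding,
    decoding_accuracy,
    learning_trend_null,
    shuffle_null_decoding,
    tuning_labels,
)

from conftest import make_session


def brute_force_auc(a, b):
    """Independent oracle: direct pair counting with half credit for ties."""
    wins = sum(1.0 if bb > aa else 0.5 if bb == aa else 0.0
               for aa in a for bb in b)
    return wins / (len(a) * len(b))


class TestAUC:
    def test_complete_separation(self):
        assert auc([1, 2], [3, 4]) == 1.0

    def test_identical_groups(self):
        assert auc([1, 2, 3], [1, 2, 3]) == 0.5

    def test_interleaved(self):
        assert auc([1, 3], [2, 4]) == pytest.approx(0.75)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.integers(0, 4, size=rng.integers(2, 10)).astype(float)
            b = rng.integers(0, 4, size=rng.integers(2, 10)).astype(float)
            assert auc(a, b) == pytest.approx(brute_force_auc(a, b), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.poisson(2, 8).astype(float), rng.poisson(2, 9).astype(float)
        assert auc(a, b) + auc(b, a) == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            auc([], [1.0])


class TestDecodingAccuracy:
    @pytest.mark.parametrize("a,expected", [(0.5, 0.0), (1.0, 1.0),
                                            (0.75, 0.5), (0.0, 1.0)])
    def test_formula(self, a, expected):
        assert decoding_accuracy(a) == pytest.approx(expected)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(size=7)
        assert decoding_accuracy(auc(a, b)) == pytest.approx(
            decoding_accuracy(auc(b, a))
        )


class TestShuffleNull:
    def test_perfect_separation_small_p(self):
        values = np.concatenate([np.zeros(20), np.ones(20)])
        labels = np.concatenate([np.zeros(20, bool), np.ones(20, bool)])
        res = shuffle_null_decoding(values, labels, n_shuffles=1000, seed=0)
        assert res.p_value <= 0.002
        assert res.accuracy == 1.0

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for i in range(120):
            values = rng.normal(size=24)
            labels = np.array([True, False] * 12)
            ps.append(shuffle_null_decoding(values, labels, n_shuffles=99,
                                            seed=i).p_value)
        stat = sps.kstest(ps, "uniform").pvalue
        assert stat > 0.01

    def test_zero_shuffles_rejected(self):
        with pytest.raises(ValueError):
            shuffle_null_decoding(np.arange(8.0), np.array([True, False] * 4),
                                  n_shuffles=0)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=20)
        l = np.array([True, False] * 10)
        r1 = shuffle_null_decoding(v, l, 200, seed=9)
        r2 = shuffle_null_decoding(v, l, 200, seed=9)
        assert r1.p_value == r2.p_value


class TestLearningTrend:
    def test_identical_stages_p_near_half(self):
        rng = np.random.default_rng(5)
        ps = []
        for i in range(30):
            v = rng.normal(size=30)
            l = np.array([True, False] * 15)
            ps.append(learning_trend_null(
                {"naive": (v, l), "expert": (v.copy(), l.copy())},
                n_shuffles=99, seed=i))
        assert abs(np.mean(ps) - 0.5) < 0.15

    def test_planted_increase_detected(self):
        rng = np.random.default_rng(6)
        l = np.array([True, False] * 15)
        naive = rng.normal(size=30)
        expert = np.where(l, 3.0, 0.0) + rng.normal(0, 0.5, 30)
        p = learning_trend_null({"naive": (naive, l), "expert": (expert, l)},
                                n_shuffles=500, seed=0)
        assert p < 0.05

    def test_missing_stage(self):
        with pytest.raises(ValueError, match="expert"):
            learning_trend_null({"naive": (np.arange(8.0),
                                           np.array([True, False] * 4))})


class TestBootstrap:
    def test_clear_increase(self):
        p = bootstrap_increase({"naive": np.zeros(10), "expert": np.ones(10)},
                               n_boot=1000, seed=0)
        assert p <= 0.001 + 1e-9

    def test_calibration_exchangeable(self):
        rng = np.random.default_rng(7)
        rejections = 0
        runs = 150
        for i in range(runs):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            if bootstrap_increase({"naive": a, "expert": b}, n_boot=99,
                                  seed=i) < 0.05:
                rejections += 1
        assert rejections / runs < 0.12

    def test_zero_boot_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_increase({"naive": np.ones(3), "expert": np.ones(3)},
                               n_boot=0)


class TestBHFDR:
    def test_hand_enumerated_example(self):
        # thresholds 0.0125 / 0.025 / 0.0375 / 0.05 -> first three rejected
        mask = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert mask.tolist() == [True, True, True, False]

    def test_all_ones_none(self):
        assert not bh_fdr(np.ones(5)).any()

    def test_single_small_p(self):
        assert bh_fdr(np.array([0.04]), q=0.05).tolist() == [True]

    def test_matches_step_up_oracle(self):
        def oracle(p, q):
            m = len(p)
            order = np.argsort(p)
            k = 0
            for i, idx in enumerate(order, start=1):
                if p[idx] <= i * q / m:
                    k = i
            mask = np.zeros(m, bool)
            mask[order[:k]] = True
            return mask

        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.random(rng.integers(1, 20))
            np.testing.assert_array_equal(bh_fdr(p, 0.05), oracle(p, 0.05))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, np.nan]))


class TestClassifyEncoding:
    def _tuned_session(self, delta=3.0, seed=0):
        sess = make_session(n_neurons=4, n_trials=40, seed=seed)
        rng = np.random.default_rng(seed)
        sess.activity = rng.poisson(1.0, sess.activity.shape).astype(float)
        for ti, trial in sess.trials.iterrows():
            go = int(trial.go_cue_frame)
            if trial.choice_side == "R":
                sess.activity[0, go - 9:go] += delta  # strong R choice tuning
        return sess

    def test_planted_right_tuning_labelled(self):
        sess = self._tuned_session()
        labels = classify_encoding(sess, variable="choice")
        assert labels.loc[0, "choice_encoding"] == "R"

    def test_identical_groups_none(self):
        sess = make_session(n_neurons=3, n_trials=30)
        sess.activity[:] = 1.0
        labels = classify_encoding(sess, variable="choice")
        assert (labels["choice_encoding"] == "none").all()

    def test_false_label_rate_calibrated(self):
        rng = np.random.default_rng(9)
        false = total = 0
        for i in range(12):
            sess = make_session(n_neurons=10, n_trials=40, seed=100 + i)
            sess.activity = rng.poisson(1.0, sess.activity.shape).astype(float)
            labels = classify_encoding(sess, variable="choice")
            false += (labels["choice_encoding"] != "none").sum()
            total += len(labels)
        assert false / total < 0.12

    def test_tuning_labels_combines_both(self):
        sess = self._tuned_session()
        t = tuning_labels(sess)
        assert set(t.columns) == {"neuron_id", "stimulus_encoding",
                                  "choice_encoding"}
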