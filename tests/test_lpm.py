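"""Joint model, margin-ranking loss, and training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import log_softmax
from scipy.stats import spearmanr

import lossgate as lg
from lossgate.lpm import NotTrainedError


finite_loss = st.floats(0.0, 10.0, allow_nan=False)
pred_loss = st.floats(-20.0, 20.0, allow_nan=False)


class TestMarginRankingLoss:
    @pytest.mark.parametrize(
        "l, lhat, eps, expected",
        [
            # correct order with gap >= margin -> hinge inactive
            ([0.8, 0.2], [2.0, 0.5], 1.0, 0.0),
            # wrong order -> max(0, -(+1)*(-0.4) + 1) = 1.4
            ([0.8, 0.2], [0.1, 0.5], 1.0, 1.4),
            # mean over two pairs: (1.4 + 0) / 2
            ([0.8, 0.2, 0.8, 0.2], [0.1, 0.5, 2.0, 0.5], 1.0, 0.7),
        ],
    )
    def test_worked_examples(self, l, lhat, eps, expected):
        assert lg.margin_ranking_loss(l, lhat, eps) == pytest.approx(expected)

    def test_odd_batch_rejected(self):
        with pytest.raises(ValueError):
            lg.margin_ranking_loss([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])

    @settings(derandomize=True, max_examples=200)
    @given(
        l=st.lists(finite_loss, min_size=2, max_size=12).filter(lambda x: len(x) % 2 == 0),
        lhat=st.lists(pred_loss, min_size=2, max_size=12).filter(lambda x: len(x) % 2 == 0),
        eps=st.floats(0.1, 3.0),
    )
    def test_zero_iff_sign_correct_with_margin(self, l, lhat, eps):
        n = min(len(l), len(lhat)) // 2 * 2
        l, lhat = np.array(l[:n]), np.array(lhat[:n])
        loss = lg.margin_ranking_loss(l, lhat, eps)
        assert loss >= 0.0
        pairs_ok = all(
            (1.0 if l[i] > l[i + 1] else -1.0) * (lhat[i] - lhat[i + 1]) >= eps
            for i in range(0, n, 2)
        )
        assert (loss == 0.0) == pairs_ok

    @settings(derandomize=True, max_examples=100)
    @given(
        l=st.lists(finite_loss, min_size=4, max_size=4),
        lhat=st.lists(st.floats(-5, 5), min_size=4, max_size=4),
        shift=st.floats(-100, 100),
    )
    def test_shift_invariance(self, l, lhat, shift):
        a = lg.margin_ranking_loss(l, lhat, 1.0)
        b = lg.margin_ranking_loss(l, np.array(lhat) + shift, 1.0)
        assert a == pytest.approx(b, abs=1e-6)


class TestJointLoss:
    def test_worked_examples(self):
        uniform_ce = np.log(3.0)
        assert lg.joint_loss([uniform_ce] * 4, 0.0, 1.0) == pytest.approx(1.0986, abs=1e-4)
        assert lg.joint_loss([0.5, 0.5], 0.4, 1.0) == pytest.approx(0.9)

    def test_lambda_zero_degenerates_to_target(self):
        for rank in (0.0, 3.7, 100.0):
            assert lg.joint_loss([0.2, 0.8], rank, 0.0) == pytest.approx(0.5)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Hand-written backprop against central differences on a tiny model."""
        model = lg.JointModel(patch_size=8, stem_cell=4, seed=0)
        model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(4, 8, 8, 3))
        y = np.array([0, 1, 2, 0])
        _, _, _, _, _, grads = model._loss_and_grads(X, y)
        eps = 1e-5
        for name in ("Ws0", "Wcls", "Wlpm", "Wt2", "bs1", "blpm"):
            w = model.params[name]
            flat = w.ravel()
            for k in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                up, *_ = model._loss_and_grads(X, y)
                flat[k] = orig - eps
                dn, *_ = model._loss_and_grads(X, y)
                flat[k] = orig
                num = (up - dn) / (2 * eps)
                assert grads[name].ravel()[k] == pytest.approx(num, rel=1e-4, abs=1e-7), name

    def test_lambda_zero_backbone_independent_of_lpm(self):
        """With lambda = 0 the ranking loss must not touch the backbone."""
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(20, 32, 32, 3))
        y = rng.integers(0, 3, size=20)
        cfg = lg.TrainConfig(epochs=2, lam=0.0, seed=7)
        m1 = lg.JointModel(seed=3, lam=0.0)
        m2 = lg.JointModel(seed=3, lam=0.0)
        m2.params["Wlpm"] += 0.5  # perturb only the LPM head
        lg.train_joint(m1, X, y, cfg)
        lg.train_joint(m2, X, y, cfg)
        for k in m1.params:
            if k.startswith(("Ws", "bs", "Wcls", "bcls")):
                np.testing.assert_array_equal(m1.params[k], m2.params[k])


class TestTraining:
    def test_deterministic_under_seed(self, small_corpus):
        clean = [p.id for p in small_corpus.patches if p.noise_type == "none"][:50]
        X, y = small_corpus.images(clean), small_corpus.labels(clean)
        cfg = lg.TrainConfig(epochs=2, seed=11)
        m1, t1 = lg.train_joint(lg.JointModel(seed=11), X, y, cfg)
        m2, t2 = lg.train_joint(lg.JointModel(seed=11), X, y, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])
        np.testing.assert_array_equal(
            t1.records[-1].true_losses, t2.records[-1].true_losses
        )

    def test_empty_labeled_set_rejected(self):
        with pytest.raises(ValueError):
            lg.train_joint(
                lg.JointModel(), np.empty((0, 32, 32, 3)), np.empty(0, int), lg.TrainConfig()
            )

    def test_learns_task_and_ranks_losses(self):
        """A modest fit reaches high accuracy and a positive loss-rank signal."""
        corpus = lg.generate_corpus(lg.CorpusSpec(n_clean_per_class=150, seed=21))
        clean = [
            p.id for p in corpus.patches if p.split == "pool" and p.noise_type == "none"
        ]
        rng = np.random.default_rng(4)
        ids = sorted(rng.choice(clean, 300, replace=False))
        model, _ = lg.train_joint(
            lg.JointModel(seed=6),
            corpus.images(ids),
            corpus.labels(ids),
            lg.TrainConfig(seed=6),
        )
        test_ids = corpus.test_ids
        probs = model.predict_proba(corpus.images(test_ids))
        acc = np.mean(np.argmax(probs, axis=1) == corpus.labels(test_ids))
        assert acc > 0.8

        held = sorted(set(clean) - set(ids))
        logits, lhat, _ = model.forward(corpus.images(held))
        ce = -log_softmax(logits.astype(float), axis=1)[
            np.arange(len(held)), corpus.labels(held)
        ]
        trained_rho = spearmanr(lhat, ce).statistic
        assert trained_rho > 0

        # an untrained LPM carries no comparable signal
        fresh = lg.JointModel(seed=99)
        _, lhat0, _ = fresh.forward(corpus.images(held))
        assert trained_rho > abs(spearmanr(lhat0, ce).statistic)


class TestPredictLosses:
    def test_eval_mode_deterministic_and_order_preserving(self, trained_small, small_corpus):
        model, _, _ = trained_small
        ids = small_corpus.pool_ids[:17]
        X = small_corpus.images(ids)
        c1, l1 = lg.predict_losses(model, X)
        c2, l2 = lg.predict_losses(model, X)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(l1, l2)
        assert len(c1) == len(l1) == 17
        # order preserved: reversing inputs reverses outputs
        c3, l3 = lg.predict_losses(model, np.ascontiguousarray(X[::-1]))
        np.testing.assert_allclose(l3, l1[::-1], rtol=1e-5)

    def test_predicted_losses_finite_and_nonnegative(self, trained_small):
        model, _, _ = trained_small
        zeros = np.zeros((3, 32, 32, 3))
        _, lhat = lg.predict_losses(model, zeros)
        assert np.all(np.isfinite(lhat)) and np.all(lhat >= 0.0)

    def test_untrained_model_flagged(self):
        with pytest.raises(NotTrainedError):
            lg.predict_losses(lg.JointModel(), np.zeros((1, 32, 32, 3)))
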