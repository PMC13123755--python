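"""Neural core and estimators: gradients, parameter counts, seeding,
MDN algebra, tokenizer contracts, and the classical baselines."""

import numpy as np
import pytest

from surgdur._autograd import Tensor, concat, logsumexp
from surgdur.models import (
    MDNParams,
    MLMDNRegressor,
    MultiheadMLPRegressor,
    SingleHeadMLPRegressor,
    Tokenizer,
    baselines_fit_predict,
    make_baseline,
    mdn_nll_value,
    mdn_point,
)
from surgdur.nn import LOG_2PI


class TestAutograd:
    def test_numeric_gradient_of_composite_expression(self, rng):
        """Backprop gradients match central finite differences."""
        x0 = rng.normal(size=(4, 3))
        w0 = rng.normal(size=(3, 2))

        def f(xv, wv):
            x, w = Tensor(xv, requires_grad=True), Tensor(wv, requires_grad=True)
            h = (x @ w).tanh().relu()
            z = concat([h, h * h], axis=1)
            out = (z.sigmoid().log() * -1.0).mean() + (x * x).sum() * 0.01
            return out, x, w

        out, x, w = f(x0, w0)
        out.backward()
        eps = 1e-6
        for arr, grad in ((x0, x.grad), (w0, w.grad)):
            flat = arr.ravel()
            for idx in range(0, flat.size, 2):
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = f(x0, w0)[0].data
                flat[idx] = orig - eps
                lo = f(x0, w0)[0].data
                flat[idx] = orig
                num = (hi - lo) / (2 * eps)
                assert grad.ravel()[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_logsumexp_matches_numpy(self, rng):
        x = rng.normal(size=(5, 4))
        t = Tensor(x, requires_grad=True)
        out = logsumexp(t, axis=1)
        ref = np.log(np.exp(x).sum(axis=1))
        assert np.allclose(out.data, ref)
        out.sum().backward()
        soft = np.exp(x - ref[:, None])
        assert np.allclose(t.grad, soft)


class TestArchitecture:
    def test_parameter_counts_match_closed_form(self):
        d_tab, d_text = 50, 1024
        model = MultiheadMLPRegressor(seed=0)
        model._build(d_tab, d_text, np.random.default_rng(0))
        assert model.tab_head_.layers[0].n_params == 50 * 256 + 256  # = 13056
        assert model.text_head_.layers[0].n_params == 1024 * 256 + 256  # = 262400
        closed = (
            (d_tab * 256 + 256) + (256 * 128 + 128)
            + (d_text * 256 + 256) + (256 * 128 + 128)
            + (256 * 64 + 64)  # fusion input = 128 + 128
            + (64 * 1 + 1)
        )
        assert model.n_parameters_ == closed

    def test_fusion_consumes_both_branch_outputs(self):
        model = MultiheadMLPRegressor(seed=0)
        model._build(10, 1024, np.random.default_rng(0))
        assert model.fusion_.W.data.shape[0] == 128 + 128

    def test_nonpositive_dimension_rejected(self):
        model = MultiheadMLPRegressor(seed=0)
        with pytest.raises(ValueError):
            model._build(0, 1024, np.random.default_rng(0))

    def test_forward_is_deterministic_with_dropout_off(self, rng):
        model = MultiheadMLPRegressor(seed=0, max_epochs=2,
                                      validation_fraction=0.0)
        X = (rng.normal(size=(20, 5)), rng.normal(size=(20, 8)))
        y = rng.normal(size=20)
        model.fit(X, y)
        a = model.predict(X)
        b = model.predict(X)
        assert np.array_equal(a, b)


class TestTraining:
    def test_same_seed_reproduces_epoch1_loss(self, rng):
        X = (rng.normal(size=(64, 6)), rng.normal(size=(64, 10)))
        y = rng.normal(size=64)
        h1 = MultiheadMLPRegressor(seed=7, max_epochs=1).fit(X, y).history_
        h2 = MultiheadMLPRegressor(seed=7, max_epochs=1).fit(X, y).history_
        assert h1.train_loss[0] == h2.train_loss[0]

    def test_zero_target_converges_to_zero(self, rng):
        X = (rng.normal(size=(80, 4)), rng.normal(size=(80, 6)))
        y = np.zeros(80)
        model = MultiheadMLPRegressor(seed=0, max_epochs=30, dropout_rate=0.0,
                                      validation_fraction=0.0)
        model.fit(X, y)
        assert model.history_.train_loss[-1] < 1e-3
        assert np.max(np.abs(model.predict(X))) < 0.5

    def test_early_stopping_restores_best_epoch(self, rng):
        X = (rng.normal(size=(60, 4)), rng.normal(size=(60, 4)))
        y = rng.normal(size=60)
        model = MultiheadMLPRegressor(seed=0, max_epochs=200, patience=5)
        model.fit(X, y)
        assert len(model.history_.train_loss) < 200
        assert model.history_.best_epoch >= 0


class TestSingleHead:
    def test_input_width_follows_mode(self, small_features):
        _, bundle = small_features
        d_tab = bundle.tabular.shape[1]
        m_tab = SingleHeadMLPRegressor(seed=0, max_epochs=1).fit(
            bundle.tabular, bundle.y_min)
        assert m_tab.stack_.layers[0].W.data.shape[0] == d_tab
        m_cat = SingleHeadMLPRegressor(seed=0, max_epochs=1).fit(
            bundle.concat_matrix(), bundle.y_min)
        assert m_cat.stack_.layers[0].W.data.shape[0] == d_tab + 1024


class TestMDN:
    def test_expectation_weighted_mean(self):
        assert mdn_point(np.array([0.5, 0.5]), np.array([10.0, 20.0])) == 15.0
        assert mdn_point(np.array([1.0, 0.0]), np.array([7.0, 99.0])) == 7.0

    def test_point_is_linear_in_mu(self, rng):
        alpha = np.full((5, 3), 1 / 3)
        mu1, mu2 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        lhs = mdn_point(alpha, 2.0 * mu1 + mu2)
        rhs = 2.0 * mdn_point(alpha, mu1) + mdn_point(alpha, mu2)
        assert np.allclose(lhs, rhs)

    def test_single_gaussian_nll_closed_form(self):
        y = np.array([1.7])
        nll = mdn_nll_value(np.array([[1.0]]), np.array([[1.7]]), np.array([[1.0]]), y)
        assert nll == pytest.approx(0.5 * LOG_2PI)

    def test_params_validate_simplex_and_positivity(self):
        with pytest.raises(ValueError):
            MDNParams(alpha=np.array([[0.7, 0.7]]), mu=np.zeros((1, 2)),
                      sigma=np.ones((1, 2)))
        with pytest.raises(ValueError):
            MDNParams(alpha=np.array([[0.5, 0.5]]), mu=np.zeros((1, 2)),
                      sigma=np.array([[1.0, -1.0]]))

    def test_forward_produces_valid_mixture_for_random_inputs(self, rng):
        model = MLMDNRegressor(seed=0, max_epochs=1, validation_fraction=0.0)
        X = rng.normal(size=(40, 3))
        model.fit(X, rng.normal(size=40), texts=["alpha beta"] * 40)
        p = model.predict_params(X, texts=["beta gamma"] * 40)
        assert np.allclose(p.alpha.sum(axis=1), 1.0, atol=1e-9)
        assert (p.sigma > 0).all()
        assert np.allclose(p.point(), (p.alpha * p.mu).sum(axis=1))


class TestTokenizer:
    def test_padding_to_fixed_length(self):
        tok = Tokenizer(max_len=10).fit(["one two three"])
        seq = tok.transform(["one two three"])[0]
        assert len(seq) == 10
        assert (seq[3:] == Tokenizer.PAD).all()
        assert (seq[:3] != Tokenizer.PAD).all()

    def test_out_of_vocabulary_maps_to_unknown(self):
        tok = Tokenizer(max_len=4).fit(["known words only"])
        seq = tok.transform(["unseen token"])[0]
        assert seq[0] == Tokenizer.UNK and seq[1] == Tokenizer.UNK

    def test_empty_training_text_rejected(self):
        with pytest.raises(ValueError):
            Tokenizer().fit(["", "   "])


class TestMLMDNEndToEnd:
    def test_fit_on_small_cohort_returns_finite_nll(self, small_cohort, small_features):
        feat, bundle = small_features
        texts = [r.note for r in small_cohort.records]
        model = MLMDNRegressor(seed=0, max_epochs=3)
        model.fit(bundle.tabular[:200], bundle.y_min[:200], texts=texts[:200])
        assert np.isfinite(model.history_.train_loss).all()
        pred = model.predict(bundle.tabular[200:], texts=texts[200:])
        assert pred.shape == (100,)
        assert np.isfinite(pred).all()


class TestBaselines:
    def test_mean_baseline_predicts_training_mean(self, rng):
        Xtr, Xte = rng.normal(size=(30, 4)), rng.normal(size=(10, 4))
        y_std = rng.normal(size=30)
        stats = (40.0, 10.0)
        pred = baselines_fit_predict("mean", Xtr, y_std, Xte, stats)
        assert np.allclose(pred, y_std.mean() * 10.0 + 40.0)

    def test_ridge_recovers_noiseless_linear_target(self, rng):
        X = rng.normal(size=(200, 5))
        beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y_std = X @ beta
        pred = baselines_fit_predict("ridge", X, y_std, X, (0.0, 1.0))
        assert np.mean(np.abs(pred - y_std)) < 0.05

    def test_all_names_run_end_to_end(self, small_features):
        feat, bundle = small_features
        X = bundle.concat_matrix()[:200]
        Xte = bundle.concat_matrix()[200:]
        for name in ("ridge", "tree", "svr", "forest", "gbm", "mean"):
            pred = baselines_fit_predict(name, X, bundle.y_std[:200], Xte,
                                         feat.schema_.target_stats)
            assert pred.shape == (bundle.n - 200,)
            assert np.isfinite(pred).all()

    def test_unknown_name_lists_options(self):
        with pytest.raises(ValueError, match="ridge"):
            make_baseline("nope")
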