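import numpy as np
import pytest

from ghostcyto.cnn import (
    CnnConfig,
    _BatchNorm1d,
    _Conv1d,
    _MaxPool1d,
    build_cnn,
    crossfold_eval,
    evaluate_multiclass,
    predict_cnn,
    train_cnn,
)
from ghostcyto.signal_chain import Event


def _wf_event(i, waveforms, scalars, cls):
    return Event(
        event_id=i,
        waveforms={m: np.asarray(w, float) for m, w in waveforms.items()},
        scalars=scalars,
        fluorescence={},
        true_class=cls,
    )


def _template_events(n_per_class, n_classes=3, length=64, noise=0.05, seed=0):
    """Separable classes: each has a distinct deterministic waveform template."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 4 * np.pi, length)
    templates = [np.sin(t * (k + 1)) + k for k in range(n_classes)]
    events = []
    for k in range(n_classes):
        for _ in range(n_per_class):
            wf = templates[k] + rng.normal(0, noise, length)
            events.append(
                _wf_event(len(events), {"dGMI": wf},
                          {"fsc_area": float(k + rng.normal(0, noise)), "bsc": 0.0},
                          f"class{k}")
            )
    return events


def _small_config(n_classes=3, **kw):
    defaults = dict(
        waveform_modalities=("dGMI",), scalar_features=("fsc_area", "bsc"),
        n_classes=n_classes, channels=(4, 4, 8, 8, 8), fc_width=16,
        learning_rate=1e-3, batch_size=64, max_epochs=60, patience=15, seed=0,
    )
    defaults.update(kw)
    return CnnConfig(**defaults)


class TestBuild:
    def test_layer_census(self):
        model = build_cnn(_small_config(), segment_length=128)
        names = [type(l).__name__ for l in model.trunk]
        assert names.count("_Conv1d") == 5
        assert names.count("_BatchNorm1d") == 5
        assert names.count("_ReLU") == 5
        assert names.count("_MaxPool1d") == 5
        assert model.fc is not None and model.head is not None

    def test_temporal_length_after_five_poolings(self):
        model = build_cnn(_small_config(), segment_length=128)
        # 128 / 2^5 = 4 temporal samples enter the flatten
        assert model.flat_dim == model.config.channels[-1] * 4

    def test_scalar_concatenation_widens_fc_input(self):
        cfg = _small_config()
        model = build_cnn(cfg, segment_length=128)
        assert model.fc.w.shape[0] == model.flat_dim + len(cfg.scalar_features)

    def test_pool_exhaustion_names_layer(self):
        with pytest.raises(ValueError, match="layer"):
            build_cnn(_small_config(), segment_length=16)

    def test_five_conv_layers_enforced(self):
        with pytest.raises(ValueError):
            _small_config(channels=(4, 4, 4)).validate()


class TestGradients:
    """Finite-difference checks of the hand-written backward passes."""

    def _num_grad(self, f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            x[idx] += eps
            fp = f()
            x[idx] -= 2 * eps
            fm = f()
            x[idx] += eps
            g[idx] = (fp - fm) / (2 * eps)
        return g

    def test_conv_backward(self):
        rng = np.random.default_rng(0)
        layer = _Conv1d(2, 3, 3, rng)
        x = rng.standard_normal((2, 2, 8))
        dy = rng.standard_normal((2, 3, 8))

        def loss():
            return float((layer.forward(x, True) * dy).sum())

        loss()
        dx = layer.backward(dy)
        np.testing.assert_allclose(dx, self._num_grad(loss, x), atol=1e-5)
        np.testing.assert_allclose(layer.dw, self._num_grad(loss, layer.w), atol=1e-5)

    def test_batchnorm_backward(self):
        rng = np.random.default_rng(1)
        layer = _BatchNorm1d(3)
        layer.gamma = rng.standard_normal(3)
        x = rng.standard_normal((4, 3, 5))
        dy = rng.standard_normal((4, 3, 5))

        def loss():
            return float((layer.forward(x, True) * dy).sum())

        loss()
        dx = layer.backward(dy)
        np.testing.assert_allclose(dx, self._num_grad(loss, x), atol=1e-4)

    def test_maxpool_backward_routes_to_argmax(self):
        layer = _MaxPool1d(2)
        x = np.array([[[1.0, 3.0, 2.0, 0.0]]])
        layer.forward(x, True)
        dx = layer.backward(np.array([[[1.0, 1.0]]]))
        np.testing.assert_array_equal(dx, [[[0.0, 1.0, 1.0, 0.0]]])


class TestTrainPredict:
    def test_separable_templates_reach_perfect_f1(self):
        events = _template_events(40, seed=2)
        model = train_cnn(events[::2], events[1::2], _small_config())
        _, pred = predict_cnn(model, events[1::2])
        truth = np.array([e.true_class for e in events[1::2]], dtype=object)
        assert evaluate_multiclass(pred, truth).macro_f1 == 1.0

    def test_early_stopping_fires_on_stagnant_loss(self):
        # labels shuffled: the validation loss cannot keep improving, so the
        # patience rule must stop training well before max_epochs
        events = _template_events(20, seed=3)
        rng = np.random.default_rng(0)
        labels = np.array([e.true_class for e in events], dtype=object)
        permuted = labels[rng.permutation(labels.size)]
        cfg = _small_config(max_epochs=500, patience=8)
        model = train_cnn(events[::2], events[1::2], cfg,
                          train_labels=permuted[::2], val_labels=permuted[1::2])
        assert len(model.history["val_loss"]) < cfg.max_epochs
        assert model.best_epoch is not None
        assert model.best_epoch <= len(model.history["val_loss"]) - 1

    def test_probabilities_normalized_and_deterministic(self):
        events = _template_events(10, seed=4)
        model = train_cnn(events[::2], events[1::2], _small_config(max_epochs=20, patience=5))
        probs, pred = predict_cnn(model, events[:4])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        probs2, pred2 = predict_cnn(model, events[:4])
        np.testing.assert_array_equal(probs, probs2)
        np.testing.assert_array_equal(pred, pred2)

    def test_uniform_logits_tie_break_to_first_class(self):
        events = _template_events(4, seed=5)
        model = build_cnn(_small_config(), segment_length=64)
        model.classes = ("a", "b", "c")
        model.wf_mean, model.wf_std = np.zeros(1), np.ones(1)
        model.sc_mean, model.sc_std = np.zeros(2), np.ones(2)
        model.head.w[:] = 0.0
        model.head.b[:] = 0.0
        _, pred = predict_cnn(model, events[:3])
        assert all(p == "a" for p in pred)

    def test_missing_class_in_training_rejected(self):
        events = _template_events(10, n_classes=2, seed=6)
        with pytest.raises(ValueError):
            train_cnn(events[::2], events[1::2], _small_config(n_classes=3))

    def test_concat_after_fc_variant_trains(self):
        events = _template_events(20, seed=7)
        cfg = _small_config(concat_mode="after_fc", max_epochs=40)
        model = train_cnn(events[::2], events[1::2], cfg)
        _, pred = predict_cnn(model, events[1::2])
        truth = np.array([e.true_class for e in events[1::2]], dtype=object)
        assert evaluate_multiclass(pred, truth).macro_f1 > 0.9


def _macro_f1_oracle(cm):
    """Hand macro-F1 from a confusion matrix (rows true, cols predicted)."""
    f1s = []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        prec = tp / cm[:, k].sum() if cm[:, k].sum() else 0.0
        rec = tp / cm[k].sum() if cm[k].sum() else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return float(np.mean(f1s))


class TestEvaluateMulticlass:
    def test_perfect_predictions(self):
        truth = np.array(["a", "b", "c"] * 5, dtype=object)
        res = evaluate_multiclass(truth.copy(), truth)
        assert res.macro_f1 == 1.0
        assert np.all(res.confusion == np.diag(res.confusion.diagonal()))

    def test_binary_hand_value(self):
        # confusion [[8,2],[3,7]]: F1_0 = 0.762, F1_1 = 0.737, macro = 0.749
        truth = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        pred = np.array(["a"] * 8 + ["b"] * 2 + ["a"] * 3 + ["b"] * 7, dtype=object)
        res = evaluate_multiclass(pred, truth)
        np.testing.assert_array_equal(res.confusion, [[8, 2], [3, 7]])
        assert res.macro_f1 == pytest.approx(0.749, abs=5e-4)

    def test_never_predicted_class_scores_zero(self):
        truth = np.array(["a", "a", "b"], dtype=object)
        pred = np.array(["a", "a", "a"], dtype=object)
        res = evaluate_multiclass(pred, truth)
        assert res.per_class_f1[list(res.classes).index("b")] == 0.0

    def test_matches_hand_oracle_on_random_matrices(self):
        rng = np.random.default_rng(21)
        classes = ("x", "y", "z")
        for _ in range(20):
            cm = rng.integers(0, 6, size=(3, 3))
            truth, pred = [], []
            for i, ci in enumerate(classes):
                for j, cj in enumerate(classes):
                    truth += [ci] * int(cm[i, j])
                    pred += [cj] * int(cm[i, j])
            if not truth:
                continue
            res = evaluate_multiclass(
                np.array(pred, dtype=object), np.array(truth, dtype=object), classes=classes
            )
            assert res.macro_f1 == pytest.approx(_macro_f1_oracle(cm), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_multiclass(np.array([]), np.array([]))


class TestCrossfold:
    def test_fold_statistics_and_best_fold_contract(self):
        events = _template_events(30, seed=8)
        cfg = _small_config(max_epochs=30, patience=10)
        res = crossfold_eval(events, cfg, k=3)
        assert res.fold_f1s.shape == (3,)
        assert res.mean_f1 == pytest.approx(res.fold_f1s.mean())
        assert res.macro_f1 == pytest.approx(res.fold_f1s.max())
        assert res.mean_f1 > 0.95  # separable by construction

    def test_class_smaller_than_k_rejected(self):
        events = _template_events(4, seed=9)
        with pytest.raises(ValueError, match="fewer"):
            crossfold_eval(events, _small_config(), k=5)


def test_transfer_across_batches_and_batch_effect_dose_response():
    """Donor-transfer: with no batch effect, training on one simulated donor
    and testing on another costs little; a severe gain shift (x3) collapses
    the transferred macro F1."""
    from dataclasses import replace

    from ghostcyto import benchmarks
    from ghostcyto.cnn import _carve_validation, transfer_eval
    from ghostcyto.phantoms import BatchEffect, apply_batch_effect

    opt = benchmarks.wbc_optics()
    spec_a = benchmarks.wbc_like_spec(n_events=420, seed=31)
    spec_b = replace(benchmarks.wbc_like_spec(n_events=420, seed=32), batch_id="donor2")
    spec_c = apply_batch_effect(
        benchmarks.wbc_like_spec(n_events=420, seed=33), BatchEffect(gain_scale=3.0), "donor3"
    )
    ev_a, _ = benchmarks.simulate_benchmark(spec_a, opt, seed=31)
    ev_b, _ = benchmarks.simulate_benchmark(spec_b, opt, seed=32)
    ev_c, _ = benchmarks.simulate_benchmark(spec_c, opt, seed=33)

    cfg = replace(
        benchmarks.wbc_cnn_config(seed=0),
        channels=(4, 8, 16, 16, 16), fc_width=32, max_epochs=80, patience=15,
    )
    intra, inter = transfer_eval(ev_a, ev_b, cfg)
    assert inter > intra - 0.15  # exchangeable donors transfer cheaply

    lab_a = np.array([e.true_class for e in ev_a], dtype=object)
    va_ev, va_lab, tr_ev, tr_lab = _carve_validation(ev_a, lab_a, seed=13)
    model = train_cnn(tr_ev, va_ev, cfg, tr_lab, va_lab)
    _, pred_c = predict_cnn(model, ev_c)
    truth_c = np.array([e.true_class for e in ev_c], dtype=object)
    f1_c = evaluate_multiclass(pred_c, truth_c, classes=model.classes).macro_f1
    assert f1_c < intra - 0.1
    assert f1_c < inter - 0.1
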