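import numpy as np
import pytest

from conftest import mann_whitney_auc
from ghostcyto.signal_chain import Event
from ghostcyto.svm import (
    RocCurve,
    SvmConfig,
    estimate_throughput,
    export_linear_scorer,
    featurize,
    mean_roc,
    recovery_at_fpr,
    repeated_eval,
    roc_auc,
    simulate_sort,
    svm_score,
    train_svm,
)


def _scalar_event(i, x, y, cls):
    return Event(
        event_id=i, waveforms={},
        scalars={"fsc_area": float(x), "ssc": float(y)},
        fluorescence={}, true_class=cls,
    )


def _blob_events(n_per_class, sep, seed=0):
    """Two Gaussian blobs in the FSC/SSC plane, `sep` sigmas apart."""
    rng = np.random.default_rng(seed)
    events, labels = [], []
    for cls, mu in (("neg", 0.0), ("pos", sep)):
        for _ in range(n_per_class):
            x, y = rng.normal(mu, 1.0, size=2)
            events.append(_scalar_event(len(events), x, y, cls))
            labels.append(cls)
    return events, np.array(labels, dtype=object)


def _waveform_event(i, wf, cls):
    return Event(
        event_id=i, waveforms={"dGMI": np.asarray(wf, float), "ssGMI": np.asarray(wf, float)},
        scalars={"fsc_area": 1.0, "ssc": 2.0, "bsc": 3.0, "fsc_height": 0.0, "fsc_width": 0.0},
        fluorescence={}, true_class=cls,
    )


class TestFeaturize:
    def test_single_waveform_dimension(self):
        ev = _waveform_event(0, np.zeros(128), "a")
        assert featurize([ev], ("dGMI",)).shape == (1, 128)

    def test_waveforms_plus_scalars_dimension(self):
        ev = _waveform_event(0, np.zeros(128), "a")
        X = featurize([ev], ("dGMI", "ssGMI", "fsc_area", "ssc"))
        assert X.shape == (1, 258)

    def test_scalar_only_baseline_dimension(self):
        ev = _waveform_event(0, np.zeros(4), "a")
        assert featurize([ev], ("fsc_area", "ssc")).shape == (1, 2)

    def test_missing_modality_rejected(self):
        with pytest.raises(KeyError):
            featurize([_scalar_event(0, 1, 2, "a")], ("dGMI",))


class TestTrainSvm:
    def test_separable_blobs_reach_perfect_training_auc(self):
        events, labels = _blob_events(50, sep=8.0)
        cfg = SvmConfig(kernel="linear", modality_set=("fsc_area", "ssc"),
                        gamma_grid=(), inner_folds=3, seed=0)
        model = train_svm(events, labels, cfg)
        _, auc = roc_auc(svm_score(model, events), labels, positive_class="pos")
        assert auc == 1.0

    def test_permuted_labels_give_chance_auc(self):
        events, labels = _blob_events(200, sep=8.0, seed=1)
        rng = np.random.default_rng(5)
        permuted = labels[rng.permutation(labels.size)]
        cfg = SvmConfig(kernel="linear", modality_set=("fsc_area", "ssc"),
                        gamma_grid=(), inner_folds=3, seed=0)
        model = train_svm(events[:300], permuted[:300], cfg)
        _, auc = roc_auc(svm_score(model, events[300:]), permuted[300:], "pos")
        assert 0.4 <= auc <= 0.6

    def test_hyperparameter_choice_is_deterministic(self):
        events, labels = _blob_events(40, sep=2.0, seed=2)
        cfg = SvmConfig(kernel="rbf", modality_set=("fsc_area", "ssc"), inner_folds=3, seed=7)
        m1 = train_svm(events, labels, cfg)
        m2 = train_svm(events, labels, cfg)
        assert (m1.C, m1.gamma) == (m2.C, m2.gamma)

    def test_single_class_rejected(self):
        events, _ = _blob_events(10, sep=1.0)
        labels = np.array(["same"] * len(events), dtype=object)
        with pytest.raises(ValueError):
            train_svm(events, labels, SvmConfig(kernel="linear", modality_set=("fsc_area", "ssc")))

    def test_normalizer_is_fitted_on_training_data_only(self):
        events, labels = _blob_events(50, sep=3.0, seed=3)
        cfg = SvmConfig(kernel="linear", modality_set=("fsc_area", "ssc"),
                        gamma_grid=(), inner_folds=3)
        model = train_svm(events[:60], labels[:60], cfg)
        train_mean = featurize(events[:60], ("fsc_area", "ssc")).mean(axis=0)
        np.testing.assert_allclose(model.scaler.mean_, train_mean, rtol=1e-12)
        full_mean = featurize(events, ("fsc_area", "ssc")).mean(axis=0)
        assert not np.allclose(model.scaler.mean_, full_mean)


class TestRocAuc:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array(["p", "p", "n", "n"], dtype=object)
        _, auc = roc_auc(scores, labels, positive_class="p")
        assert auc == 1.0

    def test_half_the_pairs_ordered(self):
        scores = np.array([0.8, 0.2, 0.6, 0.4])
        labels = np.array(["p", "p", "n", "n"], dtype=object)
        _, auc = roc_auc(scores, labels, positive_class="p")
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_tie_counts_one_half(self):
        _, auc = roc_auc(np.array([0.5, 0.5]), np.array(["p", "n"], dtype=object), "p")
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n_pos, n_neg = rng.integers(2, 20, size=2)
            # quantize so ties actually occur
            pos = np.round(rng.random(n_pos), 1)
            neg = np.round(rng.random(n_neg), 1)
            scores = np.concatenate([pos, neg])
            labels = np.array(["p"] * n_pos + ["n"] * n_neg, dtype=object)
            _, auc = roc_auc(scores, labels, positive_class="p")
            assert auc == pytest.approx(mann_whitney_auc(pos, neg), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array(["p", "p"], dtype=object))


class TestMeanRocRecovery:
    def test_recovery_interpolates_toy_curve(self):
        roc = RocCurve(fpr=np.array([0.0, 0.01, 1.0]), tpr=np.array([0.0, 0.6, 1.0]))
        assert recovery_at_fpr(roc, 0.01) == pytest.approx(0.6)
        assert recovery_at_fpr(roc, 0.505) == pytest.approx(0.8)  # midpoint by hand

    def test_averaging_curve_with_itself(self):
        roc = RocCurve(fpr=np.array([0.0, 0.3, 1.0]), tpr=np.array([0.0, 0.9, 1.0]))
        avg = mean_roc([roc, roc], fpr_grid=np.array([0.0, 0.15, 0.3, 1.0]))
        np.testing.assert_allclose(avg.tpr, [0.0, 0.45, 0.9, 1.0])

    def test_recovery_endpoints(self):
        roc = RocCurve(fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]))
        assert recovery_at_fpr(roc, 1.0) == 1.0
        with pytest.raises(ValueError):
            recovery_at_fpr(roc, 1.5)

    def test_empty_roc_list_rejected(self):
        with pytest.raises(ValueError):
            mean_roc([])


class TestRepeatedEval:
    def _config(self, n=20):
        return SvmConfig(kernel="linear", modality_set=("fsc_area", "ssc"),
                         gamma_grid=(), inner_folds=2, C_grid=(1.0,),
                         n_trials=3, n_train_per_class=n, n_test_per_class=n, seed=0)

    def test_degenerate_features_give_chance(self):
        events = [_scalar_event(i, 1.0, 1.0, "a" if i % 2 else "b") for i in range(120)]
        labels = np.array([e.true_class for e in events], dtype=object)
        res = repeated_eval(events, labels, self._config())
        assert abs(res.mean_auc - 0.5) < 0.15

    def test_separated_classes_give_perfect_auc(self):
        events, labels = _blob_events(60, sep=12.0, seed=4)
        res = repeated_eval(events, labels, self._config())
        assert res.mean_auc == 1.0
        assert res.std_auc == 0.0
        assert res.auc_of_mean_roc == pytest.approx(1.0, abs=1e-9)


class TestSort:
    def _events(self, classes):
        return [_scalar_event(i, 0, 0, c) for i, c in enumerate(classes)]

    def test_perfect_scorer_reaches_full_purity(self):
        events = self._events(["t", "t", "o", "o"])
        rep = simulate_sort(events, None, 0.0, "t", scores=np.array([2.0, 3.0, -1.0, -2.0]))
        assert rep.purity == 1.0 and rep.sort_yield == 1.0

    def test_counting_case(self):
        events = self._events(["t", "t", "o", "t"])
        rep = simulate_sort(events, None, 0.0, "t", scores=np.array([1.0, 1.0, 1.0, -1.0]))
        assert rep.purity == pytest.approx(2 / 3)

    def test_keep_everything_recovers_presort_fraction(self):
        events = self._events(["t", "o", "o", "o"])
        rep = simulate_sort(events, None, -np.inf, "t", scores=np.zeros(4))
        assert rep.purity == pytest.approx(rep.pre_fraction) == pytest.approx(0.25)
        assert rep.sort_yield == 1.0

    def test_nothing_kept_reports_undefined_purity(self):
        events = self._events(["t", "o"])
        rep = simulate_sort(events, None, 10.0, "t", scores=np.zeros(2))
        assert rep.purity is None


class TestExportScorer:
    def test_exported_weights_reproduce_scores(self):
        events, labels = _blob_events(50, sep=4.0, seed=6)
        cfg = SvmConfig(kernel="linear", modality_set=("fsc_area", "ssc"),
                        gamma_grid=(), inner_folds=3)
        model = train_svm(events, labels, cfg)
        w, b = export_linear_scorer(model)
        assert w.shape == (2,)
        X = featurize(events, ("fsc_area", "ssc"))
        np.testing.assert_allclose(X @ w + b, svm_score(model, events), atol=1e-9)

    def test_rbf_model_not_exportable(self):
        events, labels = _blob_events(30, sep=4.0, seed=7)
        cfg = SvmConfig(kernel="rbf", modality_set=("fsc_area", "ssc"),
                        C_grid=(1.0,), gamma_grid=(0.1,), inner_folds=2)
        with pytest.raises(ValueError, match="linear"):
            export_linear_scorer(train_svm(events, labels, cfg))


class TestThroughput:
    @pytest.mark.parametrize("t, rate", [(100e-6, 10_000.0), (1.0, 1.0), (50e-6, 20_000.0)])
    def test_reciprocal(self, t, rate):
        assert estimate_throughput(t) == pytest.approx(rate)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            estimate_throughput(0.0)
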