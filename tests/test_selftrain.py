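import logging

import numpy as np
import pytest

from comention.models import Prediction, TrainConfig, ensemble_predict
from comention.preprocessing import EncodedExample, PreprocessConfig, Preprocessor
from comention.selftrain import (
    PseudoLabeledSet,
    SelfTrainConfig,
    choose_added_size,
    run_pipeline,
    select_pseudolabels,
    train_ensemble,
)
from comention.synthetic import SynthConfig, generate_dataset

SMALL_NN = dict(embedding_dim=24, cnn_filters_per_width=16, rnn_hidden_size=32, epochs_cnn_rnn=6)


def _pred(pos):
    return Prediction(probs=(1.0 - pos, pos), predicted_class=1 if pos > 0.5 else 0, confidence=pos)


def _examples(n):
    return [EncodedExample(ids=(2, 3, 0, 0)) for _ in range(n)]


def _encode_all(ds, max_len=40):
    pre = Preprocessor(ds.proteins, ds.phenotypes, PreprocessConfig(max_len=max_len))
    pre.fit_vocab(ds.labeled)
    return pre.encode(ds.labeled), pre.encode(ds.unlabeled), pre.encode(ds.test)


class TestSelectPseudolabels:
    def test_threshold_forces_selection(self):
        pool = _examples(3)
        preds = [_pred(0.99), _pred(0.95), _pred(0.60)]
        out = select_pseudolabels(pool, preds, k=2, cfg=SelfTrainConfig(class_ratio_policy="natural"))
        assert len(out) == 2
        assert set(out.pool_indices) == {0, 1}
        assert all(e.label == 1 for e in out.examples)

    def test_quota_preserves_labeled_ratio(self):
        pool = _examples(8)
        preds = [_pred(0.99)] * 4 + [_pred(0.01)] * 4
        out = select_pseudolabels(pool, preds, k=4, cfg=SelfTrainConfig(), labeled_positive_fraction=0.5)
        assert out.class_counts == {0: 2, 1: 2}

    def test_shortfall_takes_all_and_warns(self, caplog):
        pool = _examples(3)
        preds = [_pred(0.99), _pred(0.97), _pred(0.95)]
        with caplog.at_level(logging.WARNING):
            out = select_pseudolabels(pool, preds, k=10, cfg=SelfTrainConfig(class_ratio_policy="natural"))
        assert len(out) == 3
        assert out.shortfall
        assert "taking all" in caplog.text or "no backfill" in caplog.text or len(out) < 10

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            select_pseudolabels([], [], k=-1)

    def test_zero_candidates_empty_with_warning(self, caplog):
        pool = _examples(2)
        preds = [_pred(0.6), _pred(0.55)]
        with caplog.at_level(logging.WARNING):
            out = select_pseudolabels(pool, preds, k=5, cfg=SelfTrainConfig(class_ratio_policy="natural"))
        assert len(out) == 0
        assert "threshold" in caplog.text

    def test_no_selected_member_below_threshold_randomized(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            n = int(rng.integers(5, 60))
            pool = _examples(n)
            preds = [_pred(float(rng.random())) for _ in range(n)]
            tau = float(rng.uniform(0.55, 0.99))
            cfg = SelfTrainConfig(confidence_threshold=tau, class_ratio_policy="natural", seed=trial)
            out = select_pseudolabels(pool, preds, k=int(rng.integers(0, n)), cfg=cfg)
            for i in out.pool_indices:
                p = preds[i]
                assert p.probs[p.predicted_class] >= tau

    def test_deterministic_given_seed(self):
        pool = _examples(50)
        rng = np.random.default_rng(1)
        preds = [_pred(float(rng.uniform(0.9, 1.0))) for _ in range(50)]
        cfg = SelfTrainConfig(class_ratio_policy="natural", seed=3)
        a = select_pseudolabels(pool, preds, 10, cfg)
        b = select_pseudolabels(pool, preds, 10, cfg)
        assert a.pool_indices == b.pool_indices


class TestChooseAddedSize:
    def test_unlabeled_helps_returns_100(self):
        ds = generate_dataset(
            SynthConfig(n_labeled=60, n_unlabeled=600, n_test=200, signal_strength=0.9, label_noise=0.05, seed=5)
        )
        train, pool, val = _encode_all(ds)
        from comention.models import train_classifier

        base = train_classifier(train, "lightweight", TrainConfig(seed=0))
        cfg = SelfTrainConfig(candidate_added_sizes=(100,), default_k=100, selection_repeats=3, seed=0)
        k = choose_added_size(base, pool, train, val, cfg, TrainConfig(seed=0, **SMALL_NN), ensemble_kinds=("cnn",))
        assert k == 100

    def test_all_tied_returns_smallest(self):
        ds = generate_dataset(SynthConfig(n_labeled=40, n_unlabeled=50, n_test=20, seed=2))
        train, pool, test = _encode_all(ds)
        from comention.models import train_classifier

        base = train_classifier(train, "lightweight", TrainConfig(seed=0))
        # threshold 1.0: no candidates -> every arm trains on the same set -> exact tie
        cfg = SelfTrainConfig(confidence_threshold=1.0, candidate_added_sizes=(10, 20), default_k=10, seed=0)
        k = choose_added_size(base, pool, train, test, cfg, TrainConfig(seed=0, epochs_cnn_rnn=1, embedding_dim=8, cnn_filters_per_width=4), ensemble_kinds=("lightweight",))
        assert k == 0

    def test_empty_candidates_returns_zero(self):
        ds = generate_dataset(SynthConfig(n_labeled=40, n_unlabeled=10, n_test=10, seed=2))
        train, pool, test = _encode_all(ds)
        from comention.models import train_classifier

        base = train_classifier(train, "lightweight", TrainConfig(seed=0))
        cfg = SelfTrainConfig(candidate_added_sizes=(), default_k=0, seed=0)
        assert choose_added_size(base, pool, train, test, cfg) == 0


@pytest.fixture(scope="module")
def data():
    ds = generate_dataset(
        SynthConfig(n_labeled=100, n_unlabeled=400, n_test=100, signal_strength=0.9, label_noise=0.05, seed=9)
    )
    return _encode_all(ds)


class TestRunPipeline:

    def test_k0_identical_to_supervised_only(self, data):
        train, pool, test = data
        tcfg = TrainConfig(seed=13, **SMALL_NN)
        ens1, report = run_pipeline(train, [], pool, 0, SelfTrainConfig(seed=13), tcfg)
        ens2 = train_ensemble(train, ("cnn", "rnn"), tcfg)
        np.testing.assert_array_equal(ens1.predict_proba(test), ens2.predict_proba(test))
        assert report["expanded_size"] == len(train)

    def test_expanded_size_bookkeeping(self, data):
        train, pool, _ = data
        cfg = SelfTrainConfig(seed=1, candidate_added_sizes=(50,), default_k=50)
        tcfg = TrainConfig(seed=1, epochs_cnn_rnn=1, embedding_dim=8, cnn_filters_per_width=4, rnn_hidden_size=8)
        _, report = run_pipeline(train, [], pool, 50, cfg, tcfg, ensemble_kinds=("lightweight",))
        sel = report["selections"][0]["selected"]
        assert report["expanded_size"] == len(train) + sel
        counts = report["expanded_class_counts"]
        tr_counts = report["train_class_counts"]
        sel_counts = report["selections"][0]["selected_class_counts"]
        assert counts["0"] == tr_counts["0"] + sel_counts[0]
        assert counts["1"] == tr_counts["1"] + sel_counts[1]

    def test_validation_never_added(self, data):
        train, pool, _ = data
        with pytest.raises(ValueError, match="leak"):
            run_pipeline(train, train, pool, 0, SelfTrainConfig(), TrainConfig())

    def test_negative_k_rejected(self, data):
        train, pool, _ = data
        with pytest.raises(ValueError):
            run_pipeline(train, [], pool, -5, SelfTrainConfig(), TrainConfig())

    def test_report_contains_validation_metrics(self, data):
        train, pool, test = data
        tcfg = TrainConfig(seed=2, epochs_cnn_rnn=1, embedding_dim=8, cnn_filters_per_width=4, rnn_hidden_size=8)
        _, report = run_pipeline(train, test, pool, 0, SelfTrainConfig(seed=2), tcfg, ensemble_kinds=("lightweight",))
        assert set(report["validation"]) == {"precision", "recall", "f1", "auroc"}


class TestSelfTrainConfig:
    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            SelfTrainConfig(confidence_threshold=0.4)

    def test_default_k_must_be_candidate(self):
        with pytest.raises(ValueError):
            SelfTrainConfig(candidate_added_sizes=(100,), default_k=200)

    def test_defaults_match_contract(self):
        cfg = SelfTrainConfig()
        assert cfg.candidate_added_sizes == (1000, 2000, 3000, 5000, 10000)
        assert cfg.default_k == 5000
        assert cfg.confidence_threshold == 0.9
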