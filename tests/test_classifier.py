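"""Classifier head, pooling, unfreezing mechanics and task protocols."""

import numpy as np
import pytest

from protlm.classifier import (
    ClassifierConfig,
    SequenceClassifier,
    UnfreezeSchedule,
    build_classifier,
    combine_with_external_scores,
    concat_pool,
    ensemble,
    filter_go_terms,
    go_config,
    predict_proba,
    predict_proba_tokens,
    run_detection_task,
)
from protlm.lm import LMConfig
from protlm.nn import Tensor
from protlm.synthetic import SyntheticCorpusConfig, generate_detection_benchmark
from protlm.vocab import AminoAcidVocabulary, ProteinRecord

VOCAB = AminoAcidVocabulary()


def tiny_lm_config(**kw):
    return LMConfig(embedding_dim=8, hidden_dim=12, seed=0, **kw)


def tiny_clf_config(**kw):
    defaults = dict(n_outputs=3, head_hidden=16, epochs_final=2,
                    batch_size=4, seed=0)
    defaults.update(kw)
    return ClassifierConfig(**defaults)


class TestConcatPool:
    def test_constant_states_give_triplicated_vector(self):
        h = np.array([1.0, -2.0, 3.0])
        states = Tensor(np.tile(h, (5, 1, 1)))  # (T=5, B=1, d=3)
        out = concat_pool(states)
        np.testing.assert_allclose(out.data[0], np.concatenate([h, h, h]))

    def test_single_timestep_blocks_identical(self):
        states = Tensor(np.random.default_rng(0).normal(size=(1, 2, 4)))
        out = concat_pool(states).data
        np.testing.assert_allclose(out[:, :4], out[:, 4:8])
        np.testing.assert_allclose(out[:, :4], out[:, 8:])

    def test_matches_brute_force_max_mean(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 1, 3))
        out = concat_pool(Tensor(x)).data[0]
        np.testing.assert_allclose(out[:3], x[-1, 0])
        np.testing.assert_allclose(out[3:6], x[:, 0].max(axis=0))
        np.testing.assert_allclose(out[6:], x[:, 0].mean(axis=0))

    def test_padding_excluded_from_pooling(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 2, 3))
        lengths = np.array([4, 6])
        out = concat_pool(Tensor(x), lengths).data
        np.testing.assert_allclose(out[0, :3], x[3, 0])  # last valid state
        np.testing.assert_allclose(out[0, 3:6], x[:4, 0].max(axis=0))
        np.testing.assert_allclose(out[0, 6:], x[:4, 0].mean(axis=0))

    def test_zero_timesteps_rejected(self):
        with pytest.raises(ValueError):
            concat_pool(Tensor(np.zeros((2, 1, 3))), np.array([0]))


class TestBuildClassifier:
    def test_encoder_initialized_from_lm_weights_exactly(self):
        lmc = tiny_lm_config()
        from protlm.lm import build_lm

        lm = build_lm(lmc, VOCAB)
        weights = lm.encoder.state_dict()
        clf = build_classifier(weights, tiny_clf_config(), lmc, VOCAB)
        for key, arr in clf.encoder.state_dict().items():
            np.testing.assert_array_equal(arr, weights[key])

    def test_from_scratch_reproducible_and_independent_of_lm(self):
        a = build_classifier(None, tiny_clf_config(seed=3), tiny_lm_config(), VOCAB)
        b = build_classifier(None, tiny_clf_config(seed=3), tiny_lm_config(), VOCAB)
        for pa, pb in zip(a.parameters_all(), b.parameters_all()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_level1_enzyme_config_has_six_output_units(self):
        clf = build_classifier(None, tiny_clf_config(n_outputs=6),
                               tiny_lm_config(), VOCAB)
        assert clf.fc2.weight.shape[1] == 6

    def test_dimension_mismatch_rejected(self):
        lmc = tiny_lm_config()
        from protlm.lm import build_lm

        weights = build_lm(lmc, VOCAB).encoder.state_dict()
        other = LMConfig(embedding_dim=16, hidden_dim=12, seed=0)
        with pytest.raises(ValueError):
            build_classifier(weights, tiny_clf_config(), other, VOCAB)

    def test_go_configuration_uses_1024_head_and_binary_loss(self):
        cfg = go_config(n_terms=100)
        assert cfg.head_hidden == 1024
        assert cfg.loss == "binary"
        assert cfg.n_outputs == 100


class TestUnfreezeSchedule:
    def test_group_lrs_halve_toward_input(self):
        sched = UnfreezeSchedule(base_lr=0.008)
        assert sched.group_lrs() == [0.008, 0.004, 0.002, 0.001]

    def test_stage_progression_and_final_epoch_count(self):
        sched = UnfreezeSchedule(epochs_per_stage=1, epochs_final=30)
        stages = list(sched.stages())
        assert [k for k, _ in stages] == [1, 2, 3, 4]
        assert [e for _, e in stages] == [1, 1, 1, 30]

    def test_frozen_groups_receive_zero_gradient(self):
        clf = build_classifier(None, tiny_clf_config(), tiny_lm_config(), VOCAB)
        clf.set_unfrozen(1)  # only the head trains in stage 1
        ids = np.array([[1], [2], [3], [4]])
        from protlm.nn import cross_entropy_logits

        logits = clf.forward(ids, np.array([4]), train=False)
        loss = cross_entropy_logits(logits, np.array([0]))
        loss.backward()
        groups = clf.layer_groups()
        for p in groups[0] + groups[1] + groups[2]:
            assert p.grad is None
        assert any(p.grad is not None for p in groups[3])


class TestPredictAndEnsemble:
    def records(self):
        return [ProteinRecord("a", "MSLR", 0), ProteinRecord("b", "ACDEFG", 1)]

    def test_categorical_probabilities_sum_to_one(self):
        clf = build_classifier(None, tiny_clf_config(), tiny_lm_config(), VOCAB)
        probs, errors = predict_proba(clf, self.records())
        assert not errors
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic_and_order_equivariant(self):
        clf = build_classifier(None, tiny_clf_config(), tiny_lm_config(), VOCAB)
        recs = self.records()
        p1, _ = predict_proba(clf, recs)
        p2, _ = predict_proba(clf, recs[::-1])
        np.testing.assert_allclose(p1, p2[::-1], atol=1e-12)

    def test_unknown_residue_yields_error_entry_not_abort(self):
        clf = build_classifier(None, tiny_clf_config(), tiny_lm_config(), VOCAB)
        recs = [ProteinRecord("ok", "MSLR"), ProteinRecord("bad", "MS1R")]
        probs, errors = predict_proba(clf, recs)
        assert "bad" in errors and "ok" not in errors
        assert np.isfinite(probs[0]).all() and np.isnan(probs[1]).all()

    def test_ensemble_is_elementwise_mean(self):
        np.testing.assert_allclose(
            ensemble([[0.2, 0.8]], [[0.4, 0.6]]), [[0.3, 0.7]]
        )
        x = np.array([[0.1, 0.9]])
        np.testing.assert_allclose(ensemble(x, x), x)  # idempotent
        out = ensemble([[0.2, 0.8]], [[0.5, 0.5]])
        assert out.sum() == pytest.approx(1.0)  # convexity preserves simplex

    def test_ensemble_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble(np.zeros((2, 3)), np.zeros((2, 4)))


class TestGoProtocol:
    def test_min_count_boundary_at_50(self):
        labels = np.zeros((120, 2), dtype=int)
        labels[:50, 0] = 1   # t0: exactly 50 -> kept
        labels[:49, 1] = 1   # t1: 49 -> dropped
        assert filter_go_terms(labels, 50).tolist() == [0]

    def test_threshold_counted_on_training_partition_only(self):
        train = np.zeros((100, 1), dtype=int)
        train[:10, 0] = 1  # 10 train occurrences: dropped regardless of test
        with pytest.raises(ValueError):
            filter_go_terms(train, 50)

    def test_external_weight_one_returns_external_scores(self):
        model = np.random.default_rng(0).random((4, 3))
        external = np.random.default_rng(1).random((4, 3))
        np.testing.assert_array_equal(
            combine_with_external_scores(model, external, 1.0), external
        )
        np.testing.assert_array_equal(
            combine_with_external_scores(model, external, 0.0), model
        )


class TestDetectionProtocol:
    def test_reports_per_dataset_aucs_and_their_mean(self):
        cfg = SyntheticCorpusConfig(clusters_per_family=6,
                                    members_per_cluster=2,
                                    length_range=(30, 40), seed=11)
        datasets = generate_detection_benchmark(cfg, n_datasets=2)
        report = run_detection_task(
            datasets, tiny_lm_config(),
            tiny_clf_config(n_outputs=2), epochs=2,
        )
        assert len(report["per_dataset"]) == 2
        aucs = [d["test_auc"] for d in report["per_dataset"]]
        assert report["mean_auc"] == pytest.approx(np.mean(aucs))
        for d in report["per_dataset"]:
            assert 0.0 <= d["test_auc50"] <= 1.0

    def test_constant_scores_give_auc_half(self):
        from protlm.metrics import auc

        labels = np.array([0, 1] * 10)
        assert auc(labels, np.full(20, 0.5)) == 0.5

    def test_single_class_dataset_skipped_with_warning(self):
        cfg = SyntheticCorpusConfig(clusters_per_family=6,
                                    members_per_cluster=2,
                                    length_range=(30, 40), seed=12)
        datasets = generate_detection_benchmark(cfg, n_datasets=2)
        for r in datasets[0].train_records:
            r.labels = 0  # degenerate: no positives
        with pytest.warns(UserWarning, match="single-class"):
            report = run_detection_task(
                datasets, tiny_lm_config(),
                tiny_clf_config(n_outputs=2), epochs=1,
            )
        assert len(report["per_dataset"]) == 1


class TestFinetuneMechanics:
    def test_one_cycle_trace_rises_then_falls_in_final_stage(self):
        rng = np.random.default_rng(0)
        records = [
            ProteinRecord(f"r{i}", "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20)
            ), int(i % 2))
            for i in range(24)
        ]
        cc = tiny_clf_config(n_outputs=2, epochs_final=4)
        model = SequenceClassifier(cc, tiny_lm_config(), vocab=VOCAB)
        results = model.fit(records[:16], records[16:])
        final = [h for h in results.history if h["stage"] == 4]
        assert len(final) == 4  # configured epochs_final
        lrs = np.concatenate([h["lr_trace"] for h in final])
        peak = int(np.argmax(lrs))
        assert lrs.max() == pytest.approx(cc.base_lr)
        assert np.all(np.diff(lrs[: peak + 1]) >= -1e-15)
        assert np.all(np.diff(lrs[peak:]) <= 1e-15)

    def test_empty_validation_rejected(self):
        cc = tiny_clf_config(n_outputs=2)
        model = SequenceClassifier(cc, tiny_lm_config(), vocab=VOCAB)
        with pytest.raises(ValueError):
            model.fit([ProteinRecord("a", "MSLR", 0)], [])
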