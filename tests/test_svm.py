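"""One-vs-one RBF-SVM: kernel, training invariants, fusion, metrics, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import SVC

from cwdetect import (
    BinarySVM,
    FeatureTable,
    ParameterError,
    TrainedModel,
    ValidationError,
    check_dual_constraints,
    decision_value,
    evaluate,
    kfold_cv,
    load_model,
    predict,
    rbf_kernel,
    save_model,
    train,
)
from conftest import blob_table

BLOBS3 = {"normal": (2.0, 2.0), "ischemia": (8.0, 2.0), "infarction": (2.0, 8.0)}


class TestRBFKernel:
    def test_zero_distance_gives_one(self):
        assert rbf_kernel(np.array([0.3, 0.4]), np.array([0.3, 0.4]), 0.1) == 1.0

    def test_closed_form_at_characteristic_distance(self):
        sigma = 0.1
        x = np.array([0.0, 0.0])
        xi = np.array([sigma * np.sqrt(2.0), 0.0])  # ||x-xi||^2 = 2 sigma^2
        assert rbf_kernel(x, xi, sigma) == pytest.approx(np.exp(-1.0))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ParameterError):
            rbf_kernel(np.zeros(2), np.ones(2), 0.0)

    @given(
        x=st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
        xi=st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
        sigma=st.floats(0.01, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, x, xi, sigma):
        # mathematically in (0, 1]; tiny widths may underflow to exactly 0
        k = rbf_kernel(np.array(x), np.array(xi), sigma)
        assert 0.0 <= k <= 1.0
        if x == xi:
            assert k == 1.0


class TestTraining:
    def test_three_classes_give_three_pairwise_machines(self):
        model = train(blob_table(BLOBS3, 10, seed=0))
        assert len(model.lead_models["I"]) == 3  # K(K-1)/2 with K = 3

    def test_dual_box_constraints_hold(self):
        model = train(blob_table(BLOBS3, 15, spread=2.0, seed=1), gamma_cost=10.0)
        check_dual_constraints(model)
        for m in model.lead_models["I"]:
            assert np.all(np.abs(m.dual_coef) <= 10.0 + 1e-6)
            assert abs(m.dual_coef.sum()) < 1e-6

    def test_separable_blobs_reach_perfect_training_accuracy(self):
        table = blob_table({"normal": (1.0, 1.0), "ischemia": (20.0, 20.0)}, 20, seed=2)
        model = train(table)
        decisions = predict(model, table)
        assert all(d.fused_label == d.truth for d in decisions)

    def test_duplicated_training_set_leaves_boundary_unchanged(self):
        table = blob_table(BLOBS3, 12, spread=1.5, seed=3)
        doubled = table.data.copy()
        doubled["segment_index"] = 1  # same points, new unique keys
        both = FeatureTable(pd.concat([table.data, doubled], ignore_index=True))
        probe = blob_table(BLOBS3, 30, spread=3.0, seed=4)
        a = [d.fused_label for d in predict(train(table), probe)]
        b = [d.fused_label for d in predict(train(both), probe)]
        assert a == b

    def test_single_class_lead_rejected_naming_lead(self):
        healthy = blob_table({"normal": (1.0, 1.0), "ischemia": (5.0, 5.0)}, 10, lead="I")
        lame = blob_table({"normal": (1.0, 1.0)}, 10, lead="V3")
        table = FeatureTable(pd.concat([healthy.data, lame.data], ignore_index=True))
        with pytest.raises(ValidationError, match="V3"):
            train(table)

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValidationError):
            train(blob_table(BLOBS3, 4))


class TestDecisionValue:
    def test_far_point_decays_to_bias(self):
        model = train(blob_table(BLOBS3, 10, seed=5))
        m = model.lead_models["I"][0]
        far = np.array([1e3, 1e3])
        assert decision_value(m, far) == pytest.approx(m.bias, abs=1e-9)

    def test_matches_libsvm_decision_function(self):
        # dual route: Eq.-style evaluation from stored SVs vs the solver's own
        table = blob_table({"normal": (2.0, 2.0), "ischemia": (6.0, 6.0)}, 15,
                           spread=2.0, seed=6)
        model = train(table, sigma_rbf=0.1, gamma_cost=10.0)
        m = model.lead_models["I"][0]
        x = model.scale(table.data)
        y = table.data["label"].to_numpy()
        svc = SVC(C=10.0, kernel="rbf", gamma=1.0 / (2.0 * 0.1**2)).fit(x, y)
        ours = decision_value(m, x)
        assert np.allclose(ours, svc.decision_function(x), atol=1e-8)

    def test_free_support_vectors_sit_on_the_margin(self):
        table = blob_table({"normal": (2.0, 2.0), "ischemia": (5.0, 5.0)}, 20,
                           spread=1.5, seed=7)
        model = train(table, gamma_cost=10.0)
        m = model.lead_models["I"][0]
        free = np.abs(m.dual_coef) < 10.0 - 1e-6
        assert free.any()
        r = np.abs(decision_value(m, m.support_vectors[free]))
        # KKT margin condition, up to libsvm's default solver tolerance
        assert np.allclose(r, 1.0, atol=1e-2)


def _constant_machine(neg, pos, bias):
    # single SV with alpha = 0: R == bias everywhere, vote fixed by sign(bias)
    return BinarySVM(
        class_neg=neg, class_pos=pos,
        support_vectors=np.zeros((1, 2)), dual_coef=np.zeros(1),
        bias=bias, sigma_rbf=0.1, gamma_cost=10.0,
    )


def _fixed_vote_model(lead_biases: dict[str, float]) -> TrainedModel:
    return TrainedModel(
        classes=["ischemia", "normal"],
        lead_models={
            lead: [_constant_machine("ischemia", "normal", bias)]
            for lead, bias in lead_biases.items()
        },
        scaler={"p_st": (0.0, 100.0), "p_pr": (0.0, 100.0)},
        sigma_rbf=0.1, gamma_cost=10.0,
    )


def _segment_features(leads):
    return FeatureTable(
        pd.DataFrame(
            {
                "record_id": ["x"] * len(leads),
                "segment_index": [0] * len(leads),
                "lead_name": leads,
                "p_st": [10.0] * len(leads),
                "p_pr": [20.0] * len(leads),
                "label": [None] * len(leads),
            }
        )
    )


class TestFusion:
    def test_single_lead_decision_is_fused_decision(self):
        model = _fixed_vote_model({"I": -2.0})  # votes ischemia
        [d] = predict(model, _segment_features(["I"]))
        assert d.lead_labels == {"I": "ischemia"}
        assert d.fused_label == "ischemia"

    def test_seven_lead_majority(self):
        biases = {f"L{i}": (-1.0 if i < 4 else +1.0) for i in range(7)}
        model = _fixed_vote_model(biases)  # 4 ischemia vs 3 normal
        [d] = predict(model, _segment_features(sorted(biases)))
        assert d.fused_label == "ischemia"
        assert d.votes == {"ischemia": 4, "normal": 3}
        assert sum(d.votes.values()) == 7

    def test_unknown_lead_rejected_listing_available(self):
        model = _fixed_vote_model({"I": -1.0})
        with pytest.raises(ValidationError, match="V9"):
            predict(model, _segment_features(["V9"]))


class TestEvaluate:
    def test_printed_style_confusion_arithmetic(self):
        truth = ["ischemia"] * 100 + ["normal"] * 100
        pred = (["ischemia"] * 99 + ["normal"]) + (["normal"] * 98 + ["ischemia"] * 2)
        m = evaluate(pred, truth)
        assert m["sensitivity"] == pytest.approx(0.99)
        assert m["specificity"] == pytest.approx(0.98)
        assert m["accuracy"] == pytest.approx(0.985)

    def test_all_correct(self):
        labels = ["normal", "ischemia", "infarction"] * 5
        m = evaluate(labels, labels)
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0
        assert np.trace(m["confusion"].to_numpy()) == 15

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            evaluate(["normal"], ["normal", "ischemia"])

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(11)
        truth = ["normal", "ischemia", "infarction"] * 200
        pred = list(rng.permutation(truth))
        acc = evaluate(pred, truth)["accuracy"]
        ci = 4 * np.sqrt((1 / 3) * (2 / 3) / len(truth))
        assert abs(acc - 1 / 3) < ci


class TestKFold:
    def test_each_record_in_exactly_one_test_fold(self, monkeypatch):
        table = blob_table(BLOBS3, 34, spread=1.5, seed=8)  # 102 records
        seen: list[str] = []
        import cwdetect.svm as svm_mod

        original_predict = svm_mod.predict

        def spy(model, features):
            seen.extend(features.data["record_id"])
            return original_predict(model, features)

        monkeypatch.setattr(svm_mod, "predict", spy)
        kfold_cv(table, k=10, seed=0)
        assert sorted(seen) == sorted(table.data["record_id"])

    def test_seed_determinism(self):
        table = blob_table(BLOBS3, 10, spread=1.5, seed=9)
        a = kfold_cv(table, k=5, seed=3)
        b = kfold_cv(table, k=5, seed=3)
        assert a["pooled"]["confusion"].equals(b["pooled"]["confusion"])
        assert [f["accuracy"] for f in a["folds"]] == [f["accuracy"] for f in b["folds"]]

    def test_too_few_records_rejected(self):
        with pytest.raises(ParameterError):
            kfold_cv(blob_table(BLOBS3, 2), k=10)


class TestBinaryReduction:
    def test_two_class_machine_equals_direct_binary_svm(self):
        # with K = 2 the one-vs-one assembly is a single binary SVM
        table = blob_table({"normal": (2.0, 2.0), "ischemia": (5.0, 4.0)}, 25,
                           spread=2.0, seed=10)
        model = train(table, sigma_rbf=0.1, gamma_cost=10.0)
        assert len(model.lead_models["I"]) == 1
        probe = blob_table({"normal": (2.0, 2.0), "ischemia": (5.0, 4.0)}, 40,
                           spread=3.0, seed=11)
        ours = [d.fused_label for d in predict(model, probe)]
        x = model.scale(table.data)
        svc = SVC(C=10.0, kernel="rbf", gamma=1.0 / (2.0 * 0.1**2))
        svc.fit(x, table.data["label"])
        theirs = list(svc.predict(model.scale(probe.data)))
        assert ours == theirs


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path):
        table = blob_table(BLOBS3, 10, seed=12)
        model = train(table)
        save_model(model, tmp_path / "model.json")
        back = load_model(tmp_path / "model.json")
        probe = blob_table(BLOBS3, 20, spread=3.0, seed=13)
        assert [d.fused_label for d in predict(model, probe)] == [
            d.fused_label for d in predict(back, probe)
        ]

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        save_model(train(blob_table(BLOBS3, 10, seed=14)), path)
        payload = path.read_text().replace('"format_version": 1', '"format_version": 99')
        path.write_text(payload)
        with pytest.raises(ValidationError):
            load_model(path)
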