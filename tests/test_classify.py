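"""Feature matrices, SVM weights, ranking, selection and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from ssmotif.classify import (
    FeatureMatrix,
    build_feature_matrix,
    compute_feature_weights,
    count_matrix,
    evaluate,
    incremental_selection,
    incremental_selection_cv,
    predict,
    rank_motifs,
    roc_auc,
    train_svm,
)
from ssmotif.discovery import MotifCatalog, MotifRecord, SSMotif
from ssmotif.hairpins import Hairpin

from conftest import ss_from_text


def motif(text):
    return SSMotif.from_text(text)


def catalog(texts):
    return MotifCatalog([MotifRecord(motif=motif(t)) for t in texts])


class TestFeatureMatrix:
    def test_counts_and_absences(self):
        ss = [ss_from_text("ALALAL"), ss_from_text("GDGDGD")]
        X = count_matrix([motif("A_L A_L"), motif("U_R")], ss)
        assert X[0].tolist() == [2, 0]  # overlaps counted
        assert X[1].tolist() == [0, 0]

    def test_binary_and_normalized_modes(self):
        ss = [ss_from_text("ALALAL")]
        assert count_matrix([motif("A_L")], ss, mode="binary")[0, 0] == 1
        assert count_matrix([motif("A_L")], ss, mode="normalized")[0, 0] == pytest.approx(1.0)

    def test_build_from_hairpins(self):
        hp = Hairpin(id="h", sequence="AAA", structure="...", label="positive")
        fm = build_feature_matrix(catalog(["A_D", "G_D"]), [(hp, hp.encode())])
        assert fm.X.tolist() == [[3, 0]]
        assert fm.row_ids == ["h"] and fm.motif_texts == ["AD", "GD"]

    def test_planted_counts_match_bookkeeping(self, rng):
        from ssmotif.synth import GeneratorConfig, make_corpus

        cfg = GeneratorConfig(
            n_positive=6, n_negative=2, length_range=(30, 60), stem_range=(8, 18),
            loop_range=(4, 6), planting_prob=1.0,
            positive_motifs=("G_L G_L C_L A_L U_L G_L",), negative_motifs=(), seed=2,
        )
        corpus = make_corpus(cfg)
        m = motif("G_L G_L C_L A_L U_L G_L")
        X = count_matrix([m], [hp.encode() for hp in corpus.positives])
        n_plantings = sum(1 for p in corpus.manifest["plantings"] if p["motif"] == m.human)
        assert n_plantings == 6
        assert (X[:, 0] >= 1).all()


class TestSVM:
    def test_two_point_hand_solved_dual(self):
        """x=(1,0) y=+1 and x=(-1,0) y=-1: alpha=0.5 each, w=(1,0), b=0."""
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        model = train_svm(X, [1, -1], kernel="linear", C=1e6)
        w = compute_feature_weights(model)
        assert w == pytest.approx([1.0, 0.0], abs=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        assert model.decision_function(X) == pytest.approx([1.0, -1.0], abs=1e-6)

    def test_duplicated_dataset_same_decision(self):
        # separable data, hard-margin limit: the maximum-margin hyperplane
        # depends on the point set, not its multiplicities
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        X[:, 0] += y  # widen the margin
        m1 = train_svm(X, y, kernel="linear", C=1e6)
        m2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]), kernel="linear", C=1e6)
        assert m1.decision_function(X) == pytest.approx(m2.decision_function(X), abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_svm(np.ones((3, 2)), [1, 1, 1])

    def test_constant_feature_gets_zero_weight(self):
        X = np.array([[1.0, 1.0], [1.0, -1.0]])
        model = train_svm(X, [1, -1], kernel="linear", C=1e6)
        w = compute_feature_weights(model)
        assert w[0] == pytest.approx(0.0, abs=1e-6)
        assert w[1] > 0.5

    def test_positive_enriched_feature_gets_positive_weight(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        model = train_svm(X, [1, 1, -1, -1], kernel="linear", C=10.0)
        w = compute_feature_weights(model)
        assert w[0] > 0 > w[1]

    def test_gaussian_model_has_no_linear_weights(self):
        X = np.array([[1.0], [0.0], [2.0], [-1.0]])
        model = train_svm(X, [1, -1, 1, -1], kernel="gaussian", C=1.0)
        assert model.gamma == pytest.approx(1.0)
        with pytest.raises(ValueError, match="linear"):
            compute_feature_weights(model)

    def test_weight_faithfulness_on_training_rows(self):
        """w.x + b reproduces the solver's decision values (rel tol 1e-6)."""
        rng = np.random.default_rng(42)
        X = rng.poisson(2.0, size=(40, 12)).astype(float)
        y = np.where(X[:, 0] - X[:, 1] + rng.normal(scale=0.5, size=40) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        model = train_svm(X, y, kernel="linear", C=1.0)
        w = compute_feature_weights(model)
        np.testing.assert_allclose(
            X @ w + model.bias, model.decision_function(X), rtol=1e-6, atol=1e-9
        )

    def test_model_roundtrip(self, tmp_path):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        model = train_svm(X, [1, -1], motif_texts=["AL", "UL"])
        model.save(tmp_path / "model.json")
        from ssmotif.classify import TrainedModel

        loaded = TrainedModel.load(tmp_path / "model.json")
        assert loaded.selected_motifs == ["AL", "UL"]
        assert loaded.decision_function(X) == pytest.approx(model.decision_function(X))


class TestRanking:
    def test_abs_ordering(self):
        cat = catalog(["A_L", "C_L", "G_L"])
        ranked, order = rank_motifs(cat, np.array([0.5, -0.9, 0.1]))
        assert [r.motif.human for r in ranked] == ["C_L", "A_L", "G_L"]
        assert order.tolist() == [1, 0, 2]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_tie_breaks_lexicographic(self):
        cat = catalog(["G_L", "A_L", "C_L"])
        ranked, _ = rank_motifs(cat, np.array([1.0, 1.0, 1.0]))
        assert [r.motif.human for r in ranked] == ["A_L", "C_L", "G_L"]

    def test_input_order_invariance(self):
        texts = ["A_L", "C_L", "G_L"]
        weights = {"AL": 0.3, "CL": -0.7, "GL": 0.5}
        a, _ = rank_motifs(catalog(texts), np.array([weights[t.replace("_", "")] for t in texts]))
        rev = texts[::-1]
        b, _ = rank_motifs(catalog(rev), np.array([weights[t.replace("_", "")] for t in rev]))
        assert [r.motif.text for r in a] == [r.motif.text for r in b]

    def test_signed_mode(self):
        cat = catalog(["A_L", "C_L"])
        ranked, _ = rank_motifs(cat, np.array([-0.9, 0.1]), mode="signed")
        assert [r.motif.human for r in ranked] == ["C_L", "A_L"]


class TestMetrics:
    def test_all_correct_and_all_flipped(self):
        y = [1, 1, -1, -1]
        assert evaluate(y, y).acc == 1.0
        rep = evaluate([-v for v in y], y)
        assert rep.acc == 0.0

    def test_confusion_arithmetic(self):
        preds = [1, 1, 1, -1, -1, 1, -1, -1]
        labels = [1, 1, 1, 1, 1, -1, -1, -1]
        rep = evaluate(preds, labels)
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (3, 2, 1, 2)
        assert rep.acc == pytest.approx(0.625)
        assert rep.sp == pytest.approx(2 / 3)
        assert rep.se == pytest.approx(0.6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate([1, -1], [1, -1, 1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([(1, 1), (1, -1), (-1, 1), (-1, -1)]), min_size=2, max_size=60))
    def test_metric_identities(self, pairs):
        preds = [p for p, _ in pairs]
        labels = [l for _, l in pairs]
        if len(set(labels)) < 2:
            labels[0] = -labels[0]
        rep = evaluate(preds, labels)
        total = rep.tp + rep.tn + rep.fp + rep.fn
        assert total == len(pairs)
        assert rep.acc == pytest.approx((rep.tp + rep.tn) / total)
        if rep.tn + rep.fp:
            assert rep.sp == pytest.approx(rep.tn / (rep.tn + rep.fp))
        if rep.tp + rep.fn:
            assert rep.se == pytest.approx(rep.tp / (rep.tp + rep.fn))


class TestROC:
    def test_perfect_and_degenerate(self):
        _, auc = roc_auc([2.0, 1.5, -1.0, -2.0], [1, 1, -1, -1])
        assert auc == pytest.approx(1.0)
        _, auc = roc_auc([0.5, 0.5, 0.5, 0.5], [1, -1, 1, -1])
        assert auc == pytest.approx(0.5)

    def test_rank_statistic_example(self):
        _, auc = roc_auc([0.9, 0.8, 0.4, 0.3], [1, -1, 1, -1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_monotone_roc(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) > 0.5, 1, -1)
        if len(set(labels)) < 2:
            labels[0] = -labels[0]
        points, _ = roc_auc(scores, labels)
        assert (np.diff(points[:, 0]) >= 0).all() and (np.diff(points[:, 1]) >= 0).all()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_auc_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = int(rng.integers(2, 20)), int(rng.integers(2, 20))
        scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # force some ties
        labels = np.array([1] * n_pos + [-1] * n_neg)
        _, auc = roc_auc(scores, labels)
        u = mannwhitneyu(scores[:n_pos], scores[n_pos:], alternative="two-sided").statistic
        assert auc == pytest.approx(u / (n_pos * n_neg))


class TestSelection:
    def test_k_below_step_single_point(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
        y = [1, -1, 1, -1]
        cat = catalog(["A_L", "C_L"])
        res = incremental_selection(cat, X, y, X, y, step=100)
        assert len(res.curve) == 1 and res.curve.iloc[0]["n"] == 2

    def test_memorization_reaches_unit_accuracy(self):
        rng = np.random.default_rng(7)
        X = np.hstack([np.array([[1.0]] * 10 + [[0.0]] * 10), rng.poisson(1.0, (20, 3)).astype(float)])
        y = [1] * 10 + [-1] * 10
        cat = catalog(["A_L", "C_L", "G_L", "U_L"])
        res = incremental_selection(cat, X, y, X, y, step=1, C=1e4)
        assert res.curve.iloc[-1]["acc"] == 1.0
        assert res.curve["n"].tolist() == [1, 2, 3, 4]

    def test_cross_validated_selection_prefers_signal(self):
        # one perfectly discriminative feature ranked first, noise after:
        # CV selection keeps a small N and classifies the data correctly
        rng = np.random.default_rng(11)
        n = 40
        X = np.hstack(
            [np.array([[1.0]] * n + [[0.0]] * n), rng.poisson(1.0, (2 * n, 5)).astype(float)]
        )
        y = [1] * n + [-1] * n
        cat = catalog(["A_L", "C_L", "G_L", "U_L", "A_D", "C_D"])
        res = incremental_selection_cv(cat, X, y, n_folds=4, step=2, C=10.0, seed=0)
        assert res.best_n <= 4
        scores = res.best_model.decision_function(X[:, : res.best_n])
        assert evaluate(np.where(scores > 0, 1, -1), y).acc == 1.0

    def test_curve_at_full_k_equals_full_training(self):
        rng = np.random.default_rng(9)
        X = rng.poisson(1.0, size=(30, 7)).astype(float)
        y = np.where(X[:, 0] > X[:, 1], 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        cat = catalog(["A_L", "C_L", "G_L", "U_L", "A_D", "C_D", "G_D"])
        res = incremental_selection(cat, X, y, X, y, step=3)
        full = train_svm(X, y)
        scores = full.decision_function(X)
        rep = evaluate(np.where(scores > 0, 1, -1), y)
        assert res.curve.iloc[-1]["acc"] == pytest.approx(rep.acc)
        assert int(res.curve.iloc[-1]["n"]) == 7


class TestPredict:
    def test_training_consistency_and_errors(self):
        hps = [
            Hairpin(id="a", sequence="AAAA", structure="....", label="positive"),
            Hairpin(id="b", sequence="GGGG", structure="....", label="negative"),
        ]
        cat = catalog(["A_D", "G_D"])
        fm = build_feature_matrix(cat, [(hp, hp.encode()) for hp in hps])
        model = train_svm(fm, [1, -1], C=1e4)
        labels, decisions, errors = predict(hps, model)
        assert labels == ["positive", "negative"] and not errors
        np.testing.assert_allclose(decisions, model.decision_function(fm.X), rtol=1e-9)

    def test_empty_input(self):
        model = train_svm(np.array([[1.0], [0.0]]), [1, -1], motif_texts=["AD"])
        labels, decisions, errors = predict([], model)
        assert labels == [] and len(decisions) == 0 and errors == []

    def test_bad_record_reported_run_continues(self):
        hp_ok = Hairpin(id="ok", sequence="AAAA", structure="....", label="unknown")
        hp_bad = Hairpin.__new__(Hairpin)  # bypass validation to simulate a corrupt record
        hp_bad.id, hp_bad.sequence, hp_bad.structure, hp_bad.label, hp_bad.mature = (
            "bad", "AXGU", "....", "unknown", None,
        )
        model = train_svm(np.array([[1.0], [0.0]]), [1, -1], motif_texts=["AD"])
        labels, decisions, errors = predict([hp_bad, hp_ok], model)
        assert labels[0] == "error" and np.isnan(decisions[0])
        assert labels[1] in ("positive", "negative")
        assert errors and errors[0][0] == "bad"
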