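"""Binary RClass heads: datasets, weighted loss, training, AUPRC, registry."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from deepes.embedding import mock_spec
from deepes.rclass_classifier import (
    DegenerateDatasetError,
    Hyperparameters,
    LabeledExample,
    ModelRegistry,
    UntrainableRClassError,
    auprc,
    build_rclass_dataset,
    grid_search_cv,
    load_registry,
    predict_rclass,
    read_pairs_tsv,
    save_registry,
    table1_grid,
    train_classifier,
    weighted_loss,
    write_pairs_tsv,
)
from deepes.rclass_classifier import SequenceExample

from conftest import separable_clusters


def _examples(n_pos, n_neg, rclass="RC00001", D=4, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_pos + n_neg):
        labels = {rclass} if i < n_pos else set()
        out.append(LabeledExample.make(f"g{i:05d}", rng.normal(size=D), labels))
    return out


class TestDatasetConstruction:
    def test_class_weight_is_neg_over_pos(self):
        ds = build_rclass_dataset(_examples(10, 990), "RC00001")
        assert ds.class_weight == 99.0
        assert ds.n_pos == 10 and ds.n_neg == 990

    def test_every_example_lands_on_exactly_one_side(self):
        examples = _examples(7, 13)
        ds = build_rclass_dataset(examples, "RC00001")
        assert len(ds.gene_ids) == 20
        assert set(ds.gene_ids) == {e.gene_id for e in examples}

    def test_all_positive_is_degenerate(self):
        with pytest.raises(DegenerateDatasetError):
            build_rclass_dataset(_examples(100, 0), "RC00001")

    def test_zero_positives_is_untrainable(self):
        # the failure mode of masking every orthologous group of a class
        with pytest.raises(UntrainableRClassError, match="RC_GONE"):
            build_rclass_dataset(_examples(5, 5), "RC_GONE")

    def test_negative_subsample_is_seeded(self):
        examples = _examples(10, 200)
        a = build_rclass_dataset(examples, "RC00001", negative_subsample=50, seed=1)
        b = build_rclass_dataset(examples, "RC00001", negative_subsample=50, seed=1)
        assert a.gene_ids == b.gene_ids and a.n_neg == 50


class TestWeightedLoss:
    @pytest.mark.parametrize(
        "p,y,w,expected",
        [
            (0.5, 1, 1.0, np.log(2)),
            (0.5, 1, 99.0, 99 * np.log(2)),
            (0.5, 0, 1.0, np.log(2)),
            (0.5, 0, 99.0, np.log(2)),  # weight hits the positive class only
        ],
    )
    def test_closed_forms(self, p, y, w, expected):
        assert weighted_loss(p, y, w) == pytest.approx(expected, rel=1e-12)

    def test_unit_weight_reduces_to_bce(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=50)
        y = rng.integers(0, 2, size=50)
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert np.allclose(weighted_loss(p, y, 1.0), bce)

    def test_saturated_probabilities_are_clamped_finite(self):
        assert np.isfinite(weighted_loss(0.0, 1, 5.0))
        assert np.isfinite(weighted_loss(1.0, 0, 5.0))


class TestTraining:
    def test_separable_clusters_reach_auprc_of_logistic_oracle(self):
        examples, X, y = separable_clusters(n=200, D=8, seed=0)
        train, test = examples[::2], examples[1::2]
        ds = build_rclass_dataset(train, "RC_SEP")
        model = train_classifier(ds, Hyperparameters(epochs=100), seed=0)
        Xte = np.stack([e.embedding for e in test])
        yte = np.array(["RC_SEP" in e.rclass_ids for e in test], int)
        got = auprc(model.predict_batch(Xte), yte)

        Xtr = np.stack([e.embedding for e in train])
        ytr = np.array(["RC_SEP" in e.rclass_ids for e in train], int)
        oracle = LogisticRegression(max_iter=2000).fit(Xtr, ytr)
        ref = auprc(oracle.predict_proba(Xte)[:, 1], yte)
        assert ref >= 0.99  # the data really is separable
        assert got >= 0.99

    def test_shuffled_labels_score_near_prevalence(self):
        examples, X, y = separable_clusters(n=200, D=8, seed=0)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        shuffled = [
            LabeledExample.make(e.gene_id, e.embedding, {"RC_SEP"} if lbl else set())
            for e, lbl in zip(examples, y_perm)
        ]
        train, test = shuffled[::2], shuffled[1::2]
        ds = build_rclass_dataset(train, "RC_SEP")
        model = train_classifier(ds, seed=0)
        Xte = np.stack([e.embedding for e in test])
        yte = np.array(["RC_SEP" in e.rclass_ids for e in test], int)
        prevalence = yte.mean()
        # under label permutation AUPRC concentrates near the prevalence
        assert abs(auprc(model.predict_batch(Xte), yte) - prevalence) <= 0.15

    def test_identical_seed_dataset_hp_give_identical_weights(self):
        ds = build_rclass_dataset(_examples(20, 80), "RC00001")
        a = train_classifier(ds, seed=7)
        b = train_classifier(ds, seed=7)
        for key in a.weights:
            assert np.array_equal(a.weights[key], b.weights[key])

    def test_training_invariant_to_example_order(self):
        examples = _examples(20, 80)
        ds1 = build_rclass_dataset(examples, "RC00001")
        ds2 = build_rclass_dataset(examples[::-1], "RC00001")
        a = train_classifier(ds1, seed=3)
        b = train_classifier(ds2, seed=3)
        for key in a.weights:
            assert np.array_equal(a.weights[key], b.weights[key])

    def test_constant_feature_model_converges_to_analytic_optimum(self):
        # with no usable feature the best constant predictor of the
        # weighted loss is p* = w*pi / (w*pi + 1 - pi)
        rng = np.random.default_rng(5)
        n, n_pos = 1000, 100
        X = np.ones((n, 4)) + rng.normal(scale=1e-9, size=(n, 4))
        examples = [
            LabeledExample.make(f"g{i:05d}", X[i], {"RC"} if i < n_pos else set())
            for i in range(n)
        ]
        ds = build_rclass_dataset(examples, "RC")
        ds.class_weight = 3.0  # decouple the weight from |neg|/|pos|
        pi = n_pos / n
        p_star = 3.0 * pi / (3.0 * pi + 1 - pi)
        model = train_classifier(
            ds, Hyperparameters(epochs=200, learning_rate=1e-2, dropout_rate=0.0),
            seed=0,
        )
        fitted = model.predict_batch(X).mean()
        assert fitted == pytest.approx(p_star, abs=0.02)

    def test_nonfinite_loss_aborts_with_diagnostics(self):
        examples = _examples(5, 5, D=2)
        ds = build_rclass_dataset(examples, "RC00001")
        ds.X = ds.X * np.inf
        with np.errstate(invalid="ignore"), pytest.raises(FloatingPointError):
            train_classifier(ds, Hyperparameters(epochs=1))


class TestPrediction:
    def test_probability_range_and_determinism(self):
        ds = build_rclass_dataset(_examples(10, 40, D=4), "RC00001")
        model = train_classifier(ds, seed=0)
        x = np.zeros(4)
        p = predict_rclass(model, x)
        assert 0.0 <= p <= 1.0
        assert predict_rclass(model, x) == p

    def test_separable_positive_scores_on_the_oracle_side(self):
        examples, X, y = separable_clusters(n=200, D=8, seed=0)
        ds = build_rclass_dataset(examples, "RC_SEP")
        model = train_classifier(ds, Hyperparameters(epochs=100), seed=0)
        held_out_positive = np.full(8, 3.0)  # positive-cluster centroid
        oracle = LogisticRegression(max_iter=2000).fit(X, y)
        assert oracle.predict_proba(held_out_positive[None])[0, 1] > 0.5
        assert predict_rclass(model, held_out_positive) > 0.5

    def test_dimension_mismatch_is_an_error(self):
        ds = build_rclass_dataset(_examples(10, 40, D=4), "RC00001")
        model = train_classifier(ds, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            predict_rclass(model, np.zeros(5))


def _auprc_by_threshold_enumeration(scores, labels):
    """Independent oracle: walk thresholds in descending score order and
    accumulate precision * recall increments."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    s = np.asarray(scores)[order]
    y = np.asarray(labels)[order]
    n_pos = y.sum()
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        sel = s >= t
        tp = int(y[sel].sum())
        precision = tp / sel.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestAuprc:
    def test_perfect_separation_scores_one(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auprc([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_interleaved_example_matches_enumeration(self):
        scores, labels = [0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]
        assert auprc(scores, labels) == pytest.approx(
            _auprc_by_threshold_enumeration(scores, labels), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_enumeration_on_small_datasets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=n), 2)  # force ties sometimes
        assert auprc(scores, labels) == pytest.approx(
            _auprc_by_threshold_enumeration(scores, labels), abs=1e-12
        )

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            auprc([0.5, 0.6], [1, 1])


class TestGridSearch:
    def test_published_grid_has_108_cells(self):
        grid = table1_grid()
        assert len(grid) == 108
        assert {hp.epochs for hp in grid} == {1, 5, 10, 20}
        assert {hp.hidden_size for hp in grid} == {64, 128, 256}
        assert {hp.learning_rate for hp in grid} == {1e-2, 5e-3, 1e-3}
        assert {hp.dropout_rate for hp in grid} == {0.1, 0.25, 0.5}

    def test_single_cell_grid_is_returned_as_is(self):
        examples, _, _ = separable_clusters(n=100, D=8, seed=0)
        only = Hyperparameters(epochs=5, hidden_size=8)
        best, report = grid_search_cv(examples, "RC_SEP", grid=[only], folds=5, seed=0)
        assert best == only and len(report) == 1

    def test_tie_break_prefers_smaller_hidden_layer(self):
        examples, _, _ = separable_clusters(n=100, D=8, seed=0)
        grid = [
            Hyperparameters(epochs=50, hidden_size=64),
            Hyperparameters(epochs=50, hidden_size=8),
        ]
        best, report = grid_search_cv(examples, "RC_SEP", grid=grid, folds=5, seed=0)
        assert all(row["mean_auprc"] >= 0.99 for row in report.rows)
        assert best.hidden_size == 8

    def test_too_few_positives_suggests_fewer_folds(self):
        examples = _examples(3, 50)
        with pytest.raises(ValueError, match="fewer folds"):
            grid_search_cv(examples, "RC00001", grid=[Hyperparameters()], folds=10)


class TestRegistryPersistence:
    def _registry(self):
        spec = mock_spec(4)
        reg = ModelRegistry(embedder_spec=spec)
        for rc in ("RC00001", "RC00002", "RC00003"):
            ds = build_rclass_dataset(_examples(10, 40, rclass=rc, seed=1), rc)
            reg.add(train_classifier(ds, Hyperparameters(epochs=2), seed=0))
        return reg

    def test_round_trip_predictions_are_bitwise_identical(self, tmp_path):
        reg = self._registry()
        save_registry(reg, tmp_path / "reg")
        loaded = load_registry(tmp_path / "reg")
        assert sorted(loaded.models) == sorted(reg.models)
        rng = np.random.default_rng(0)
        probes = rng.normal(size=(10, 4))
        for rc in reg.models:
            for x in probes:
                assert loaded.models[rc].predict(x) == reg.models[rc].predict(x)

    def test_loading_into_wrong_dimension_session_fails(self, tmp_path):
        reg = self._registry()
        save_registry(reg, tmp_path / "reg")
        with pytest.raises(ValueError, match="spec"):
            load_registry(tmp_path / "reg", expected_spec=mock_spec(64))


def test_pairs_tsv_round_trip(tmp_path):
    examples = [
        SequenceExample("g1", "MKTA", frozenset({"RC00001", "RC00002"}), "K00001"),
        SequenceExample("g2", "MVLS", frozenset()),
    ]
    tsv = tmp_path / "pairs.tsv"
    write_pairs_tsv(examples, tsv)
    fasta = tmp_path / "seqs.faa"
    fasta.write_text(">g1\nMKTA\n>g2\nMVLS\n")
    back = read_pairs_tsv(tsv, fasta)
    assert back == examples
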