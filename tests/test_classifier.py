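import numpy as np
import pytest
from sklearn.svm import SVC

from pitha.classifier import (
    FeatureVector,
    LabeledDataset,
    TrainedModel,
    _decision_values,
    _rbf_kernel,
    _smo_solve,
    _SMO_EPS,
    _SMO_MAX_ITER,
    loo_accuracy,
    predict,
    prediction_accuracy,
    read_dataset_csv,
    train_svm,
    write_dataset_csv,
)
from pitha.synthetic import make_feature_dataset


class TestSmoSolver:
    """The SMO solver must agree with an independent SVM implementation."""

    @pytest.mark.parametrize("seed", range(8))
    def test_predictions_match_sklearn_on_random_problems(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 28))
        X = rng.random((n, 2))
        y = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        Xt = rng.random((25, 2))
        for C, gamma in [(1.0, 1.0), (2.0**-5, 2.0**-3), (2.0**15, 2.0**3),
                         (8.0, 2.0**-15)]:
            K = _rbf_kernel(X, X, gamma)
            alpha, rho = _smo_solve(K, y, C, _SMO_EPS, _SMO_MAX_ITER)
            dec = _decision_values(_rbf_kernel(Xt, X, gamma), alpha, y, rho)
            ref = SVC(C=C, gamma=gamma, kernel="rbf").fit(X, y)
            assert np.array_equal(np.sign(dec), np.sign(ref.decision_function(Xt)))

    def test_box_and_equality_constraints_hold(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 2))
        y = np.where(np.arange(20) % 2 == 0, 1.0, -1.0)
        K = _rbf_kernel(X, X, 1.0)
        alpha, _ = _smo_solve(K, y, 4.0, _SMO_EPS, _SMO_MAX_ITER)
        assert np.all(alpha >= -1e-12) and np.all(alpha <= 4.0 + 1e-12)
        assert abs(np.dot(alpha, y)) < 1e-9


def _tiny_dataset():
    return make_feature_dataset(n_per_class=5, separation=10.0, seed=1)


class TestTraining:
    def test_separable_clusters_classified_perfectly(self):
        dataset = make_feature_dataset(n_per_class=8, separation=10.0, seed=2)
        model = train_svm(dataset, ("cavity_volume", "h3_hydrophobic_area"))
        results = predict(model, dataset.feature_vectors)
        assert prediction_accuracy(results, dataset.labels) == 100.0
        assert loo_accuracy(
            dataset, ("cavity_volume", "h3_hydrophobic_area")
        ) == 100.0

    def test_single_class_rejected(self):
        dataset = _tiny_dataset()
        single = LabeledDataset(
            [(fv, "immunogenic") for fv, _ in dataset.items]
        )
        with pytest.raises(ValueError, match="single class"):
            train_svm(single, ("cavity_volume", "h3_hydrophobic_area"))

    def test_too_small_dataset_rejected(self):
        dataset = _tiny_dataset()
        small = LabeledDataset(dataset.items[:2] + dataset.items[-2:])
        with pytest.raises(ValueError, match="at least 6"):
            train_svm(small, ("cavity_volume", "h3_hydrophobic_area"))

    def test_missing_feature_names_antibody(self):
        fvs = [
            FeatureVector(f"ab{i}", 100.0 + i, 1, cavity_volume=None,
                          structure_source="modeled")
            for i in range(6)
        ]
        dataset = LabeledDataset(
            [(fv, "immunogenic" if i < 3 else "non-immunogenic")
             for i, fv in enumerate(fvs)]
        )
        with pytest.raises(ValueError, match="ab0"):
            train_svm(dataset, "crystal")

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            train_svm(_tiny_dataset(), "chimeric")

    def test_training_deterministic(self):
        d1 = make_feature_dataset(n_per_class=6, separation=2.0, seed=9)
        d2 = make_feature_dataset(n_per_class=6, separation=2.0, seed=9)
        m1 = train_svm(d1, ("cavity_volume", "h3_hydrophobic_area"))
        m2 = train_svm(d2, ("cavity_volume", "h3_hydrophobic_area"))
        assert (m1.C, m1.gamma) == (m2.C, m2.gamma)
        assert np.array_equal(m1.alpha, m2.alpha)

    def test_permutation_invariance(self):
        dataset = make_feature_dataset(n_per_class=6, separation=2.0, seed=5)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(dataset))
        shuffled = dataset.subset(list(perm))
        features = ("cavity_volume", "h3_hydrophobic_area")
        m1 = train_svm(dataset, features)
        m2 = train_svm(shuffled, features)
        probes = make_feature_dataset(n_per_class=5, separation=2.0, seed=8)
        p1 = [r.predicted_label for r in predict(m1, probes.feature_vectors)]
        p2 = [r.predicted_label for r in predict(m2, probes.feature_vectors)]
        assert p1 == p2
        assert loo_accuracy(dataset, features) == loo_accuracy(shuffled, features)

    def test_affine_feature_rescaling_absorbed(self):
        dataset = make_feature_dataset(n_per_class=6, separation=2.0, seed=4)
        scaled_items = [
            (
                FeatureVector(
                    fv.antibody_name,
                    fv.h3_hydrophobic_area * 7.5 + 40.0,
                    fv.gly_h2_turn_count,
                    cavity_volume=fv.cavity_volume,
                    structure_source=fv.structure_source,
                ),
                label,
            )
            for fv, label in dataset.items
        ]
        scaled = LabeledDataset(scaled_items)
        features = ("cavity_volume", "h3_hydrophobic_area")
        m1 = train_svm(dataset, features)
        m2 = train_svm(scaled, features)
        assert (m1.C, m1.gamma) == (m2.C, m2.gamma)
        p1 = [r.predicted_label for r in predict(m1, dataset.feature_vectors)]
        p2 = [r.predicted_label for r in predict(m2, scaled.feature_vectors)]
        assert p1 == p2

    def test_training_point_predicted_consistently(self):
        dataset = make_feature_dataset(n_per_class=8, separation=10.0, seed=2)
        model = train_svm(dataset, ("cavity_volume", "h3_hydrophobic_area"))
        results = predict(model, dataset.feature_vectors)
        truth = [1 if lab == "immunogenic" else 0 for lab in dataset.labels]
        assert [r.predicted_label for r in results] == truth


class TestModelSerialization:
    def test_json_round_trip_preserves_predictions(self):
        dataset = make_feature_dataset(n_per_class=6, separation=3.0, seed=6)
        model = train_svm(dataset, ("cavity_volume", "h3_hydrophobic_area"))
        restored = TrainedModel.from_json(model.to_json())
        p1 = [r.predicted_label for r in predict(model, dataset.feature_vectors)]
        p2 = [r.predicted_label for r in predict(restored, dataset.feature_vectors)]
        assert p1 == p2 and restored.features == model.features


class TestDatasetCsv:
    def test_round_trip(self):
        dataset = make_feature_dataset(n_per_class=4, separation=5.0, seed=0)
        text = write_dataset_csv(dataset)
        back = read_dataset_csv(text)
        assert back.names == dataset.names
        assert back.labels == dataset.labels
        for a, b in zip(back.feature_vectors, dataset.feature_vectors):
            assert a.h3_hydrophobic_area == pytest.approx(b.h3_hydrophobic_area)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            read_dataset_csv("antibody,label\nx,immunogenic\n")

    def test_empty_rows_rejected(self):
        header = "antibody,cavity_volume,h3_hydrophobic_area,gly_count,label,source\n"
        with pytest.raises(ValueError, match="no rows"):
            read_dataset_csv(header)

    def test_gly_presence_derived_from_count(self):
        fv = FeatureVector("x", 100.0, 3)
        assert fv.gly_h2_turn_present == 1
        assert FeatureVector("y", 100.0, 0).gly_h2_turn_present == 0

    def test_negative_feature_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            FeatureVector("x", -1.0, 0)
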