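"""Classifier specs, stratified splitting, the end-to-end tabular model,
and the evaluation arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafkdx.classify import (
    ClassifierSpec,
    KDeficiencyDiagnoser,
    diagnose,
    evaluate,
    load_model,
    make_classifier,
    save_model,
    split_dataset,
    train,
)
from leafkdx.features import FEATURE_NAMES


def blob_table(n_per_class=100, sep=4.0, seed=0):
    """A separable FeatureTable: two Gaussian clusters across all 22 features."""
    rng = np.random.default_rng(seed)
    X1 = rng.normal(0.0, 1.0, (n_per_class, 22))
    X2 = rng.normal(0.0, 1.0, (n_per_class, 22))
    X2[:, :6] += sep
    df = pd.DataFrame(np.vstack([X1, X2]), columns=FEATURE_NAMES)
    df["label"] = np.r_[np.ones(n_per_class, int), 2 * np.ones(n_per_class, int)]
    df["k_content"] = np.where(df["label"] == 1, 0.5, 1.1) + rng.normal(0, 0.05, 2 * n_per_class)
    df["sample_id"] = [f"s{i}" for i in range(2 * n_per_class)]
    df["period"] = "flowering"
    return df


# ---------------------------------------------------------------- split


def test_split_1700_gives_1190_510():
    df = pd.DataFrame(
        {"label": np.r_[np.ones(850, int), 2 * np.ones(850, int)], "x": np.arange(1700)}
    )
    tr, te = split_dataset(df, 0.7, seed=0)
    assert len(tr) == 1190 and len(te) == 510


def test_split_reproducible_disjoint_exhaustive():
    df = blob_table(50)
    tr1, te1 = split_dataset(df, seed=3)
    tr2, te2 = split_dataset(df, seed=3)
    assert list(tr1.index) == list(tr2.index)
    assert set(tr1.index) | set(te1.index) == set(df.index)
    assert set(tr1.index) & set(te1.index) == set()


def test_split_stratification():
    df = blob_table(100)
    tr, te = split_dataset(df, seed=1)
    assert (tr["label"] == 1).sum() == 70
    assert (te["label"] == 1).sum() == 30


def test_split_tiny_dataset_missing_class_errors():
    df = pd.DataFrame({"label": [1, 1, 1, 2], "x": range(4)})
    with pytest.raises(ValueError):
        split_dataset(df, 0.7, seed=0)


def test_split_bad_fraction():
    with pytest.raises(ValueError):
        split_dataset(blob_table(10), 1.5)


# ---------------------------------------------------------------- training


@pytest.mark.parametrize("kind", ["svm", "knn", "dt"])
def test_separable_blobs_train_perfectly(kind):
    df = blob_table(60, sep=6.0, seed=2)
    model = train(ClassifierSpec(kind=kind, seed=0), df)
    assert (diagnose(model, df) == df["label"].to_numpy()).all()


def test_knn_majority_vote_manhattan():
    """Brute-force oracle: 6 Manhattan-nearest neighbors vote 4-2 for class 1."""
    X_train = np.array(
        [[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1], [0.2, 0], [0, 0.2], [5, 5], [5.1, 5]]
    )
    y_train = np.array([1, 1, 1, 2, 2, 1, 2, 2])
    query = np.array([[0.05, 0.05]])
    d = np.abs(X_train - query).sum(axis=1)
    nn = np.argsort(d, kind="stable")[:6]
    votes = np.bincount(y_train[nn])
    assert votes[1] == 4 and votes[2] == 2  # oracle: 4 class-1 / 2 class-2
    clf = make_classifier(ClassifierSpec(kind="knn")).fit(X_train, y_train)
    assert clf.predict(query)[0] == 1


def test_knn_even_tie_goes_to_deficient():
    X_train = np.array([[0.0], [0.2], [0.4], [0.6], [0.8], [1.0]])
    y_train = np.array([1, 1, 1, 2, 2, 2])
    clf = make_classifier(ClassifierSpec(kind="knn")).fit(X_train, y_train)
    assert clf.predict([[0.5]])[0] == 1  # 3-3 vote resolves to class 1


def test_dt_depth_constraint():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(300, 4))
    y = np.where(X[:, 0] + 0.3 * rng.normal(size=300) > 0, 1, 2)
    clf = make_classifier(ClassifierSpec(kind="dt", seed=0)).fit(X, y)
    assert clf.get_depth() <= 5


def test_spec_validation():
    with pytest.raises(ValueError):
        ClassifierSpec(kind="forest").validate()
    with pytest.raises(ValueError):
        ClassifierSpec(svm_C=-1).validate()


def test_single_class_fit_errors():
    df = blob_table(20)
    df["label"] = 1
    with pytest.raises(ValueError):
        train(ClassifierSpec(), df)


def test_diagnose_consistent_with_training_predictions():
    df = blob_table(80, sep=3.0, seed=7)
    model = train(ClassifierSpec(kind="svm", seed=0), df)
    assert np.array_equal(diagnose(model, df), model.predict(df))


def test_model_roundtrip_identical_predictions(tmp_path):
    df = blob_table(60, sep=3.0, seed=8)
    model = train(ClassifierSpec(kind="svm", seed=0), df)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    back = load_model(path)
    assert np.array_equal(back.predict(df), model.predict(df))
    assert path.with_suffix(".joblib.json").exists()


def test_heldout_accuracy_on_two_cluster_design():
    df = blob_table(100, sep=4.0, seed=9)
    tr, te = split_dataset(df, seed=9)
    model = train(ClassifierSpec(kind="svm", seed=9), tr)
    rep = evaluate(te["label"].to_numpy(), model.predict(te))
    assert rep.Acc >= 0.9


def test_screening_disabled_keeps_all_features():
    df = blob_table(60, seed=10)
    model = KDeficiencyDiagnoser(classifier="svm", screening=False, seed=0)
    model.fit(df, df["label"].to_numpy())
    assert model.retained_ == FEATURE_NAMES


def test_unknown_feature_names_error():
    df = blob_table(30, seed=11)
    model = train(ClassifierSpec(), df)
    with pytest.raises(ValueError, match="missing"):
        model.predict(df.drop(columns=["CR"]))


# ---------------------------------------------------------------- evaluate


def test_field_accuracy_arithmetic():
    """Error counts 17/12/13/10 of 200 give 91.5 / 94 / 93.5 / 95 %."""
    for errors, acc in [(17, 0.915), (12, 0.94), (13, 0.935), (10, 0.95)]:
        y_true = np.r_[np.ones(100, int), 2 * np.ones(100, int)]
        y_pred = y_true.copy()
        y_pred[:errors] = 2  # flip `errors` deficient leaves to normal
        rep = evaluate(y_true, y_pred)
        assert rep.Acc == pytest.approx(acc, abs=1e-12)


def test_all_correct_metrics_one():
    y = np.array([1, 2, 1, 2])
    rep = evaluate(y, y)
    assert rep.Acc == rep.Rec == rep.Pre == rep.F1 == 1.0


def test_hand_computed_confusion():
    """TP=80, FN=20, FP=10, TN=90 (hand-computed oracle)."""
    y_true = np.r_[np.ones(100, int), 2 * np.ones(100, int)]
    y_pred = np.r_[np.ones(80, int), 2 * np.ones(20, int), np.ones(10, int), 2 * np.ones(90, int)]
    rep = evaluate(y_true, y_pred)
    assert rep.confusion.tolist() == [[80, 20], [10, 90]]
    assert rep.Rec == pytest.approx(0.8)
    assert rep.Pre == pytest.approx(8 / 9)
    assert rep.F1 == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))


def test_metric_errors():
    with pytest.raises(ValueError, match="mismatch"):
        evaluate([1, 2], [1])
    with pytest.raises(ValueError, match="labels"):
        evaluate([0, 1], [1, 1])


@given(st.lists(st.tuples(st.integers(1, 2), st.integers(1, 2)), min_size=1, max_size=60))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_metric_invariants(pairs):
    y_true = np.array([p[0] for p in pairs])
    y_pred = np.array([p[1] for p in pairs])
    rep = evaluate(y_true, y_pred)
    for m in (rep.Acc, rep.Rec, rep.Pre, rep.F1):
        assert 0 <= m <= 1
    assert rep.F1 <= max(rep.Pre, rep.Rec) + 1e-12
    assert (rep.F1 == 0) == (rep.Pre * rep.Rec == 0)
    assert rep.confusion.sum() == rep.n
    # order invariance
    perm = np.random.default_rng(0).permutation(len(y_true))
    rep2 = evaluate(y_true[perm], y_pred[perm])
    assert rep2.confusion.tolist() == rep.confusion.tolist()
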