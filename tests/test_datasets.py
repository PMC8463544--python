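import numpy as np
import pandas as pd
import pytest

from synmedbench.datasets import (BenchmarkSetting, DatasetStore, binarize_labels,
                                  build_benchmark_setting, filter_rare_classes,
                                  largest_remainder_counts,
                                  make_equivalent_synthetic_folds,
                                  stratified_patient_split,
                                  undersample_negative_class)
from synmedbench.synthetic_data import ClassList, default_spec, generate_dataset


def _make_store(label_rows, patient_ids=None, folds=None, resolution=8, seed=0):
    lm = np.asarray(label_rows, dtype=np.int64)
    n, n_labels = lm.shape
    rng = np.random.default_rng(seed)
    names = [f"l{j}" for j in range(n_labels)]
    table = pd.DataFrame(lm, columns=names)
    table.insert(0, "image_id", [f"im{i:04d}" for i in range(n)])
    table.insert(1, "patient_id", patient_ids if patient_ids is not None
                 else [f"p{i:04d}" for i in range(n)])
    if folds is not None:
        table.insert(2, "fold", folds)
    return DatasetStore(rng.random((n, resolution, resolution)), table, names, resolution)


# ------------------------------------------------------------- binarization
def test_binarize_uncertain_positive():
    raw = pd.DataFrame({"a": [0, 1, "uncertain"], "b": [1, "u", 0]})
    out = binarize_labels(raw, "uncertain_positive")
    assert out["a"].tolist() == [0, 1, 1]
    assert out["b"].tolist() == [1, 1, 0]


def test_binarize_probability_positive():
    raw = pd.DataFrame({"a": [0.3, 0.0, 1.0]})
    out = binarize_labels(raw, "probability_positive")
    assert out["a"].tolist() == [1, 0, 1]


def test_binarize_all_zero_row_unchanged():
    raw = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
    out = binarize_labels(raw, "uncertain_positive")
    assert (out.to_numpy() == 0).all()


def test_binarize_errors():
    with pytest.raises(ValueError):
        binarize_labels(pd.DataFrame({"a": ["weird"]}), "uncertain_positive")
    with pytest.raises(ValueError):
        binarize_labels(pd.DataFrame({"a": [1.2]}), "probability_positive")
    with pytest.raises(ValueError):
        binarize_labels(pd.DataFrame({"a": [0]}), "nope")


# ------------------------------------------------------------ undersampling
def test_undersample_900_negatives_100_positives():
    rows = [[0]] * 900 + [[1]] * 100
    store = _make_store(rows)
    out = undersample_negative_class(store, 0.5, seed=1)
    lm = out.label_matrix()
    n_neg = int((lm.sum(axis=1) == 0).sum())
    n_pos = int((lm.sum(axis=1) > 0).sum())
    assert n_pos == 100                       # positives untouched
    assert n_neg <= 100
    assert n_pos / len(out) >= 0.5            # positive share at least 50%


def test_undersample_balanced_is_noop():
    rows = [[0]] * 50 + [[1]] * 50
    store = _make_store(rows)
    out = undersample_negative_class(store, 0.5, seed=1)
    assert len(out) == 100
    assert out.labels.equals(store.labels)


# ----------------------------------------------------------------- splitting
def test_split_ten_single_image_patients():
    store = _make_store([[1]] * 10)
    out = stratified_patient_split(store, (0.8, 0.1, 0.1), seed=0)
    counts = out.labels["fold"].value_counts().to_dict()
    assert counts == {"train": 8, "val": 1, "test": 1}


def test_split_is_patient_partition():
    spec = default_spec(16, 2, images_per_patient=2)
    cl = ClassList(((1, 0), (0, 1), (1, 1)))
    store = generate_dataset(spec, cl, per_class=20, seed=5)
    out = stratified_patient_split(store, seed=7)
    per_patient = out.labels.groupby("patient_id")["fold"].nunique()
    assert (per_patient == 1).all()
    assert set(out.labels["fold"]) <= {"train", "val", "test"}


def test_split_fractions_within_one_patient_per_stratum():
    store = _make_store([[1, 0]] * 37 + [[0, 1]] * 23)
    out = stratified_patient_split(store, (0.8, 0.1, 0.1), seed=3)
    for key, grp in out.labels.groupby(out.combination_keys()):
        n = len(grp)
        counts = grp["fold"].value_counts()
        for fold, frac in zip(("train", "val", "test"), (0.8, 0.1, 0.1)):
            assert abs(counts.get(fold, 0) - n * frac) < 1.0


def test_split_bad_fractions():
    store = _make_store([[1]] * 10)
    with pytest.raises(ValueError):
        stratified_patient_split(store, (0.8, 0.1, 0.2), seed=0)


def test_largest_remainder_exact():
    assert largest_remainder_counts(10, (0.8, 0.1, 0.1)).tolist() == [8, 1, 1]
    assert largest_remainder_counts(7, (0.5, 0.5)).sum() == 7


# ------------------------------------------------------------ rare filtering
def test_filter_rare_classes_threshold():
    rows = [[1, 0]] * 300 + [[0, 1]] * 100 + [[1, 1]] * 50
    store = _make_store(rows)
    out = filter_rare_classes(store, 100)
    assert set(out.combination_counts()) == {"10", "01"}
    assert len(out) == 400


def test_filter_rare_classes_identity_and_idempotent():
    rows = [[1, 0]] * 10 + [[0, 1]] * 5
    store = _make_store(rows)
    assert len(filter_rare_classes(store, 1)) == len(store)
    once = filter_rare_classes(store, 5)
    twice = filter_rare_classes(once, 5)
    assert once.labels.equals(twice.labels)


def test_filter_rare_classes_monotone():
    rows = [[1, 0]] * 30 + [[0, 1]] * 20 + [[1, 1]] * 10
    store = _make_store(rows)
    sizes = [len(filter_rare_classes(store, m)) for m in (1, 11, 21)]
    assert sizes == sorted(sizes, reverse=True)
    with pytest.raises(ValueError):
        filter_rare_classes(store, 1000)      # empty result is an explicit error


# --------------------------------------------------- benchmark construction
def test_build_setting_uniform_histogram():
    rows = [[1, 0]] * 30 + [[0, 1]] * 8
    folds = ["train"] * 38
    store = _make_store(rows, folds=folds)
    setting = BenchmarkSetting(resolution=8, n_classes=2, per_class=20)
    out = build_benchmark_setting(store, setting, seed=1)
    assert out.fold("train").combination_counts() == {"10": 20, "01": 20}


def test_build_setting_oversamples_with_replacement():
    rows = [[1, 0]] * 5 + [[0, 1]] * 10
    store = _make_store(rows, folds=["train"] * 15)
    setting = BenchmarkSetting(resolution=8, n_classes=2, per_class=10)
    out = build_benchmark_setting(store, setting, seed=2)
    train = out.fold("train")
    assert train.combination_counts() == {"10": 10, "01": 10}
    # the 5-record class was repeated: its images appear more than once
    small = train.subset(np.flatnonzero(train.combination_keys() == "10"))
    uniq = {img.tobytes() for img in small.images}
    assert len(uniq) == 5


def test_build_setting_identity_when_counts_match():
    rows = [[1, 0]] * 10 + [[0, 1]] * 10
    store = _make_store(rows, folds=["train"] * 20)
    setting = BenchmarkSetting(resolution=8, n_classes=2, per_class=10)
    out = build_benchmark_setting(store, setting, seed=3)
    assert sorted(out.fold("train").labels["image_id"].str.split("#").str[0]) == \
        sorted(store.labels["image_id"])


def test_build_setting_missing_class_errors():
    rows = [[1, 0]] * 10
    store = _make_store(rows, folds=["train"] * 10)
    setting = BenchmarkSetting(resolution=8, n_classes=2, per_class=5,
                               classes=[(1, 0), (0, 1)])
    with pytest.raises(ValueError):
        build_benchmark_setting(store, setting, seed=0)


def test_setting_train_size_invariant():
    with pytest.raises(ValueError):
        BenchmarkSetting(resolution=8, n_classes=2, per_class=10, train_size=25)
    s = BenchmarkSetting(resolution=8, n_classes=20, per_class=1450)
    assert s.train_size == 29000


# ------------------------------------------------------- equivalent folds
def test_equivalent_folds_label_multisets(toy_store16):
    gen = lambda labels, rng: rng.random((len(labels), 16, 16))  # noqa: E731
    syn = make_equivalent_synthetic_folds(gen, toy_store16, seed=5)
    for fold in ("train", "val", "test"):
        real = toy_store16.fold(fold)
        s = syn.fold(fold)
        assert len(s) == len(real)
        assert sorted(map(tuple, s.label_matrix())) == \
            sorted(map(tuple, real.label_matrix()))
    assert (syn.labels["origin"] == "synthetic").all()


def test_equivalent_folds_noise_independence(toy_store16):
    gen = lambda labels, rng: rng.random((len(labels), 16, 16))  # noqa: E731
    a = make_equivalent_synthetic_folds(gen, toy_store16, seed=1)
    b = make_equivalent_synthetic_folds(gen, toy_store16, seed=2)
    assert not np.array_equal(a.images, b.images)
    assert a.labels.equals(b.labels)


def test_equivalent_folds_shape_mismatch_errors(toy_store16):
    bad = lambda labels, rng: rng.random((len(labels), 8, 8))  # noqa: E731
    with pytest.raises(ValueError):
        make_equivalent_synthetic_folds(bad, toy_store16, seed=0)


def test_store_roundtrip(tmp_path, toy_store16):
    toy_store16.save(tmp_path / "npz", image_format="npz")
    back = DatasetStore.load(tmp_path / "npz")
    assert np.array_equal(back.images, toy_store16.images)
    assert back.label_names == toy_store16.label_names
    toy_store16.save(tmp_path / "png", image_format="png")
    back_png = DatasetStore.load(tmp_path / "png")
    assert np.abs(back_png.images - toy_store16.images).max() <= 1.0 / 255.0


def test_store_rejects_duplicate_ids():
    table = pd.DataFrame({"image_id": ["a", "a"], "patient_id": ["p", "p"],
                          "l0": [0, 1]})
    with pytest.raises(ValueError):
        DatasetStore(np.zeros((2, 8, 8)), table, ["l0"], 8)
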