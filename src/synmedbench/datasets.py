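"""Dataset model and benchmark-construction rules.

A :class:`DatasetStore` bundles grayscale images in [0, 1] with a multi-hot
label table, patient grouping and fold assignment. The operations here
implement label binarization, no-finding undersampling, patient-stratified
splitting, rare-combination filtering, balanced benchmark-setting
construction with oversampling, and label-equivalent synthetic fold
generation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "ImageRecord", "DatasetStore", "BenchmarkSetting",
    "binarize_labels", "undersample_negative_class", "stratified_patient_split",
    "filter_rare_classes", "build_benchmark_setting",
    "make_equivalent_synthetic_folds", "largest_remainder_counts",
]

FOLDS = ("train", "val", "test")
META_COLUMNS = ("image_id", "patient_id", "fold", "origin")


@dataclass
class ImageRecord:
    """A single image with its multi-hot labels and bookkeeping."""

    image_id: str
    patient_id: str
    labels: np.ndarray
    fold: str = "unassigned"
    image: np.ndarray | None = None


@dataclass
class DatasetStore:
    """Images + label table + patient grouping + fold assignment.

    ``labels`` is a DataFrame with columns ``image_id, patient_id, fold,
    origin`` followed by one 0/1 column per label name; row *i* corresponds to
    ``images[i]``.
    """

    images: np.ndarray          # (N, H, W) float64 in [0, 1]
    labels: pd.DataFrame
    label_names: list[str]
    resolution: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be (N, H, W)")
        if len(self.labels) != len(self.images):
            raise ValueError("label table and image array lengths differ")
        if self.images.shape[1] != self.resolution or self.images.shape[2] != self.resolution:
            raise ValueError("image shape does not match resolution")
        self.labels = self.labels.copy()
        if "fold" not in self.labels.columns:
            self.labels["fold"] = "unassigned"
        if "origin" not in self.labels.columns:
            self.labels["origin"] = "real"
        if self.labels["image_id"].duplicated().any():
            raise ValueError("image_id values must be unique within a store")
        lm = self.label_matrix()
        if not np.isin(lm, (0, 1)).all():
            raise ValueError("labels must be binary")
        self.labels = self.labels.reset_index(drop=True)

    # ------------------------------------------------------------- accessors
    def __len__(self) -> int:
        return len(self.images)

    def label_matrix(self) -> np.ndarray:
        return self.labels[self.label_names].to_numpy(dtype=np.int64)

    def records(self) -> list[ImageRecord]:
        lm = self.label_matrix()
        return [ImageRecord(row.image_id, row.patient_id, lm[i], row.fold, self.images[i])
                for i, row in enumerate(self.labels.itertuples(index=False))]

    def fold_indices(self, fold: str) -> np.ndarray:
        return np.flatnonzero((self.labels["fold"] == fold).to_numpy())

    def subset(self, indices: Sequence[int]) -> "DatasetStore":
        indices = np.asarray(indices, dtype=np.int64)
        return DatasetStore(self.images[indices],
                            self.labels.iloc[indices].reset_index(drop=True),
                            list(self.label_names), self.resolution, dict(self.meta))

    def fold(self, name: str) -> "DatasetStore":
        return self.subset(self.fold_indices(name))

    def combination_keys(self) -> np.ndarray:
        """String key per record identifying its exact label combination."""
        lm = self.label_matrix()
        return np.array(["".join(map(str, row)) for row in lm])

    def combination_counts(self) -> dict[str, int]:
        keys, counts = np.unique(self.combination_keys(), return_counts=True)
        return dict(zip(keys.tolist(), counts.tolist()))

    # ------------------------------------------------------------------- I/O
    def save(self, directory: str | Path, image_format: str = "npz") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.labels.to_csv(directory / "labels.csv", index=False)
        with open(directory / "spec.yaml", "w") as fh:
            yaml.safe_dump({"resolution": int(self.resolution),
                            "label_names": list(self.label_names),
                            "image_format": image_format,
                            "meta": _plain(self.meta)}, fh)
        if image_format == "npz":
            np.savez(directory / "arrays.npz", images=self.images)
        elif image_format == "png":
            img_dir = directory / "images"
            img_dir.mkdir(exist_ok=True)
            for i, image_id in enumerate(self.labels["image_id"]):
                arr = np.clip(np.round(self.images[i] * 255.0), 0, 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(img_dir / f"{image_id}.png")
        else:
            raise ValueError(f"unknown image format {image_format!r}")

    @classmethod
    def load(cls, directory: str | Path) -> "DatasetStore":
        directory = Path(directory)
        with open(directory / "spec.yaml") as fh:
            spec = yaml.safe_load(fh)
        labels = pd.read_csv(directory / "labels.csv",
                             dtype={"image_id": str, "patient_id": str})
        if spec["image_format"] == "npz":
            images = np.load(directory / "arrays.npz")["images"]
        else:
            imgs = []
            for image_id in labels["image_id"]:
                arr = np.asarray(Image.open(directory / "images" / f"{image_id}.png"))
                imgs.append(arr.astype(np.float64) / 255.0)
            images = np.stack(imgs)
        return cls(images, labels, list(spec["label_names"]),
                   int(spec["resolution"]), spec.get("meta") or {})


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class BenchmarkSetting:
    """One benchmark configuration: resolution, class list and fold sizes."""

    resolution: int
    n_classes: int
    per_class: int
    n_binary_labels: int | None = None
    train_size: int | None = None
    val_size: int | None = None
    test_size: int | None = None
    classes: list[tuple[int, ...]] | None = None  # explicit combinations, optional

    def __post_init__(self):
        if self.train_size is None:
            self.train_size = self.n_classes * self.per_class
        elif self.train_size != self.n_classes * self.per_class:
            raise ValueError("balanced setting requires train_size == n_classes * per_class")
        if self.classes is not None and len(self.classes) != self.n_classes:
            raise ValueError("explicit class list length != n_classes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkSetting":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "classes" in raw and raw["classes"] is not None:
            raw["classes"] = [tuple(int(v) for v in combo) for combo in raw["classes"]]
        return cls(**raw)


# ----------------------------------------------------------- label handling
_UNCERTAIN_TOKENS = {"uncertain", "u", "-1", "-1.0"}


def binarize_labels(raw_table: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Map a raw label table to a strictly binary one.

    ``uncertain_positive``: entries in {0, 1, uncertain}; uncertain becomes 1.
    ``probability_positive``: entries are probabilities in [0, 1]; any p > 0
    becomes 1.
    """
    out = {}
    for col in raw_table.columns:
        vals = raw_table[col].to_numpy()
        if mode == "uncertain_positive":
            binary = np.empty(len(vals), dtype=np.int64)
            for i, v in enumerate(vals):
                sv = str(v).strip().lower()
                if sv in _UNCERTAIN_TOKENS:
                    binary[i] = 1
                elif sv in {"0", "0.0"}:
                    binary[i] = 0
                elif sv in {"1", "1.0"}:
                    binary[i] = 1
                else:
                    raise ValueError(f"unknown label symbol {v!r} in column {col!r}")
        elif mode == "probability_positive":
            probs = np.asarray(vals, dtype=np.float64)
            if np.any((probs < 0) | (probs > 1)) or np.any(~np.isfinite(probs)):
                raise ValueError(f"probability out of [0, 1] in column {col!r}")
            binary = (probs > 0).astype(np.int64)
        else:
            raise ValueError(f"unknown binarization mode {mode!r}")
        out[col] = binary
    return pd.DataFrame(out, index=raw_table.index)


def undersample_negative_class(store: DatasetStore, max_negative_fraction: float = 0.5,
                               seed: int = 0) -> DatasetStore:
    """Drop seeded-random all-zero ("no finding") records until their share is
    at most ``max_negative_fraction``. Positive records are untouched."""
    lm = store.label_matrix()
    neg = np.flatnonzero(lm.sum(axis=1) == 0)
    pos = np.flatnonzero(lm.sum(axis=1) > 0)
    if len(pos) == 0:
        raise ValueError("no positive records; undersampling undefined")
    # n_neg / (n_neg + n_pos) <= f  =>  n_neg <= f/(1-f) * n_pos
    max_neg = int(np.floor(max_negative_fraction / (1.0 - max_negative_fraction) * len(pos)))
    if len(neg) <= max_neg:
        return store
    rng = np.random.default_rng(seed)
    keep_neg = rng.choice(neg, size=max_neg, replace=False)
    keep = np.sort(np.concatenate([pos, keep_neg]))
    return store.subset(keep)


def largest_remainder_counts(n: int, fractions: Sequence[float],
                             rng: np.random.Generator | None = None) -> np.ndarray:
    """Apportion ``n`` items to bins by the largest-remainder method.

    Ties in the fractional remainders are broken by a seeded shuffle when a
    generator is supplied, otherwise by bin order.
    """
    fractions = np.asarray(fractions, dtype=np.float64)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    quotas = n * fractions
    counts = np.floor(quotas).astype(np.int64)
    remainders = quotas - counts
    missing = n - counts.sum()
    order = np.arange(len(fractions))
    if rng is not None:
        order = rng.permutation(order)
    order = order[np.argsort(-remainders[order], kind="stable")]
    for i in range(missing):
        counts[order[i]] += 1
    return counts


def _patient_strata(labels: pd.DataFrame, lm: np.ndarray) -> dict[str, str]:
    """Stratum key per patient: the patient's most frequent label combination
    (ties broken lexicographically)."""
    keys = np.array(["".join(map(str, row)) for row in lm])
    strata: dict[str, str] = {}
    for pid, grp in pd.Series(keys).groupby(labels["patient_id"].to_numpy()):
        counts = grp.value_counts()
        top = counts.max()
        strata[pid] = sorted(counts[counts == top].index)[0]
    return strata


def stratified_patient_split(store: DatasetStore,
                             fractions: Sequence[float] = (0.8, 0.1, 0.1),
                             seed: int = 0) -> DatasetStore:
    """Assign train/val/test folds at the patient level within label strata.

    Every patient's images land in exactly one fold; within each stratum the
    patient counts follow the fractions by largest-remainder apportionment.
    """
    fractions = np.asarray(fractions, dtype=np.float64)
    if len(fractions) != 3 or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must be a triple summing to 1")
    rng = np.random.default_rng(seed)
    strata = _patient_strata(store.labels, store.label_matrix())
    fold_of: dict[str, str] = {}
    by_stratum: dict[str, list[str]] = {}
    for pid, key in strata.items():
        by_stratum.setdefault(key, []).append(pid)
    for key in sorted(by_stratum):
        patients = sorted(by_stratum[key])
        rng.shuffle(patients)
        counts = largest_remainder_counts(len(patients), fractions, rng)
        start = 0
        for fold, c in zip(FOLDS, counts):
            for pid in patients[start:start + c]:
                fold_of[pid] = fold
            start += c
    labels = store.labels.copy()
    labels["fold"] = labels["patient_id"].map(fold_of)
    return DatasetStore(store.images, labels, list(store.label_names),
                        store.resolution, dict(store.meta))


def filter_rare_classes(store: DatasetStore, min_count: int) -> DatasetStore:
    """Remove every record whose exact label combination occurs fewer than
    ``min_count`` times in the store."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    keys = store.combination_keys()
    counts = pd.Series(keys).value_counts()
    surviving = set(counts[counts >= min_count].index)
    keep = np.flatnonzero(np.isin(keys, list(surviving)))
    if len(keep) == 0:
        raise ValueError("rare-class filtering removed every record")
    return store.subset(keep)


def _select_classes(train_keys: np.ndarray, n_classes: int) -> list[str]:
    counts = pd.Series(train_keys).value_counts()
    ordered = sorted(counts.index, key=lambda k: (-counts[k], k))
    if len(ordered) < n_classes:
        raise ValueError(f"only {len(ordered)} classes available, {n_classes} requested")
    return ordered[:n_classes]


def build_benchmark_setting(store: DatasetStore, setting: BenchmarkSetting,
                            seed: int = 0) -> DatasetStore:
    """Resample the train fold to exactly ``per_class`` records per class.

    Classes with fewer real records are oversampled with replacement
    (seeded); classes with more are subsampled without replacement. The
    val/test folds are restricted to the chosen classes and optionally
    subsampled to the configured sizes.
    """
    if store.resolution != setting.resolution:
        raise ValueError("store resolution does not match setting")
    rng = np.random.default_rng(seed)
    keys = store.combination_keys()
    folds = store.labels["fold"].to_numpy()
    train_mask = folds == "train"
    if setting.classes is not None:
        class_keys = ["".join(map(str, combo)) for combo in setting.classes]
        missing = [k for k in class_keys if not np.any(keys[train_mask] == k)]
        if missing:
            raise ValueError(f"requested classes absent from train fold: {missing}")
    else:
        class_keys = _select_classes(keys[train_mask], setting.n_classes)

    pieces: list[np.ndarray] = []
    dup_flags: list[np.ndarray] = []
    for key in class_keys:
        idx = np.flatnonzero(train_mask & (keys == key))
        if len(idx) >= setting.per_class:
            chosen = rng.choice(idx, size=setting.per_class, replace=False)
            dup = np.zeros(setting.per_class, dtype=bool)
        else:
            extra = rng.choice(idx, size=setting.per_class - len(idx), replace=True)
            chosen = np.concatenate([idx, extra])
            dup = np.concatenate([np.zeros(len(idx), dtype=bool),
                                  np.ones(len(extra), dtype=bool)])
        pieces.append(chosen)
        dup_flags.append(dup)

    def _restrict(fold: str, target: int | None) -> np.ndarray:
        idx = np.flatnonzero((folds == fold) & np.isin(keys, class_keys))
        if target is None or len(idx) <= target:
            return idx
        # proportional per-class subsample via largest remainder
        out = []
        sub_keys = keys[idx]
        uniq = sorted(set(sub_keys.tolist()))
        fracs = np.array([np.sum(sub_keys == k) for k in uniq], dtype=np.float64)
        counts = largest_remainder_counts(target, fracs / fracs.sum(), rng)
        for k, c in zip(uniq, counts):
            pool = idx[sub_keys == k]
            out.append(rng.choice(pool, size=min(c, len(pool)), replace=False))
        return np.sort(np.concatenate(out))

    train_idx = np.concatenate(pieces)
    dup_all = np.concatenate(dup_flags)
    val_idx = _restrict("val", setting.val_size)
    test_idx = _restrict("test", setting.test_size)

    all_idx = np.concatenate([train_idx, val_idx, test_idx])
    images = store.images[all_idx]
    labels = store.labels.iloc[all_idx].reset_index(drop=True)
    # oversampled duplicates need fresh unique image ids
    is_dup = np.concatenate([dup_all, np.zeros(len(val_idx) + len(test_idx), dtype=bool)])
    ids = labels["image_id"].to_numpy(dtype=object).copy()
    for i in np.flatnonzero(is_dup):
        ids[i] = f"{ids[i]}#dup{i}"
    labels["image_id"] = ids
    meta = dict(store.meta)
    meta["benchmark_setting"] = _plain(dataclasses.asdict(setting))
    return DatasetStore(images, labels, list(store.label_names), store.resolution, meta)


def make_equivalent_synthetic_folds(generator_handle: Callable[[np.ndarray, np.random.Generator], np.ndarray],
                                    real_store: DatasetStore,
                                    seed: int = 0) -> DatasetStore:
    """Build a synthetic twin of ``real_store``: one image per real record,
    conditioned on that record's labels, with fresh seeded noise.

    Label multisets and fold sizes of real and synthetic stores are identical
    by construction.
    """
    rng = np.random.default_rng(seed)
    lm = real_store.label_matrix()
    images = np.empty_like(real_store.images)
    for fold in FOLDS:
        idx = real_store.fold_indices(fold)
        if len(idx) == 0:
            continue
        out = generator_handle(lm[idx], rng)
        out = np.asarray(out, dtype=np.float64)
        if out.shape != (len(idx), real_store.resolution, real_store.resolution):
            raise ValueError("generator returned images with mismatched shape")
        images[idx] = out
    labels = real_store.labels.copy()
    labels["image_id"] = ["syn_" + str(i) for i in labels["image_id"]]
    labels["origin"] = "synthetic"
    return DatasetStore(images, labels, list(real_store.label_names),
                        real_store.resolution, dict(real_store.meta))
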