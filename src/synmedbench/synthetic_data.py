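"""Seeded multi-label toy image corpora.

Images are a shared elliptical background phantom plus one localized
geometric primitive per positive label (blob, line, ring or texture patch),
followed by additive Gaussian noise. Label information is therefore
spatially localized with a known ground truth, which downstream attribution
and privacy analyses can exploit. Pixels live in [0, 1]; patient ids are
assigned in consecutive blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import DatasetStore, largest_remainder_counts

__all__ = ["LesionDescriptor", "PhantomSpec", "ClassList",
           "generate_image", "generate_dataset", "lesion_mask", "default_spec"]

_PRIMITIVES = ("blob", "line", "ring", "texture")


@dataclass(frozen=True)
class LesionDescriptor:
    """One localized image feature: primitive kind, position, size, contrast."""

    kind: str                       # blob | line | ring | texture
    center: tuple[float, float]     # (row, col) as fractions of the image
    extent: float                   # radius / half-length as fraction
    contrast: float                 # additive intensity (image units)

    def __post_init__(self):
        if self.kind not in _PRIMITIVES:
            raise ValueError(f"unknown primitive {self.kind!r}")
        if not np.isfinite(self.contrast):
            raise ValueError("contrast must be finite")
        if not (0.0 < self.extent < 1.0):
            raise ValueError("extent must be a fraction in (0, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for the toy corpus: background phantom plus per-label lesions."""

    resolution: int
    label_names: tuple[str, ...]
    lesion_descriptors: dict[str, LesionDescriptor]
    background_axes: tuple[float, float] = (0.42, 0.36)  # ellipse semi-axes (fractions)
    background_intensity: float = 0.35
    noise_sigma: float = 0.02
    images_per_patient: int = 1

    def __post_init__(self):
        r = self.resolution
        if r < 8 or (r & (r - 1)) != 0:
            raise ValueError("resolution must be a power of two >= 8")
        if set(self.lesion_descriptors) != set(self.label_names):
            raise ValueError("every label needs exactly one lesion descriptor")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.images_per_patient < 1:
            raise ValueError("images_per_patient must be positive")

    def to_dict(self) -> dict:
        return {
            "resolution": self.resolution,
            "label_names": list(self.label_names),
            "lesion_descriptors": {
                name: {"kind": d.kind, "center": list(d.center),
                       "extent": d.extent, "contrast": d.contrast}
                for name, d in self.lesion_descriptors.items()},
            "background_axes": list(self.background_axes),
            "background_intensity": self.background_intensity,
            "noise_sigma": self.noise_sigma,
            "images_per_patient": self.images_per_patient,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "PhantomSpec":
        descs = {name: LesionDescriptor(d["kind"], tuple(d["center"]),
                                        d["extent"], d["contrast"])
                 for name, d in raw["lesion_descriptors"].items()}
        return cls(resolution=int(raw["resolution"]),
                   label_names=tuple(raw["label_names"]),
                   lesion_descriptors=descs,
                   background_axes=tuple(raw.get("background_axes", (0.42, 0.36))),
                   background_intensity=float(raw.get("background_intensity", 0.35)),
                   noise_sigma=float(raw.get("noise_sigma", 0.02)),
                   images_per_patient=int(raw.get("images_per_patient", 1)))


@dataclass(frozen=True)
class ClassList:
    """Distinct multi-hot label combinations; each combination is a class."""

    combinations: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        if len(self.combinations) == 0:
            raise ValueError("ClassList must be non-empty")
        n = len(self.combinations[0])
        for combo in self.combinations:
            if len(combo) != n:
                raise ValueError("all combinations must have equal length")
            if any(v not in (0, 1) for v in combo):
                raise ValueError("combinations must be multi-hot (0/1)")
        if len(set(self.combinations)) != len(self.combinations):
            raise ValueError("combinations must be distinct")

    @property
    def n_labels(self) -> int:
        return len(self.combinations[0])

    @classmethod
    def single_label(cls, n_labels: int, include_no_finding: bool = True) -> "ClassList":
        combos = []
        if include_no_finding:
            combos.append(tuple([0] * n_labels))
        for i in range(n_labels):
            combos.append(tuple(1 if j == i else 0 for j in range(n_labels)))
        return cls(tuple(combos))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassList":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(tuple(tuple(int(v) for v in combo) for combo in raw["combinations"]))


def default_spec(resolution: int = 32, n_labels: int = 3, contrast: float = 0.3,
                 noise_sigma: float = 0.02, images_per_patient: int = 1) -> PhantomSpec:
    """A ready-made spec with well-separated lesion positions."""
    kinds = ["blob", "ring", "line", "texture"]
    positions = [(0.30, 0.35), (0.30, 0.65), (0.62, 0.35), (0.62, 0.65),
                 (0.46, 0.50), (0.75, 0.50), (0.25, 0.50), (0.50, 0.30)]
    if n_labels > len(positions):
        raise ValueError(f"default_spec supports at most {len(positions)} labels")
    names = tuple(f"finding_{i}" for i in range(n_labels))
    descs = {names[i]: LesionDescriptor(kinds[i % len(kinds)], positions[i],
                                        0.12, contrast)
             for i in range(n_labels)}
    return PhantomSpec(resolution=resolution, label_names=names,
                       lesion_descriptors=descs, noise_sigma=noise_sigma,
                       images_per_patient=images_per_patient)


# ---------------------------------------------------------------- rendering
def _grid(resolution: int) -> tuple[np.ndarray, np.ndarray]:
    coords = (np.arange(resolution) + 0.5) / resolution
    return np.meshgrid(coords, coords, indexing="ij")


def background_phantom(spec: PhantomSpec) -> np.ndarray:
    yy, xx = _grid(spec.resolution)
    ay, ax = spec.background_axes
    ellipse = ((yy - 0.5) / ay) ** 2 + ((xx - 0.5) / ax) ** 2 <= 1.0
    return np.where(ellipse, spec.background_intensity, 0.0)


def lesion_mask(desc: LesionDescriptor, resolution: int) -> np.ndarray:
    """Boolean support of a primitive on the pixel grid."""
    yy, xx = _grid(resolution)
    cy, cx = desc.center
    r = desc.extent
    if desc.kind in ("blob", "texture"):
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    if desc.kind == "ring":
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        return (d2 <= r ** 2) & (d2 >= (0.55 * r) ** 2)
    if desc.kind == "line":
        thickness = max(1.5 / resolution, 0.25 * r)
        return (np.abs(yy - cy) <= thickness) & (np.abs(xx - cx) <= r)
    raise ValueError(desc.kind)


def _render_lesion(desc: LesionDescriptor, resolution: int) -> np.ndarray:
    mask = lesion_mask(desc, resolution)
    patch = np.where(mask, desc.contrast, 0.0)
    if desc.kind == "texture":
        yy, xx = np.indices((resolution, resolution))
        checker = ((yy + xx) % 2) * 2.0 - 1.0       # zero-mean on the mask (a.e.)
        patch = patch * (1.0 + 0.3 * checker)
    return patch


def generate_image(labels: Sequence[int], spec: PhantomSpec, seed: int) -> np.ndarray:
    """Render one grayscale image in [0, 1], deterministic in (labels, spec, seed)."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != (len(spec.label_names),):
        raise ValueError("label vector length does not match spec.label_names")
    img = background_phantom(spec)
    for name, on in zip(spec.label_names, labels):
        if on:
            img = img + _render_lesion(spec.lesion_descriptors[name], spec.resolution)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        img = np.clip(img, 0.0, 1.0)
    return img


def generate_dataset(spec: PhantomSpec, classes: ClassList, per_class: int,
                     fold_fractions: Sequence[float] = (0.8, 0.1, 0.1),
                     seed: int = 0) -> DatasetStore:
    """Render ``per_class`` images for every class with exact fold sizes.

    Patient ids are assigned in consecutive blocks of ``images_per_patient``
    within each class, so no patient spans classes; folds are assigned per
    patient with largest-remainder counts, keeping fold sizes exact whenever
    ``images_per_patient`` divides the per-fold image counts.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    if classes.n_labels != len(spec.label_names):
        raise ValueError("ClassList label dimension does not match spec")
    fold_fractions = np.asarray(fold_fractions, dtype=np.float64)
    if not np.isclose(fold_fractions.sum(), 1.0):
        raise ValueError("fold fractions must sum to 1")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    image_seeds = ss.generate_state(len(classes.combinations) * per_class, dtype=np.uint32)

    images, rows = [], []
    patient_counter = 0
    k = 0
    for ci, combo in enumerate(classes.combinations):
        n_patients = int(np.ceil(per_class / spec.images_per_patient))
        patient_ids = [f"p{patient_counter + i:05d}" for i in range(n_patients)]
        patient_counter += n_patients
        counts = largest_remainder_counts(n_patients, fold_fractions, rng)
        patient_fold = {}
        start = 0
        for fold, c in zip(("train", "val", "test"), counts):
            for pid in patient_ids[start:start + c]:
                patient_fold[pid] = fold
            start += c
        for j in range(per_class):
            pid = patient_ids[j // spec.images_per_patient]
            images.append(generate_image(combo, spec, int(image_seeds[k])))
            rows.append({"image_id": f"img{k:06d}", "patient_id": pid,
                         "fold": patient_fold[pid], "origin": "real",
                         **{name: int(v) for name, v in zip(spec.label_names, combo)}})
            k += 1
    labels = pd.DataFrame(rows)
    store = DatasetStore(np.stack(images), labels, list(spec.label_names),
                         spec.resolution, {"phantom_spec": spec.to_dict()})
    return store
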