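"""End-to-end benchmark orchestration.

For each seed: train (or inject) a conditional generator on the real train
fold, synthesise label-equivalent folds, train one classifier on the real
and one on the synthetic train fold, evaluate both on the real test fold and
collect the utility gap (AUC_real - AUC_syn) and the label-overfitting
statistic delta_syn. Extrema comparisons use the one-sided Mann-Whitney U
test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classifier import ClassifierConfig, evaluate_mean_auc, train_classifier
from .datasets import (BenchmarkSetting, DatasetStore, build_benchmark_setting,
                       make_equivalent_synthetic_folds)
from .fid import EmbeddingModel, FidController, FidProtocol
from .gan import GanConfig, generator_handle, train_gan
from .stats import mann_whitney_u

__all__ = ["SeedResult", "BenchmarkResult", "run_benchmark_setting",
           "delta_syn", "mann_whitney_extrema",
           "fold_replay_factory", "corner_tag_factory", "noisy_replay_factory"]


@dataclass
class SeedResult:
    seed: int
    auc_real: float
    auc_syn: float
    delta_auc: float
    delta_syn: float
    fid_trace: list = field(default_factory=list)
    failed: bool = False
    failure_cause: str = ""


@dataclass
class BenchmarkResult:
    setting: BenchmarkSetting
    per_seed: list[SeedResult]

    @property
    def delta_aucs(self) -> np.ndarray:
        return np.array([r.delta_auc for r in self.per_seed if not r.failed])

    @property
    def delta_syns(self) -> np.ndarray:
        return np.array([r.delta_syn for r in self.per_seed if not r.failed])

    def summary(self) -> dict:
        d = self.delta_aucs
        s = self.delta_syns
        return {"n_seeds": len(d),
                "mean_delta_auc": float(d.mean()) if len(d) else float("nan"),
                "sd_delta_auc": float(d.std(ddof=1)) if len(d) > 1 else float("nan"),
                "mean_delta_syn": float(s.mean()) if len(s) else float("nan"),
                "n_failed": sum(r.failed for r in self.per_seed)}

    def to_json(self, path: str | Path) -> None:
        payload = {"setting": dataclasses.asdict(self.setting),
                   "per_seed": [dataclasses.asdict(r) for r in self.per_seed],
                   "summary": self.summary()}
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def delta_syn(classifier, syn_test: DatasetStore, real_test: DatasetStore) -> float:
    """AUC on the synthetic test fold minus AUC on the real test fold for a
    synthetic-trained classifier. Folds must be label-equivalent."""
    syn_lm = sorted(map(tuple, syn_test.label_matrix()))
    real_lm = sorted(map(tuple, real_test.label_matrix()))
    if syn_lm != real_lm:
        raise ValueError("test folds are not label-equivalent")
    auc_on_syn = evaluate_mean_auc(classifier, syn_test).mean_auc
    auc_on_real = evaluate_mean_auc(classifier, real_test).mean_auc
    return float(auc_on_syn - auc_on_real)


def mann_whitney_extrema(sample_a: Sequence[float], sample_b: Sequence[float],
                         alternative: str = "greater") -> tuple[float, float]:
    """One-sided Mann-Whitney U test between the two extreme settings'
    score distributions. Returns (U statistic of sample_a, p-value)."""
    return mann_whitney_u(sample_a, sample_b, alternative=alternative)


def run_benchmark_setting(real_store: DatasetStore, setting: BenchmarkSetting,
                          gan_config: GanConfig, clf_config: ClassifierConfig,
                          seeds: Sequence[int],
                          generator_factory: Callable | None = None,
                          fid_protocol: FidProtocol | None = None,
                          embedder: EmbeddingModel | None = None) -> BenchmarkResult:
    """Execute one benchmark setting over the given seeds.

    ``generator_factory(built_store, rng) -> handle`` may replace GAN
    training with an injected generator (e.g. for oracle analyses); the
    handle maps (label matrix, rng) to images in [0, 1]. Synthetic images
    are pre-computed once per seed, never resampled per batch. A failed
    stage aborts that seed with a logged cause; the partial result is
    flagged.
    """
    if len(seeds) == 0:
        raise ValueError("at least one seed is required")
    results: list[SeedResult] = []
    for seed in seeds:
        ss = np.random.SeedSequence(seed)
        data_s, gan_s, synth_s, clf_real_s, clf_syn_s = ss.generate_state(5).tolist()
        try:
            built = build_benchmark_setting(real_store, setting, seed=data_s)
            fid_trace: list = []
            if generator_factory is not None:
                handle = generator_factory(built, np.random.default_rng(gan_s))
            else:
                cfg = dataclasses.replace(gan_config, seed=gan_s)
                train_fold = built.fold("train")
                controller = None
                if fid_protocol is not None:
                    emb = embedder or EmbeddingModel.default(built.resolution)
                    controller = FidController(fid_protocol, emb,
                                               train_fold.images,
                                               train_fold.label_matrix(), seed=gan_s)
                generator, state = train_gan(train_fold, cfg, controller, seed=gan_s)
                handle = generator_handle(generator)
                fid_trace = state.fid_trace
            syn = make_equivalent_synthetic_folds(handle, built, seed=synth_s)

            cfg_r = dataclasses.replace(clf_config, seed=clf_real_s)
            cfg_s = dataclasses.replace(clf_config, seed=clf_syn_s)
            clf_real, _ = train_classifier(built.fold("train"), built.fold("val"), cfg_r)
            clf_syn, _ = train_classifier(syn.fold("train"), syn.fold("val"), cfg_s)

            real_test = built.fold("test")
            auc_real = evaluate_mean_auc(clf_real, real_test).mean_auc
            auc_syn = evaluate_mean_auc(clf_syn, real_test).mean_auc
            dsyn = delta_syn(clf_syn, syn.fold("test"), real_test)
            results.append(SeedResult(seed=seed, auc_real=auc_real, auc_syn=auc_syn,
                                      delta_auc=float(auc_real - auc_syn),
                                      delta_syn=dsyn, fid_trace=fid_trace))
        except Exception as exc:  # noqa: BLE001 - per-seed isolation is the contract
            results.append(SeedResult(seed=seed, auc_real=float("nan"),
                                      auc_syn=float("nan"), delta_auc=float("nan"),
                                      delta_syn=float("nan"), failed=True,
                                      failure_cause=f"{type(exc).__name__}: {exc}"))
    return BenchmarkResult(setting=setting, per_seed=results)


# ------------------------------------------------- diagnostic oracle generators
def fold_replay_factory(built: DatasetStore, rng: np.random.Generator | None = None):
    """Identity oracle: replays each real fold verbatim as its synthetic twin.

    Useful as a ground-truth diagnostic — the utility gap of a perfect
    generator is sampling noise only and delta_syn is exactly zero. The
    handle is stateful: it expects one call per non-empty fold, in
    train/val/test order (the synthesis contract).
    """
    lm = built.label_matrix()
    pending = [f for f in ("train", "val", "test")
               if len(built.fold_indices(f)) > 0]

    def handle(labels: np.ndarray, _rng: np.random.Generator) -> np.ndarray:
        if not pending:
            raise ValueError("more fold requests than real folds")
        fold = pending.pop(0)
        idx = built.fold_indices(fold)
        if len(idx) != len(labels) or not np.array_equal(lm[idx], labels):
            raise ValueError(f"label block does not match the {fold} fold")
        return built.images[idx].copy()

    return handle


def noisy_replay_factory(built: DatasetStore, sigma: float):
    """Fold replay plus label-independent Gaussian pixel noise at level sigma."""
    replay = fold_replay_factory(built)

    def handle(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        images = replay(labels, rng)
        if sigma > 0:
            images = np.clip(images + rng.normal(0.0, sigma, images.shape), 0.0, 1.0)
        return images

    return handle


def corner_tag_factory(built: DatasetStore, rng: np.random.Generator | None = None,
                       tag_size: int = 4):
    """Label-overfitting oracle: emits a label-independent base image plus a
    corner tag whose brightness encodes the class index.

    A classifier trained on these synthetics keys on the tag, which is absent
    from real images, so its synthetic-test score far exceeds its real-test
    score — the constructed signature of unrealistic label encoding (large
    positive delta_syn in expectation over training seeds; a single seed's
    off-distribution transfer to real images is random)."""
    base = built.images[built.fold_indices("train")].mean(axis=0)
    combos = sorted({tuple(row) for row in built.label_matrix()})
    index = {c: i for i, c in enumerate(combos)}

    def handle(labels: np.ndarray, _rng: np.random.Generator) -> np.ndarray:
        out = np.repeat(base[None], len(labels), axis=0)
        for i, row in enumerate(labels):
            k = index[tuple(int(v) for v in row)]
            out[i, :tag_size, :tag_size] = k / max(len(combos) - 1, 1)
        return out

    return handle


def summary_frame(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {"n_classes": res.setting.n_classes,
               "per_class": res.setting.per_class,
               "resolution": res.setting.resolution}
        row.update(res.summary())
        rows.append(row)
    return pd.DataFrame(rows)
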