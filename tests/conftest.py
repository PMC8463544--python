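import numpy as np
import pytest

from synmedbench.benchmark import (corner_tag_factory, fold_replay_factory,
                                   run_benchmark_setting)
from synmedbench.classifier import ClassifierConfig, train_classifier
from synmedbench.datasets import BenchmarkSetting
from synmedbench.gan import GanConfig
from synmedbench.synthetic_data import (ClassList, LesionDescriptor, PhantomSpec,
                                        default_spec, generate_dataset)


@pytest.fixture(scope="session")
def toy_spec16():
    """Two brightness-matched lesion shapes (equal pixel area x contrast) so
    that classes are separable by shape but not by global statistics."""
    blob = LesionDescriptor("blob", (0.38, 0.38), 0.14, 0.35)
    ring = LesionDescriptor("ring", (0.58, 0.62), 0.168, 0.35)
    return PhantomSpec(resolution=16, label_names=("finding_0", "finding_1"),
                       lesion_descriptors={"finding_0": blob, "finding_1": ring},
                       noise_sigma=0.03)


@pytest.fixture(scope="session")
def toy_classes2():
    return ClassList(((1, 0), (0, 1)))


@pytest.fixture(scope="session")
def toy_store16(toy_spec16, toy_classes2):
    """Two well-separated single-label classes at 16 px, 60 images each."""
    return generate_dataset(toy_spec16, toy_classes2, per_class=60, seed=101)


@pytest.fixture(scope="session")
def fast_clf_config():
    return ClassifierConfig(input_size=None, batch_size=16, learning_rate=3e-3,
                            channels=(6, 12), max_epochs=10, seed=0)


@pytest.fixture(scope="session")
def toy_setting16():
    return BenchmarkSetting(resolution=16, n_classes=2, per_class=48)


@pytest.fixture(scope="session")
def toy_gan_config():
    return GanConfig(kind="cpd", resolution=16, latent_dim=16, n_labels=2,
                     max_channels=16, batch_size=8, learning_rate=2e-3,
                     max_images=400, seed=0)


@pytest.fixture(scope="session")
def trained_toy_classifier(toy_store16, fast_clf_config):
    model, log = train_classifier(toy_store16.fold("train"),
                                  toy_store16.fold("val"), fast_clf_config)
    return model, log


@pytest.fixture(scope="session")
def identity_benchmark_result(toy_store16, toy_setting16, toy_gan_config,
                              fast_clf_config):
    """Benchmark run with the fold-replay (identity) oracle, 4 seeds."""
    return run_benchmark_setting(toy_store16, toy_setting16, toy_gan_config,
                                 fast_clf_config, seeds=[0, 1, 2, 3],
                                 generator_factory=fold_replay_factory)


@pytest.fixture(scope="session")
def corner_tag_benchmark_result(toy_store16, toy_setting16, toy_gan_config,
                                fast_clf_config):
    """Benchmark run with the corner-tag (label-overfitting) oracle, 4 seeds."""
    return run_benchmark_setting(toy_store16, toy_setting16, toy_gan_config,
                                 fast_clf_config, seeds=[0, 1, 2, 3],
                                 generator_factory=corner_tag_factory)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
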