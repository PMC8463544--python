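# synmedbench

Benchmark toolkit for evaluating **synthetic medical-image sharing**: train
conditional GANs on a multi-label image corpus, stop training when the
Fréchet distance between real and synthetic feature distributions converges,
synthesise label-equivalent data folds, and measure how much downstream
utility is lost when classifiers are trained on synthetic instead of real
data — plus the accompanying diagnostics (label-overfitting statistic,
occlusion feature importance, nearest-neighbour privacy audit, reader-study
statistics).

Everything runs end to end on CPU against a built-in, fully seeded
multi-label phantom image generator, so no external data or pretrained
weights are required. The neural-network stack (including double
backpropagation for the gradient penalty) is implemented on numpy inside the
package.

## Modules

| Module | Contents |
| --- | --- |
| `synmedbench.synthetic_data` | Seeded phantom corpora: elliptical background + per-label geometric lesions, patient grouping, exact per-class/fold bookkeeping |
| `synmedbench.datasets` | `DatasetStore` data model; label binarization, no-finding undersampling, patient-stratified splitting, rare-combination filtering, benchmark-setting construction with oversampling, label-equivalent synthetic folds |
| `synmedbench.gan` | Conditional generators: progressive-growing reference model (WGAN-GP + auxiliary classifier, minibatch stddev, equalized learning rate) and the projection-discriminator model with conditionally normalised pixel features and an output-skip generator |
| `synmedbench.fid` | Gaussian feature summaries, squared Fréchet distance, fixed-N sampling with real-image cycling, two-strike convergence controller |
| `synmedbench.classifier` | Multi-label CNN (small CNN default, densenet-style option with a 1024-d penultimate layer), plateau LR schedule and early stopping, per-label AUROC |
| `synmedbench.benchmark` | Orchestration across seeds: AUC_real − AUC_syn, delta_syn, Mann-Whitney extrema tests, diagnostic oracle generators |
| `synmedbench.analysis` | Occlusion attribution maps, cosine nearest-neighbour audit, reader-study accuracy + Wilcoxon test |

## CLI

```bash
# generate a toy corpus (labels.csv + arrays.npz/images/*.png + spec.yaml)
synth-data --resolution 32 --classes-file classes.yaml --per-class 100 --seed 7 --out data/

# train a conditional GAN with FID-based stopping, then sample from it
train-gan --config gan.yaml --data data/ --seed 1 --out ckpt/gan.npz
gan-generate --ckpt ckpt/gan.npz --labels data/labels.csv --seed 11 --out synth/

# train/evaluate the downstream classifier
train-classifier --data data/ --config clf.yaml --out clfout/

# run benchmark settings end to end (per-seed JSON + summary CSV)
run-benchmark --data data/ --settings settings.yaml --seeds 4 --out results/
```

`classes.yaml` holds `combinations:` (a list of multi-hot vectors, one per
class); `gan.yaml`/`clf.yaml` mirror the keyword arguments of `GanConfig`
and `ClassifierConfig`; `settings.yaml` is a list of benchmark-setting
mappings (resolution, `n_classes`, `per_class`, optional `gan:`/`classifier:`
overrides).

## Conventions

- Images are grayscale, stored in `[0, 1]`, and mapped affinely to `[-1, 1]`
  at model input.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence` fan-out); identical inputs
  reproduce byte-identical corpora.
- FID values are comparable only within one embedding model; the default is
  a small fixed-seed convolutional encoder (an Inception-style extractor can
  be plugged in via `fid.EmbeddingModel`).
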