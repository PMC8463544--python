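import numpy as np
import pytest

from synmedbench.autodiff import Tensor, grad
from synmedbench.fid import (EmbeddingModel, FidController, FidProtocol,
                             assemble_fid_sample, compute_fid)
from synmedbench.gan import (ConditionalNormParams, GanConfig, build_models,
                             conditional_pixel_norm, generate, generator_handle,
                             gradient_penalty, load_checkpoint, losses,
                             minibatch_stddev_channel, pixel_norm,
                             progressive_schedule, projection_score,
                             save_checkpoint, train_gan)
from synmedbench.nnet import Dense


# ------------------------------------------------------ conditional pixel norm
def _norm_params(rng, cond_dim, channels):
    return ConditionalNormParams(cond_dim, channels, rng)


def test_cpn_degenerate_params_reduce_to_pixel_norm(rng):
    """W1=0, b1=1, W2=0, b2=0 recovers plain pixel-wise normalisation."""
    params = _norm_params(rng, 6, 4)
    params.W1.data[:] = 0.0
    params.b1.data[:] = 1.0
    params.W2.data[:] = 0.0
    params.b2.data[:] = 0.0
    a = Tensor(rng.normal(size=(2, 4, 3, 3)))
    z, y = Tensor(rng.normal(size=(2, 4))), Tensor(rng.integers(0, 2, (2, 2)).astype(float))
    out = conditional_pixel_norm(a, z, y, params)
    np.testing.assert_allclose(out.data, pixel_norm(a).data, atol=1e-12)


def test_cpn_equal_channels_self_normalize(rng):
    params = _norm_params(rng, 4, 3)
    params.W1.data[:] = 0.0
    params.b1.data[:] = 1.0
    params.W2.data[:] = 0.0
    params.b2.data[:] = 0.0
    a = Tensor(np.full((1, 3, 2, 2), 0.7))
    out = conditional_pixel_norm(a, Tensor(np.zeros((1, 2))),
                                 Tensor(np.zeros((1, 2))), params)
    np.testing.assert_allclose(out.data, 1.0, atol=1e-6)


def test_cpn_matches_scalar_oracle(rng):
    """Per-channel hand evaluation of the conditioning equation."""
    params = _norm_params(rng, 5, 4)
    a = rng.normal(size=(2, 4, 2, 2))
    z = rng.normal(size=(2, 3))
    y = rng.integers(0, 2, (2, 2)).astype(float)
    out = conditional_pixel_norm(Tensor(a), Tensor(z), Tensor(y), params)
    zy = np.concatenate([z, y], axis=1)
    gamma = zy @ params.W1.data + params.b1.data
    beta = zy @ params.W2.data + params.b2.data
    for b in range(2):
        for x in range(2):
            for w in range(2):
                rms = np.sqrt(np.mean(a[b, :, x, w] ** 2) + 1e-8)
                for i in range(4):
                    expected = a[b, i, x, w] / rms * gamma[b, i] + beta[b, i]
                    assert out.data[b, i, x, w] == pytest.approx(expected, abs=1e-10)


def test_cpn_unit_rms_invariant(rng):
    params = _norm_params(rng, 4, 8)
    params.W1.data[:] = 0.0
    params.b1.data[:] = 1.0
    params.W2.data[:] = 0.0
    params.b2.data[:] = 0.0
    a = Tensor(rng.normal(size=(3, 8, 4, 4)) * 10.0)   # RMS >> sqrt(eps)
    out = conditional_pixel_norm(a, Tensor(np.zeros((3, 2))),
                                 Tensor(np.zeros((3, 2))), params)
    ms = (out.data ** 2).mean(axis=1)
    np.testing.assert_allclose(ms, 1.0, atol=1e-6)


def test_cpn_dimension_mismatch(rng):
    params = _norm_params(rng, 4, 3)
    with pytest.raises(ValueError):
        conditional_pixel_norm(Tensor(np.zeros((1, 5, 2, 2))),
                               Tensor(np.zeros((1, 2))),
                               Tensor(np.zeros((1, 2))), params)


# ----------------------------------------------------------- projection score
def test_projection_zero_labels_gives_unconditional(rng):
    head = Dense(4, 1, rng, equalized=False)
    emb = Tensor(rng.normal(size=(3, 4)))
    feats = Tensor(rng.normal(size=(2, 4)))
    y0 = Tensor(np.zeros((2, 3)))
    out = projection_score(feats, y0, emb, head)
    np.testing.assert_allclose(out.data, head(feats).data, atol=1e-12)


def test_projection_linear_in_y(rng):
    head = Dense(4, 1, rng, equalized=False)
    emb = Tensor(rng.normal(size=(3, 4)))
    feats = Tensor(rng.normal(size=(2, 4)))
    y1 = Tensor(rng.normal(size=(2, 3)))
    y2 = Tensor(rng.normal(size=(2, 3)))
    s1 = projection_score(feats, y1, emb, head).data - head(feats).data
    s2 = projection_score(feats, y2, emb, head).data - head(feats).data
    s12 = projection_score(feats, y1 + y2, emb, head).data - head(feats).data
    np.testing.assert_allclose(s12, s1 + s2, atol=1e-10)
    doubled = projection_score(feats, y1 * 2.0, emb, head).data - head(feats).data
    np.testing.assert_allclose(doubled, 2 * s1, atol=1e-10)


def test_projection_hand_computed(rng):
    head = Dense(3, 1, rng, equalized=False)
    head.weight.data[:] = 0.0
    head.bias.data[:] = 0.0
    emb = Tensor(np.array([[1.0, 0.0, 2.0], [0.0, 1.0, -1.0]]))
    feats = Tensor(np.array([[0.5, 1.0, 2.0]]))
    y = Tensor(np.array([[1.0, 1.0]]))
    # embed(y) = (1, 1, 1); <embed, feats> = 0.5 + 1 + 2
    assert projection_score(feats, y, emb, head).data[0, 0] == pytest.approx(3.5)


def test_projection_dim_mismatch(rng):
    head = Dense(4, 1, rng, equalized=False)
    with pytest.raises(ValueError):
        projection_score(Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 2))),
                         Tensor(np.zeros((3, 4))), head)


# ------------------------------------------------------------ minibatch stddev
def test_mbstd_identical_members_zero(rng):
    x = Tensor(np.tile(rng.normal(size=(1, 2, 3, 3)), (4, 1, 1, 1)))
    out = minibatch_stddev_channel(x)
    assert out.shape == (4, 3, 3, 3)
    np.testing.assert_allclose(out.data[:, -1], 0.0, atol=1e-4)


def test_mbstd_shift_invariant(rng):
    x = rng.normal(size=(4, 2, 3, 3))
    a = minibatch_stddev_channel(Tensor(x)).data[:, -1]
    b = minibatch_stddev_channel(Tensor(x + 5.0)).data[:, -1]
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_mbstd_closed_form_two_elements():
    x = Tensor(np.array([0.0, 2.0]).reshape(2, 1, 1, 1))
    out = minibatch_stddev_channel(x)
    # population std of {0, 2} = 1
    np.testing.assert_allclose(out.data[:, -1], 1.0, atol=1e-6)


def test_mbstd_batch_of_one_is_zero_channel(rng):
    out = minibatch_stddev_channel(Tensor(rng.normal(size=(1, 2, 2, 2))))
    assert out.shape == (1, 3, 2, 2)
    np.testing.assert_array_equal(out.data[:, -1], 0.0)


# --------------------------------------------------------------------- losses
def test_gradient_penalty_unit_norm_zero(rng):
    g = rng.normal(size=(4, 1, 2, 2))
    g /= np.linalg.norm(g.reshape(4, -1), axis=1)[:, None, None, None]
    assert gradient_penalty(Tensor(g), 10.0).item() == pytest.approx(0.0, abs=1e-6)


def test_gradient_penalty_analytic_slope_two():
    """A 1-D critic f(x) = 2x has input gradient 2: penalty = w * (2-1)^2."""
    g = Tensor(np.full((3, 1), 2.0))
    assert gradient_penalty(g, 10.0).item() == pytest.approx(10.0, rel=1e-9)


def test_losses_cpd_has_no_aux_terms(rng):
    cfg = GanConfig(kind="cpd", resolution=8, n_labels=2, max_images=0)
    real = Tensor(rng.normal(size=(4, 1)))
    fake = Tensor(rng.normal(size=(4, 1)))
    g = Tensor(np.ones((4, 1)))
    g_loss, d_loss = losses(real, fake, g, cfg)
    assert g_loss.item() == pytest.approx(-fake.data.mean())
    assert d_loss.item() == pytest.approx(fake.data.mean() - real.data.mean())


def test_losses_prog_requires_logits(rng):
    cfg = GanConfig(kind="prog", resolution=8, n_labels=2, max_images=0)
    real = Tensor(rng.normal(size=(4, 1)))
    with pytest.raises(ValueError):
        losses(real, real, Tensor(np.ones((4, 1))), cfg)


def test_losses_prog_adds_aux_terms(rng):
    cfg = GanConfig(kind="prog", resolution=8, n_labels=2, aux_weight=1.0,
                    max_images=0)
    real = Tensor(np.zeros((4, 1)))
    fake = Tensor(np.zeros((4, 1)))
    g = Tensor(np.ones((4, 1)))
    labels = np.array([[1, 0]] * 4)
    logits = Tensor(rng.normal(size=(4, 2)))
    g_loss, d_loss = losses(real, fake, g, cfg, labels=labels,
                            real_logits=logits, fake_logits=logits)
    assert g_loss.item() > 0.0                 # aux CE dominates zero scores
    assert d_loss.item() > 0.0


# ------------------------------------------------------------------- schedule
def test_progressive_schedule_paper_budgets():
    sch = progressive_schedule(8, 32, 1.4e6)
    assert len(sch) == 5
    assert sch[-1]["cumulative_images"] == pytest.approx(7.0e6)
    sch = progressive_schedule(8, 128, 1e6)
    assert len(sch) == 9
    assert sch[-1]["cumulative_images"] == pytest.approx(9.0e6)


def test_progressive_schedule_trivial_and_structure():
    sch = progressive_schedule(16, 16, 100)
    assert len(sch) == 1 and sch[0]["kind"] == "stabilize"
    sch = progressive_schedule(8, 16, 10)
    assert [p["kind"] for p in sch] == ["stabilize", "transition", "stabilize"]
    assert [p["resolution"] for p in sch] == [8, 16, 16]


# ----------------------------------------------------------------- generation
@pytest.mark.parametrize("kind", ["cpd", "prog"])
@pytest.mark.parametrize("resolution", [8, 16, 32, 64])
def test_forward_shapes_across_resolutions(kind, resolution):
    cfg = GanConfig(kind=kind, resolution=resolution, start_resolution=8,
                    latent_dim=8, n_labels=2, max_channels=8, max_images=0)
    g, d = build_models(cfg)
    labels = np.array([[1, 0], [0, 1]])
    imgs = generate(g, labels, seed=0)
    assert imgs.shape == (2, resolution, resolution)
    assert imgs.min() >= -1.0 and imgs.max() <= 1.0
    x = Tensor(np.random.default_rng(0).normal(size=(2, 1, resolution, resolution)))
    if kind == "cpd":
        assert d(x, Tensor(labels.astype(float))).shape == (2, 1)
    else:
        score, aux = d(x)
        assert score.shape == (2, 1) and aux.shape == (2, 2)


def test_generate_deterministic_and_seed_sensitive(toy_gan_config):
    g, _ = build_models(toy_gan_config)
    labels = np.array([[1, 0], [0, 1]])
    a = generate(g, labels, seed=5)
    b = generate(g, labels, seed=5)
    c = generate(g, labels, seed=6)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_generate_rejects_bad_labels(toy_gan_config):
    g, _ = build_models(toy_gan_config)
    with pytest.raises(ValueError):
        generate(g, np.array([[1, 0, 1]]), seed=0)
    with pytest.raises(ValueError):
        generate(g, np.array([[2, 0]]), seed=0)


def test_zero_budget_depends_only_on_init_seed(toy_store16, toy_gan_config):
    import dataclasses
    cfg = dataclasses.replace(toy_gan_config, max_images=0)
    gen, state = train_gan(toy_store16.fold("train"), cfg, controller=None, seed=3)
    assert state.g_steps == 0
    gen2, _ = build_models(cfg)
    np.testing.assert_array_equal(generate(gen, np.array([[1, 0]]), 1),
                                  generate(gen2, np.array([[1, 0]]), 1))


# ------------------------------------------------------------ training smoke
def test_cpd_training_improves_fid(toy_store16):
    """Short adversarial run: FID at stop is below FID at initialisation."""
    tr = toy_store16.fold("train")
    cfg = GanConfig(kind="cpd", resolution=16, latent_dim=16, n_labels=2,
                    max_channels=16, batch_size=8, learning_rate=2e-3,
                    max_images=880, seed=1)
    emb = EmbeddingModel.default(16, seed=0)
    proto = FidProtocol(N=96, eval_cadence=200, patience=2, min_images=480)
    ctrl = FidController(proto, emb, tr.images, tr.label_matrix(), seed=2)
    g0, _ = build_models(cfg)
    reals, synth = assemble_fid_sample(tr.images, tr.label_matrix(), 96,
                                       generator_handle(g0), seed=2)
    fid_init = compute_fid(reals, synth, emb)
    gen, state = train_gan(tr, cfg, ctrl, seed=1)
    assert state.fid_trace, "controller never evaluated"
    assert min(f for _, f in state.fid_trace) < fid_init
    assert state.images_seen > 0


def test_prog_training_advances_phases(toy_store16):
    """Tiny growth run 8->16 crosses the transition into the final phase."""
    tr = toy_store16.fold("train")
    cfg = GanConfig(kind="prog", resolution=16, start_resolution=8,
                    latent_dim=8, n_labels=2, max_channels=8, batch_size=8,
                    learning_rate=1e-3, images_per_phase=64, max_images=200,
                    seed=0)
    gen, state = train_gan(tr, cfg, controller=None, seed=0)
    assert state.phase_index == 2              # stabilize(8), transition, stabilize(16)
    assert state.stop_reason == "max_images"
    imgs = generate(gen, np.array([[1, 0]]), seed=0)
    assert imgs.shape == (1, 16, 16)


def test_checkpoint_roundtrip(tmp_path, toy_gan_config):
    g, _ = build_models(toy_gan_config)
    state_in = __import__("synmedbench.gan", fromlist=["TrainState"]).TrainState(
        images_seen=10, seed=4)
    path = tmp_path / "gan.npz"
    save_checkpoint(path, g, toy_gan_config, state_in)
    g2, cfg2, meta = load_checkpoint(path)
    assert cfg2 == toy_gan_config
    assert meta["images_seen"] == 10
    labels = np.array([[0, 1]])
    np.testing.assert_array_equal(generate(g, labels, 9), generate(g2, labels, 9))
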