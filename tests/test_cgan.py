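"""Surrogate model: layer gradients, determinism, prediction contracts.

The full 50-pair / 5-epoch smoke training lives in the acceptance suite;
here training runs are kept tiny.
"""

import numpy as np
import pytest

from jcwmh._nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    InstanceNorm,
    bce_with_logits,
    bce_with_logits_grad,
)
from jcwmh.cgan import (
    Generator,
    PatchDiscriminator,
    TrainConfig,
    classify_with_surrogate,
    normalize_flair,
    predict_gm,
    train,
)
from jcwmh.classify import classify_all
from jcwmh.rasters import BinaryMask, IntensityImage, VolumeGeometry


def finite_diff_ok(layer, x, loss_of_output, n_checks=4, eps=1e-6, tol=1e-6):
    rng = np.random.default_rng(0)
    y = layer.forward(x)
    # analytic grads via a simple quadratic-style loss callback
    dy = loss_of_output(y, grad=True)
    for g in layer.grads.values():
        g[...] = 0.0
    layer.backward(dy)
    for name, p in layer.params.items():
        for _ in range(n_checks):
            idx = tuple(rng.integers(s) for s in p.shape)
            p[idx] += eps
            lp = loss_of_output(layer.forward(x))
            p[idx] -= 2 * eps
            lm = loss_of_output(layer.forward(x))
            p[idx] += eps
            num = (lp - lm) / (2 * eps)
            if abs(num - layer.grads[name][idx]) > tol * max(1.0, abs(num)):
                return False
    return True


@pytest.mark.parametrize(
    "layer_factory,x_shape",
    [
        (lambda rng: Conv2d(2, 3, rng=rng), (2, 2, 8, 8)),
        (lambda rng: Conv2d(3, 1, k=4, stride=1, pad=1, rng=rng), (1, 3, 8, 8)),
        (lambda rng: ConvTranspose2d(3, 2, rng=rng), (2, 3, 4, 4)),
        (lambda rng: InstanceNorm(3), (2, 3, 6, 6)),
    ],
)
def test_layer_gradients_match_finite_differences(layer_factory, x_shape):
    rng = np.random.default_rng(7)
    layer = layer_factory(np.random.default_rng(1))
    x = rng.normal(size=x_shape)
    tgt = rng.random(np.shape(layer.forward(x)))

    def loss(y, grad=False):
        if grad:
            return 2 * (y - tgt) / y.size
        return float(np.mean((y - tgt) ** 2) * 1.0)

    assert finite_diff_ok(layer, x, loss)


def test_generator_gradient_through_skips():
    rng = np.random.default_rng(3)
    gen = Generator(4, np.random.default_rng(2))
    x = rng.normal(size=(1, 1, 8, 8))
    tgt = (rng.random((1, 1, 8, 8)) > 0.5).astype(float)
    y = gen.forward(x)
    for l in gen.layers:
        for g in l.grads.values():
            g[...] = 0.0
    gen.backward(np.sign(y - tgt) / y.size)
    eps = 1e-6
    for layer in (gen.e1, gen.d3, gen.n2):
        p = layer.params[next(iter(layer.params))]
        idx = tuple(rng.integers(s) for s in p.shape)
        p[idx] += eps
        lp = float(np.abs(gen.forward(x) - tgt).mean())
        p[idx] -= 2 * eps
        lm = float(np.abs(gen.forward(x) - tgt).mean())
        p[idx] += eps
        num = (lp - lm) / (2 * eps)
        name = next(iter(layer.params))
        assert layer.grads[name][idx] == pytest.approx(num, abs=1e-6)


def test_generator_output_is_bounded_probability():
    gen = Generator(4, np.random.default_rng(0))
    for scale in (0.0, 1.0, 100.0):
        y = gen(np.random.default_rng(1).normal(size=(32, 32)) * scale)
        assert y.shape == (32, 32)
        assert y.min() >= 0.0 and y.max() <= 1.0


def tiny_pairs(n=6, size=32, seed=0):
    """Synthetic size-32 pairs: bright band in the image is the mask."""
    rng = np.random.default_rng(seed)
    geom = VolumeGeometry(1.0, 1.0)
    pairs = []
    for _ in range(n):
        img = rng.normal(0.3, 0.05, (size, size))
        r = int(rng.integers(8, 20))
        img[r : r + 6] += 0.5
        target = np.zeros((size, size), bool)
        target[r : r + 6] = True
        pairs.append((IntensityImage(img, geom), BinaryMask(target, geom)))
    return pairs


def test_training_is_seed_deterministic():
    cfg = TrainConfig(epochs=1, image_size=32, seed=5)
    _, hist_a = train(tiny_pairs(), cfg)
    _, hist_b = train(tiny_pairs(), cfg)
    assert hist_a[1].g_loss == hist_b[1].g_loss
    assert hist_a[1].d_loss == hist_b[1].d_loss
    assert hist_a[1].test.dsc == hist_b[1].test.dsc


def test_training_records_untrained_baseline_as_epoch_zero():
    cfg = TrainConfig(epochs=1, image_size=32, seed=5)
    _, hist = train(tiny_pairs(), cfg)
    assert [h.epoch for h in hist] == [0, 1]
    assert hist[0].g_loss is None


def test_train_rejects_bad_inputs():
    with pytest.raises(ValueError, match="at least 2"):
        train(tiny_pairs(1), TrainConfig(epochs=1, image_size=32))
    mixed = tiny_pairs(2, size=32) + tiny_pairs(2, size=64)
    with pytest.raises(ValueError, match="non-uniform"):
        train(mixed, TrainConfig(epochs=1, image_size=32))


def test_predict_gm_thresholding_and_totality():
    geom = VolumeGeometry(0.9, 0.9)
    flat = IntensityImage(np.zeros((32, 32)), geom)
    gen = Generator(4, np.random.default_rng(0))
    out = predict_gm(flat, gen)  # all-zero input: no crash, valid mask
    assert out.pixels.dtype == bool
    probs = gen(normalize_flair(flat))
    everything = predict_gm(flat, gen, threshold=0.0)
    assert everything.pixels.all()  # threshold 0 keeps every pixel
    half = predict_gm(flat, gen, threshold=0.5)
    assert np.array_equal(half.pixels, probs >= 0.5)


def test_surrogate_substitution_identity(bundle128):
    """Feeding the pipeline's own GM mask through the surrogate path
    reproduces classify_all exactly: classification is a pure function of
    the GM mask."""
    from jcwmh.phantom import pipeline_gm_target

    gm = pipeline_gm_target(bundle128)
    oracle = lambda _: gm.pixels.astype(float)  # noqa: E731
    direct = classify_all(bundle128.wmh_mask, bundle128.vent_mask, gm)
    via_surrogate = classify_with_surrogate(
        bundle128.flair, bundle128.wmh_mask, bundle128.vent_mask, oracle
    )
    assert np.array_equal(direct.label_pixels, via_surrogate.label_pixels)


def test_checkpoints_written_and_loadable(tmp_path):
    cfg = TrainConfig(epochs=2, image_size=32, seed=1)
    gen, _ = train(tiny_pairs(), cfg, checkpoint_dir=str(tmp_path))
    files = sorted(p.name for p in tmp_path.iterdir())
    assert "generator_epoch001.npz" in files and "generator_epoch002.npz" in files
    gen2 = Generator(cfg.base_channels, np.random.default_rng(99))
    gen2.load(str(tmp_path / "generator_epoch002.npz"))
    x = np.random.default_rng(0).random((32, 32))
    assert np.array_equal(gen(x), gen2(x))


def test_tiny_training_improves_on_baseline():
    """Even a 2-epoch run on 6 easy band images beats the untrained net."""
    cfg = TrainConfig(epochs=2, image_size=32, seed=2)
    _, hist = train(tiny_pairs(seed=3), cfg)
    assert hist[-1].train.dsc > hist[0].train.dsc
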