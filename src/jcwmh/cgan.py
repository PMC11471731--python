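"""Desk-scale pix2pix-style surrogate: FLAIR slice -> specialized GM mask.

The mask-refinement pipeline is deterministic but needs five
co-registered inputs.  Once it has produced enough (FLAIR, specialized
GM mask) pairs, a conditional adversarial image-to-image model can learn
the same mapping from the FLAIR slice alone: a U-Net-style
encoder-decoder generator with skip connections translates the slice
into a mask probability map, and a convolutional patch discriminator,
conditioned on the FLAIR input, scores local patches as real/fake.  The
generator objective is the standard adversarial term plus an L1 term
(weight 100) against the pipeline's target.

This implementation is intentionally small (three resolution levels,
tens of channels) and runs on plain numpy; it keeps the pix2pix
structure — paired conditioning, patch discriminator, BCE + L1·λ losses,
Adam(lr 2e-4, β₁ 0.5) — at sizes where CPU training takes minutes, not
hours.  Reproducing any dataset-scale result is a non-goal; tests only
assert that training improves on the untrained baseline and that the
learned masks support lesion classification.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from ._nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    InstanceNorm,
    bce_with_logits,
    bce_with_logits_grad,
    leaky_relu,
    leaky_relu_grad,
    sigmoid,
)
from .classify import LabeledLesionMap, RuleSet, classify_all
from .lesions import CenterMode
from .metrics import ConfusionCounts, MetricsReport, compute_metrics
from .rasters import BinaryMask, IntensityImage

__all__ = [
    "TrainConfig",
    "EpochMetrics",
    "Generator",
    "PatchDiscriminator",
    "train",
    "predict_gm",
    "classify_with_surrogate",
    "normalize_flair",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the original pix2pix recipe where it applies
    (L1 weight 100, Adam lr 2e-4 with β₁ = 0.5); ``epochs`` defaults to
    the desk-scale 5 rather than a dataset-scale run.
    """

    epochs: int = 5
    image_size: int = 64
    batch_size: int = 1
    l1_weight: float = 100.0
    learning_rate: float = 2e-4
    seed: int = 0
    split_fractions: tuple[float, float] = (0.8, 0.2)
    base_channels: int = 16
    threshold: float = 0.5  # binarization of generator output for metrics

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.image_size < 32 or self.image_size & (self.image_size - 1):
            raise ValueError("image_size must be a power of two >= 32")


@dataclass
class EpochMetrics:
    """Mask-quality metrics of the generator at the end of one epoch.

    Epoch 0 is the untrained generator — the negative-control baseline.
    """

    epoch: int
    train: MetricsReport
    test: MetricsReport
    g_loss: float | None = None
    d_loss: float | None = None


class Generator:
    """Three-level U-Net-style encoder-decoder with skip connections."""

    def __init__(self, base: int = 16, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        b = base
        self.e1 = Conv2d(1, b, rng=rng)
        self.e2 = Conv2d(b, 2 * b, rng=rng)
        self.n2 = InstanceNorm(2 * b)
        self.e3 = Conv2d(2 * b, 4 * b, rng=rng)
        self.n3 = InstanceNorm(4 * b)
        self.d1 = ConvTranspose2d(4 * b, 2 * b, rng=rng)
        self.m1 = InstanceNorm(2 * b)
        self.d2 = ConvTranspose2d(4 * b, b, rng=rng)  # input: cat(d1, e2)
        self.m2 = InstanceNorm(b)
        self.d3 = ConvTranspose2d(2 * b, 1, rng=rng)  # input: cat(d2, e1)
        self.layers = [
            self.e1, self.e2, self.n2, self.e3, self.n3,
            self.d1, self.m1, self.d2, self.m2, self.d3,
        ]
        self.base = b

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = {}
        c["z1"] = self.e1.forward(x)
        c["a1"] = leaky_relu(c["z1"])
        c["z2"] = self.n2.forward(self.e2.forward(c["a1"]))
        c["a2"] = leaky_relu(c["z2"])
        c["z3"] = self.n3.forward(self.e3.forward(c["a2"]))
        c["a3"] = leaky_relu(c["z3"])
        c["u1"] = self.m1.forward(self.d1.forward(c["a3"]))
        c["r1"] = np.maximum(c["u1"], 0.0)
        c["k1"] = np.concatenate([c["r1"], c["a2"]], axis=1)
        c["u2"] = self.m2.forward(self.d2.forward(c["k1"]))
        c["r2"] = np.maximum(c["u2"], 0.0)
        c["k2"] = np.concatenate([c["r2"], c["a1"]], axis=1)
        c["z_out"] = self.d3.forward(c["k2"])
        c["y"] = sigmoid(c["z_out"])
        self._c = c
        return c["y"]

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter grads given dL/d(output probability)."""
        c = self._c
        b2 = 2 * self.base
        dz = dy * c["y"] * (1.0 - c["y"])
        dk2 = self.d3.backward(dz)
        dr2, da1_skip = dk2[:, : self.base], dk2[:, self.base :]
        du2 = dr2 * (c["u2"] > 0)
        dk1 = self.d2.backward(self.m2.backward(du2))
        dr1, da2_skip = dk1[:, :b2], dk1[:, b2:]
        du1 = dr1 * (c["u1"] > 0)
        da3 = self.d1.backward(self.m1.backward(du1))
        dz3 = da3 * leaky_relu_grad(c["z3"])
        da2 = self.e3.backward(self.n3.backward(dz3)) + da2_skip
        dz2 = da2 * leaky_relu_grad(c["z2"])
        da1 = self.e2.backward(self.n2.backward(dz2)) + da1_skip
        dz1 = da1 * leaky_relu_grad(c["z1"])
        self.e1.backward(dz1)

    # convenience: a trained generator is callable on a 2-D image
    def __call__(self, image: np.ndarray) -> np.ndarray:
        y = self.forward(image[None, None, :, :].astype(np.float64))
        return y[0, 0]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                out[f"layer{i}.{name}"] = p
        return out

    def save(self, path: str) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path: str) -> None:
        data = np.load(path)
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = data[f"layer{i}.{name}"]


class PatchDiscriminator:
    """Convolutional patch classifier on (FLAIR, mask) channel pairs."""

    def __init__(self, base: int = 16, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.c1 = Conv2d(2, base, rng=rng)
        self.c2 = Conv2d(base, 2 * base, rng=rng)
        self.nn2 = InstanceNorm(2 * base)
        self.c3 = Conv2d(2 * base, 1, k=4, stride=1, pad=1, rng=rng)
        self.layers = [self.c1, self.c2, self.nn2, self.c3]

    def forward(self, flair: np.ndarray, mask: np.ndarray) -> np.ndarray:
        x = np.concatenate([flair, mask], axis=1)
        c = {}
        c["z1"] = self.c1.forward(x)
        c["a1"] = leaky_relu(c["z1"])
        c["z2"] = self.nn2.forward(self.c2.forward(c["a1"]))
        c["a2"] = leaky_relu(c["z2"])
        c["logits"] = self.c3.forward(c["a2"])
        self._c = c
        return c["logits"]

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Returns gradient w.r.t. the *mask* channel of the input."""
        c = self._c
        da2 = self.c3.backward(dlogits)
        dz2 = da2 * leaky_relu_grad(c["z2"])
        da1 = self.c2.backward(self.nn2.backward(dz2))
        dz1 = da1 * leaky_relu_grad(c["z1"])
        dx = self.c1.backward(dz1)
        return dx[:, 1:2]


def normalize_flair(image: IntensityImage) -> np.ndarray:
    """Per-image min-max normalisation of a FLAIR slice to [0, 1]."""
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi <= lo:
        return np.zeros_like(px)
    return (px - lo) / (hi - lo)


def _evaluate(
    gen: Generator,
    pairs: list[tuple[IntensityImage, BinaryMask]],
    threshold: float,
) -> MetricsReport:
    """Pooled pixel metrics of binarized generator output over a split."""
    tp = fp = fn = tn = 0
    for flair, target in pairs:
        pred = gen(normalize_flair(flair)) >= threshold
        t = target.pixels
        tp += int(np.sum(pred & t))
        fp += int(np.sum(pred & ~t))
        fn += int(np.sum(~pred & t))
        tn += int(np.sum(~pred & ~t))
    return compute_metrics(ConfusionCounts(tp, fp, fn, tn))


def train(
    pairs: list[tuple[IntensityImage, BinaryMask]],
    cfg: TrainConfig | None = None,
    *,
    checkpoint_dir: str | None = None,
) -> tuple[Generator, list[EpochMetrics]]:
    """Train the surrogate on paired (FLAIR, specialized GM) images.

    Returns the trained generator and one :class:`EpochMetrics` per
    epoch, with epoch 0 holding the untrained baseline.  Fully
    deterministic for a fixed seed.
    """
    cfg = cfg or TrainConfig()
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to split into train/test")
    shapes = {p[0].pixels.shape for p in pairs} | {p[1].pixels.shape for p in pairs}
    if len(shapes) != 1:
        raise ValueError(f"non-uniform image sizes: {sorted(shapes)}")
    if all(p[1].count() == 0 for p in pairs) or all(
        p[1].count() == p[1].pixels.size for p in pairs
    ):
        import logging

        logging.getLogger(__name__).warning("degenerate single-class targets")

    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg.base_channels, rng)
    disc = PatchDiscriminator(cfg.base_channels, rng)
    opt_g = Adam(gen.layers, lr=cfg.learning_rate)
    opt_d = Adam(disc.layers, lr=cfg.learning_rate)

    n_train = max(1, int(round(cfg.split_fractions[0] * len(pairs))))
    n_train = min(n_train, len(pairs) - 1)
    train_pairs, test_pairs = pairs[:n_train], pairs[n_train:]

    x_all = np.stack([normalize_flair(f) for f, _ in train_pairs])[:, None]
    y_all = np.stack([t.pixels.astype(np.float64) for _, t in train_pairs])[:, None]

    history = [
        EpochMetrics(
            0,
            _evaluate(gen, train_pairs, cfg.threshold),
            _evaluate(gen, test_pairs, cfg.threshold),
        )
    ]
    bs = cfg.batch_size
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_pairs))
        g_losses, d_losses = [], []
        for start in range(0, len(order), bs):
            idx = order[start : start + bs]
            x, y = x_all[idx], y_all[idx]
            fake = gen.forward(x)

            # discriminator step: real -> 1, fake -> 0
            opt_d.zero_grad()
            logits_real = disc.forward(x, y)
            loss_real = bce_with_logits(logits_real, 1.0)
            disc.backward(0.5 * bce_with_logits_grad(logits_real, 1.0))
            logits_fake = disc.forward(x, fake)
            loss_fake = bce_with_logits(logits_fake, 0.0)
            disc.backward(0.5 * bce_with_logits_grad(logits_fake, 0.0))
            opt_d.step()
            d_losses.append(0.5 * (loss_real + loss_fake))

            # generator step: fool the (updated) discriminator + L1
            opt_g.zero_grad()
            logits = disc.forward(x, fake)
            adv = bce_with_logits(logits, 1.0)
            l1 = float(np.abs(fake - y).mean())
            dmask = disc.backward(bce_with_logits_grad(logits, 1.0))
            for layer in disc.layers:  # discriminator grads are discarded
                for g in layer.grads.values():
                    g[...] = 0.0
            dmask = dmask + cfg.l1_weight * np.sign(fake - y) / fake.size
            gen.backward(dmask)
            opt_g.step()
            g_losses.append(adv + cfg.l1_weight * l1)

        history.append(
            EpochMetrics(
                epoch,
                _evaluate(gen, train_pairs, cfg.threshold),
                _evaluate(gen, test_pairs, cfg.threshold),
                g_loss=float(np.mean(g_losses)),
                d_loss=float(np.mean(d_losses)),
            )
        )
        if checkpoint_dir is not None:
            os.makedirs(checkpoint_dir, exist_ok=True)
            gen.save(os.path.join(checkpoint_dir, f"generator_epoch{epoch:03d}.npz"))
    return gen, history


def predict_gm(
    flair: IntensityImage, generator, threshold: float = 0.5
) -> BinaryMask:
    """Generator output on a FLAIR slice, binarized at ``threshold``.

    ``generator`` is any callable mapping a normalized 2-D array to a
    probability array of the same shape (a trained :class:`Generator`,
    or a stand-in in tests).
    """
    prob = np.asarray(generator(normalize_flair(flair)))
    if prob.shape != flair.pixels.shape:
        raise ValueError(
            f"generator output {prob.shape} does not match input {flair.pixels.shape}"
        )
    return BinaryMask(prob >= threshold, flair.geometry)


def classify_with_surrogate(
    flair: IntensityImage,
    wmh: BinaryMask,
    vent: BinaryMask,
    generator,
    rules: RuleSet | None = None,
    *,
    threshold: float = 0.5,
    center_mode: CenterMode = "pixels",
) -> LabeledLesionMap:
    """Lesion classification with the surrogate GM mask.

    Identical to the pipeline classification except that the specialized
    GM mask is predicted from the FLAIR slice instead of being computed
    by mask refinement; classification itself is a pure function of the
    GM mask, so substituting the pipeline's own mask reproduces the
    pipeline's labels exactly.
    """
    gm_pred = predict_gm(flair, generator, threshold)
    return classify_all(wmh, vent, gm_pred, rules, center_mode=center_mode)
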