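"""Adversarial training of the acetic-acid stainer and supervised training
of the pseudo-H&E renderer.

The GAN alternates blocks of generator iterations against single
discriminator iterations.  Early in training the generator takes 12 steps
per discriminator step (guarding against mode collapse from a discriminator
that overfits the targets); the ratio decays linearly by 0.25 every 1000
discriminator iterations down to a floor of 3:

    t_GperD = max(3, floor(12 - 0.25 * floor(t_D / 1000)))

Optimization is Adam, 1e-4 for the generator and 1e-5 for the
discriminator, batches of randomly cropped and augmented patches.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import nn
from .networks import (Generator, GeneratorConfig, Discriminator,
                       DiscriminatorConfig, GanLossConfig)
from .losses import berhu, total_variation


@dataclasses.dataclass
class RegisteredPair:
    """Training unit for the stainer: an aligned 7-slice unstained window
    and its single stained target slice."""

    input_stack: np.ndarray     # (D, H, W)
    target: np.ndarray          # (H, W)

    def __post_init__(self):
        self.input_stack = np.asarray(self.input_stack, dtype=np.float64)
        self.target = np.asarray(self.target, dtype=np.float64)
        if self.input_stack.ndim != 3 or self.target.ndim != 2:
            raise ValueError("input_stack must be (D,H,W), target (H,W)")
        if self.input_stack.shape[1:] != self.target.shape:
            raise ValueError("input and target spatial shapes differ")


@dataclasses.dataclass
class AugmentConfig:
    enabled: bool = True
    rotate90: bool = True          # multiples of 90 deg (no interpolation)
    flip: bool = True
    elastic_magnitude: float = 0.0  # px cap for mild elastic deformation


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 12
    patch_size: int = 256
    lr_generator: float = 1e-4
    lr_discriminator: float = 1e-5
    schedule_start: int = 12
    schedule_decay: float = 0.25
    schedule_block: int = 1000
    schedule_floor: int = 3
    total_d_iterations: int = 40000
    seed: int = 0
    loss: GanLossConfig = dataclasses.field(default_factory=GanLossConfig)
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)
    ema_half_life: float = 50.0    # divergence-monitor smoothing

    def validate(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if min(self.lr_generator, self.lr_discriminator) <= 0:
            raise ValueError("learning rates must be positive")


def schedule_g_per_d(t_d: int, start: int = 12, decay: float = 0.25,
                     block: int = 1000, floor_val: int = 3) -> int:
    """Generator iterations per discriminator iteration at count `t_d`."""
    if t_d < 0:
        raise ValueError("discriminator iteration count must be nonnegative")
    return max(floor_val, math.floor(start - decay * (t_d // block)))


def augment(input_patch: np.ndarray, target_patch: np.ndarray, seed,
            config: AugmentConfig | None = None):
    """Apply one random spatial transform identically to every slice of
    the input window and to the target.

    Rotations are restricted to 90-degree multiples and axis flips so that
    no interpolation touches the stack; an optional mild elastic
    deformation (shared smooth field, capped magnitude) can be enabled.
    """
    config = config or AugmentConfig()
    inp = np.asarray(input_patch, dtype=np.float64)
    tgt = np.asarray(target_patch, dtype=np.float64)
    squeeze = inp.ndim == 2
    if squeeze:
        inp = inp[None]
    if inp.shape[1:] != tgt.shape:
        raise ValueError("input and target patches are not aligned")
    if not config.enabled:
        return (inp[0] if squeeze else inp), tgt
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if config.rotate90:
        k = int(rng.integers(0, 4))
        inp = np.rot90(inp, k, axes=(1, 2))
        tgt = np.rot90(tgt, k)
    if config.flip:
        if rng.random() < 0.5:
            inp = inp[:, ::-1]
            tgt = tgt[::-1]
        if rng.random() < 0.5:
            inp = inp[:, :, ::-1]
            tgt = tgt[:, ::-1]
    if config.elastic_magnitude > 0:
        from .phantoms import _smooth_random_field
        from .registration.pyramid import warp
        field = _smooth_random_field(tgt.shape, config.elastic_magnitude,
                                     int(rng.integers(0, 2 ** 31)))
        inp = np.stack([warp(s, field) for s in inp])
        tgt = warp(tgt, field)
    inp = np.ascontiguousarray(inp)
    tgt = np.ascontiguousarray(tgt)
    return (inp[0] if squeeze else inp), tgt


def _random_crop(rng, pair: RegisteredPair, size: int):
    d, h, w = pair.input_stack.shape
    if h <= size and w <= size:
        return pair.input_stack, pair.target
    y = int(rng.integers(0, max(h - size, 0) + 1))
    x = int(rng.integers(0, max(w - size, 0) + 1))
    return (pair.input_stack[:, y:y + size, x:x + size],
            pair.target[y:y + size, x:x + size])


def _sample_batch(rng, pairs, config: TrainConfig):
    ins, tgts = [], []
    idx = rng.integers(0, len(pairs), size=config.batch_size)
    for i in idx:
        inp, tgt = _random_crop(rng, pairs[i], config.patch_size)
        inp, tgt = augment(inp, tgt, rng, config.augment)
        ins.append(inp)
        tgts.append(tgt)
    return np.stack(ins), np.stack(tgts)


@dataclasses.dataclass
class TrainResult:
    generator: Generator
    discriminator: Discriminator | None
    history: list                      # list of per-step dicts
    g_steps: int = 0
    d_steps: int = 0

    def history_frame(self):
        import pandas as pd
        return pd.DataFrame(self.history)


def _batch_generator_loss(output, targets: np.ndarray, d_scores,
                          cfg: GanLossConfig):
    """Average the per-image generator objective over a batch (graph)."""
    n = targets.shape[0]
    structural = None
    tv = None
    for i in range(n):
        delta = max(cfg.delta_fraction * float(targets[i].std()), 1e-12)
        s_i = berhu(nn.Tensor(targets[i]), output[i], delta)
        t_i = total_variation(output[i])
        structural = s_i if structural is None else structural + s_i
        tv = t_i if tv is None else tv + t_i
    structural = structural * (1.0 / n)
    tv = tv * (cfg.alpha / n)
    adv = ((1.0 - d_scores) ** 2).mean() * cfg.lam
    total = structural + tv + adv
    return total, {"structural": structural.item(), "tv": tv.item(),
                   "adversarial": adv.item()}


def train_vsaa(pairs: list, config: TrainConfig | None = None,
               generator: Generator | None = None,
               discriminator: Discriminator | None = None) -> TrainResult:
    """Adversarial training of the acetic-acid virtual stainer.

    Fresh batches are drawn for every generator and discriminator
    iteration.  Loss terms for both objectives are logged per step; an
    exponential moving average monitors for divergence and any non-finite
    loss aborts with a diagnostic.
    """
    if not pairs:
        raise ValueError("empty training set")
    config = config or TrainConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    if generator is None:
        generator = Generator(GeneratorConfig(
            input_depth=pairs[0].input_stack.shape[0],
            base_channels=16, seed=config.seed))
    if discriminator is None:
        discriminator = Discriminator(DiscriminatorConfig(
            base_channels=16, fc_width=128, seed=config.seed))
    opt_g = nn.Adam(generator.parameters(), lr=config.lr_generator)
    opt_d = nn.Adam(discriminator.parameters(), lr=config.lr_discriminator)
    history: list[dict] = []
    ema = None
    ema_decay = 0.5 ** (1.0 / config.ema_half_life)
    g_steps = d_steps = 0

    while d_steps < config.total_d_iterations:
        n_g = schedule_g_per_d(d_steps, config.schedule_start,
                               config.schedule_decay, config.schedule_block,
                               config.schedule_floor)
        for _ in range(n_g):
            ins, tgts = _sample_batch(rng, pairs, config)
            out = generator(ins)
            d_scores = discriminator(out)
            total, terms = _batch_generator_loss(out, tgts, d_scores,
                                                 config.loss)
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"generator loss diverged (non-finite) at g_step "
                    f"{g_steps}, d_step {d_steps}: {terms}")
            generator.zero_grad()
            discriminator.zero_grad()
            total.backward()
            opt_g.step()
            g_steps += 1
            ema = total.item() if ema is None else \
                ema_decay * ema + (1 - ema_decay) * total.item()
            history.append({"phase": "G", "g_step": g_steps,
                            "d_step": d_steps, "total": total.item(),
                            "ema": ema, **terms})
        # discriminator step on fresh batches
        ins, tgts = _sample_batch(rng, pairs, config)
        fake = generator(ins).data          # detached
        s_fake = discriminator(fake)
        s_real = discriminator(tgts)
        d_loss = (s_fake ** 2).mean() + ((1.0 - s_real) ** 2).mean()
        if not np.isfinite(d_loss.item()):
            raise RuntimeError(
                f"discriminator loss diverged at d_step {d_steps}")
        discriminator.zero_grad()
        d_loss.backward()
        opt_d.step()
        d_steps += 1
        history.append({"phase": "D", "g_step": g_steps, "d_step": d_steps,
                        "total": d_loss.item(),
                        "score_fake": float(s_fake.data.mean()),
                        "score_real": float(s_real.data.mean())})
    return TrainResult(generator, discriminator, history, g_steps, d_steps)


def train_vshe(inputs: list, targets: list, config: TrainConfig | None = None,
               model: Generator | None = None,
               n_iterations: int | None = None, lr: float = 1e-3
               ) -> TrainResult:
    """Supervised training of the pseudo-H&E renderer.

    `inputs` are (stained, unstained) image pairs; `targets` the analytic
    Beer-Lambert renderings (with the melanin absorption term where
    labeled melanin is present).  Mean absolute error objective; being a
    plain regression, it takes a larger step size than the adversarial
    generator.
    """
    if not inputs:
        raise ValueError("empty training set")
    if len(inputs) != len(targets):
        raise ValueError("inputs and targets length mismatch")
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    if model is None:
        from .networks import build_vshe_network
        model = build_vshe_network(base_channels=12, n_levels=2,
                                   seed=config.seed)
    if n_iterations is None:
        n_iterations = config.total_d_iterations
    opt = nn.Adam(model.parameters(), lr=lr)
    history = []
    xs = [np.stack([np.asarray(a, dtype=np.float64),
                    np.asarray(b, dtype=np.float64)]) for a, b in inputs]
    ys = [np.asarray(t, dtype=np.float64) for t in targets]
    for step in range(n_iterations):
        idx = rng.integers(0, len(xs), size=min(config.batch_size, len(xs)))
        bx = np.stack([xs[i] for i in idx])
        by = np.stack([ys[i] for i in idx])
        out = model(bx)
        loss = (out - nn.Tensor(by)).abs().mean()
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"pseudo-H&E training diverged at step {step}")
        model.zero_grad()
        loss.backward()
        opt.step()
        history.append({"phase": "HE", "step": step, "mae": loss.item()})
    return TrainResult(model, None, history, g_steps=n_iterations)
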