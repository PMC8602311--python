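"""GAN loss functions: reversed Huber, total variation, adversarial terms.

Each function accepts either plain numpy arrays (returning floats) or
autodiff tensors (returning graph nodes), so the same definitions serve
the training loop and the analysis code.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, as_tensor
from .networks import GanLossConfig


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def berhu(a, b, delta: float):
    """Reversed Huber distance between images `a` and `b`.

    Sum over pixels of |a-b| where the difference is at most delta, and
    (|a-b|^2 + delta^2) / (2 delta) where it exceeds delta; the two
    branches agree (both equal delta) at the threshold, so the function is
    continuous there.
    """
    if delta <= 0:
        raise ValueError("BerHu threshold delta must be positive")
    if _is_tensor(a, b):
        a, b = as_tensor(a), as_tensor(b)
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
        diff = (a - b).abs()
        small = (diff.data <= delta).astype(np.float64)   # branch mask
        lin = diff * small
        quad = (diff * diff + delta ** 2) * ((1.0 - small) / (2.0 * delta))
        return (lin + quad).sum()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = np.abs(a - b)
    return float(np.where(diff <= delta, diff,
                          (diff ** 2 + delta ** 2) / (2 * delta)).sum())


def total_variation(image):
    """Anisotropic total variation: sum of absolute horizontal and
    vertical neighbor differences.  Zero iff the image is constant."""
    if isinstance(image, Tensor):
        if image.ndim < 2:
            raise ValueError("total_variation expects a 2D image")
        dv = (image[..., 1:, :] - image[..., :-1, :]).abs().sum()
        dh = (image[..., :, 1:] - image[..., :, :-1]).abs().sum()
        return dv + dh
    image = np.asarray(image, dtype=np.float64)
    if image.ndim < 2:
        raise ValueError("total_variation expects a 2D image")
    return float(np.abs(np.diff(image, axis=-2)).sum()
                 + np.abs(np.diff(image, axis=-1)).sum())


def generator_loss(output, target, input_stack=None, d_score=None,
                   config: GanLossConfig | None = None):
    """Generator objective: BerHu structural error + TV + adversarial term.

    total = BerHu(target, output; delta = delta_fraction * std(target))
            + alpha * TV(output) + lam * (1 - D(output))^2

    Returns (total, terms) where terms maps "structural" / "tv" /
    "adversarial" to the individual contributions.  `input_stack` is
    accepted for interface symmetry (the output already is G(input)).
    """
    config = config or GanLossConfig()
    config.validate()
    target_data = target.data if isinstance(target, Tensor) else \
        np.asarray(target, dtype=np.float64)
    out_shape = output.shape if isinstance(output, Tensor) else \
        np.asarray(output).shape
    if tuple(out_shape) != target_data.shape:
        raise ValueError(
            f"output shape {tuple(out_shape)} != target {target_data.shape}")
    delta = max(config.delta_fraction * float(target_data.std()), 1e-12)
    structural = berhu(target, output, delta)
    tv = total_variation(output) * config.alpha
    if d_score is None:
        d_score = 1.0
    if isinstance(d_score, Tensor):
        adv = (1.0 - d_score) ** 2 * config.lam
        if adv.ndim > 0:
            adv = adv.mean()
    else:
        d = float(np.mean(d_score))
        if not (0.0 <= d <= 1.0):
            raise ValueError(f"discriminator score {d} outside [0, 1]")
        adv = config.lam * (1.0 - d) ** 2
    total = structural + tv + adv
    terms = {"structural": structural, "tv": tv, "adversarial": adv}
    return total, terms


def discriminator_loss(d_score_fake, d_score_real):
    """Least-squares discriminator objective.

    D(fake)^2 + (1 - D(real))^2: zero for a perfect discriminator, at most
    2 in the worst case.
    """
    if _is_tensor(d_score_fake, d_score_real):
        fake, real = as_tensor(d_score_fake), as_tensor(d_score_real)
        for s in (fake, real):
            if np.any(s.data < 0) or np.any(s.data > 1):
                raise ValueError("discriminator scores must lie in [0, 1]")
        loss = fake ** 2 + (1.0 - real) ** 2
        return loss.mean() if loss.ndim > 0 else loss
    fake = float(np.mean(d_score_fake))
    real = float(np.mean(d_score_real))
    for s in (fake, real):
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"discriminator score {s} outside [0, 1]")
    return fake ** 2 + (1.0 - real) ** 2
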