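"""Learning-based fine registration.

Two refinement rounds follow the coarse correlation-based alignment:

1. A bridge network (A) is "soft-trained" — briefly, with a structural
   loss only and no adversary — to map unstained inputs into images that
   visually resemble their stained targets.  The targets are then
   elastically re-registered against the bridge output instead of against
   the raw input, which the two images' shared appearance makes far better
   conditioned ("first fine registration").
2. After retraining the bridge on the refined pairs (A'), a DVF network
   (B) is trained, supervised by carefully tuned pyramid registrations of
   a ~10% subset, to predict a smooth displacement field directly from a
   (moving, fixed) image pair.  Applying it to every pair replaces the
   correlation search — whose occasional abnormal field values distort
   registered images — with a learned, regularized field ("second fine
   registration").
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .. import nn
from ..nn import ops
from ..networks import Generator, GeneratorConfig
from ..losses import berhu, total_variation
from ..stacks import DisplacementField
from .pyramid import PyramidConfig, estimate_dvf, warp


@dataclasses.dataclass
class BridgeNetConfig:
    """Bridge networks share the stainer's U-Net layout with fewer
    channels and downsamplings, and 2D convolutions throughout."""

    base_channels: int = 16
    n_downsamplings: int = 3
    input_channels: int = 1
    seed: int = 0

    def validate(self):
        if self.n_downsamplings < 1:
            raise ValueError("n_downsamplings must be >= 1")


def build_bridge(config: BridgeNetConfig | None = None) -> Generator:
    config = config or BridgeNetConfig()
    config.validate()
    return Generator(GeneratorConfig(
        input_depth=1, in_channels=config.input_channels,
        n_levels=config.n_downsamplings, base_channels=config.base_channels,
        seed=config.seed))


def soft_train_bridge(pairs: list, config: BridgeNetConfig | None = None,
                      budget: int = 2000, seed: int = 0,
                      batch_size: int = 4, lr: float = 1e-4):
    """Brief structural-loss training of a bridge network.

    `pairs` is a sequence of (input, target) 2D image tuples.  The budget
    is a fixed iteration count with no early stopping — the aim is a
    domain bridge that resembles the target, not a converged model.
    Returns (model, history).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training set for bridge network")
    config = config or BridgeNetConfig(seed=seed)
    model = build_bridge(config)
    history: list[dict] = []
    if budget <= 0:
        return model, history
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    xs = [np.asarray(a, dtype=np.float64) for a, _ in pairs]
    ys = [np.asarray(b, dtype=np.float64) for _, b in pairs]
    for step in range(budget):
        idx = rng.integers(0, len(xs), size=min(batch_size, len(xs)))
        bx = np.stack([xs[i] for i in idx])
        by = np.stack([ys[i] for i in idx])
        out = model(bx)
        loss = None
        for i in range(by.shape[0]):
            delta = max(0.2 * float(by[i].std()), 1e-12)
            term = berhu(nn.Tensor(by[i]), out[i], delta)
            loss = term if loss is None else loss + term
        loss = loss * (1.0 / by.shape[0])
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"bridge training diverged at step {step}")
        model.zero_grad()
        loss.backward()
        opt.step()
        history.append({"step": step, "structural": loss.item()})
    return model, history


def fine_register_first(pairs: list, bridge: Generator,
                        config: PyramidConfig | None = None):
    """Re-register each target against the bridge output of its input.

    Returns (refined pairs, report); each report row carries the median
    and maximum magnitude of the correction field for audit.
    """
    config = config or PyramidConfig()
    refined, report = [], []
    for k, (inp, tgt) in enumerate(pairs):
        reference = bridge.infer(np.asarray(inp, dtype=np.float64))
        try:
            dvf = estimate_dvf(reference, np.asarray(tgt, dtype=np.float64),
                               config)
        except ValueError as err:
            raise ValueError(f"fine registration failed on pair {k}: {err}"
                             ) from err
        registered = warp(np.asarray(tgt, dtype=np.float64), dvf)
        refined.append((np.asarray(inp, dtype=np.float64), registered))
        mag = dvf.magnitude()
        report.append({"pair": k,
                       "median_correction_px": float(np.median(mag)),
                       "max_correction_px": float(mag.max())})
    return refined, report


# -- DVF network --------------------------------------------------------------

@dataclasses.dataclass
class DVFTrainExample:
    """Supervision unit for the DVF network.

    i_m: roughly registered (moving) target patch; i_f: bridge output
    (fixed) patch; i_r_gt: accurately registered target; phi_gt: the
    ground-truth field mapping i_m onto i_f.
    """

    i_m: np.ndarray
    i_f: np.ndarray
    i_r_gt: np.ndarray
    phi_gt: np.ndarray            # (2, H, W): (dy, dx)

    def __post_init__(self):
        self.i_m = np.asarray(self.i_m, dtype=np.float64)
        self.i_f = np.asarray(self.i_f, dtype=np.float64)
        self.i_r_gt = np.asarray(self.i_r_gt, dtype=np.float64)
        if isinstance(self.phi_gt, DisplacementField):
            self.phi_gt = np.stack([self.phi_gt.dy, self.phi_gt.dx])
        self.phi_gt = np.asarray(self.phi_gt, dtype=np.float64)
        shapes = {self.i_m.shape, self.i_f.shape, self.i_r_gt.shape,
                  self.phi_gt.shape[1:]}
        if len(shapes) != 1 or self.phi_gt.shape[0] != 2:
            raise ValueError("inconsistent shapes in DVF training example")
        if not np.all(np.isfinite(self.phi_gt)):
            raise ValueError("phi_gt contains non-finite values")


def dvfnet_loss(i_r, i_r_gt, phi, phi_gt, weights=(1.0, 0.02, 0.01)):
    """Supervised DVF objective.

    w1 * MSE(i_r, i_r_gt) + w2 * MSE(phi, phi_gt) + w3 * TVpp(phi), where
    MSE is the per-element mean square error and TVpp the anisotropic
    total variation of the field summed over both components and divided
    by the pixel count.  Zero iff the registered image and field match
    their ground truths and the field is constant.  Accepts numpy arrays
    (returns float) or autodiff tensors (returns a graph node).
    """
    w1, w2, w3 = weights
    if min(w1, w2, w3) < 0:
        raise ValueError("dvfnet loss weights must be nonnegative")
    tensor_mode = any(isinstance(t, nn.Tensor) for t in (i_r, phi))
    if isinstance(phi, DisplacementField):
        phi = np.stack([phi.dy, phi.dx])
    if isinstance(phi_gt, DisplacementField):
        phi_gt = np.stack([phi_gt.dy, phi_gt.dx])
    if tensor_mode:
        i_r = nn.as_tensor(i_r)
        phi = nn.as_tensor(phi)
        i_r_gt_t = nn.Tensor(np.asarray(i_r_gt, dtype=np.float64))
        phi_gt_t = nn.Tensor(np.asarray(phi_gt, dtype=np.float64))
        if i_r.shape != i_r_gt_t.shape or phi.shape != phi_gt_t.shape:
            raise ValueError("shape mismatch in dvfnet loss")
        npix = float(np.prod(phi.shape[-2:]))
        mse_img = ((i_r - i_r_gt_t) ** 2).mean()
        mse_phi = ((phi - phi_gt_t) ** 2).mean()
        tv = total_variation(phi) * (1.0 / npix)
        return mse_img * w1 + mse_phi * w2 + tv * w3
    i_r = np.asarray(i_r, dtype=np.float64)
    i_r_gt = np.asarray(i_r_gt, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    phi_gt = np.asarray(phi_gt, dtype=np.float64)
    if i_r.shape != i_r_gt.shape or phi.shape != phi_gt.shape:
        raise ValueError("shape mismatch in dvfnet loss")
    npix = float(np.prod(phi.shape[-2:]))
    return (w1 * float(((i_r - i_r_gt) ** 2).mean())
            + w2 * float(((phi - phi_gt) ** 2).mean())
            + w3 * total_variation(phi) / npix)


class DVFNet:
    """Encoder-decoder predicting a dense 2-channel displacement field
    from a (moving, fixed) image pair; zero-initialized head so the
    initial prediction is the identity field."""

    def __init__(self, base_channels: int = 12, n_levels: int = 3,
                 seed: int = 0):
        self.model = Generator(GeneratorConfig(
            input_depth=1, in_channels=2, out_channels=2,
            n_levels=n_levels, base_channels=base_channels,
            attention_gates=False, final_activation="none",
            zero_init_final=True, seed=seed))

    def predict(self, i_m: np.ndarray, i_f: np.ndarray) -> DisplacementField:
        out = self.model.infer(np.stack([np.asarray(i_m, dtype=np.float64),
                                         np.asarray(i_f, dtype=np.float64)]))
        return DisplacementField(out[0], out[1])


def train_dvf_network(train_set: list, weights=(1.0, 0.02, 0.01),
                      budget: int = 300, seed: int = 0,
                      model: DVFNet | None = None, batch_size: int = 4,
                      lr: float = 1e-3):
    """Supervised training of the DVF network on pyramid-derived ground
    truth; returns (model, history)."""
    train_set = list(train_set)
    if not train_set:
        raise ValueError("empty DVF training set")
    model = model or DVFNet(seed=seed)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.model.parameters(), lr=lr)
    history: list[dict] = []
    for step in range(budget):
        idx = rng.integers(0, len(train_set), size=min(batch_size,
                                                       len(train_set)))
        batch = [train_set[i] for i in idx]
        ims = np.stack([ex.i_m for ex in batch])[:, None]     # (N,1,H,W)
        x = np.stack([np.stack([ex.i_m, ex.i_f]) for ex in batch])
        phi = model.model(x)                                  # (N,2,H,W)
        i_r = ops.flow_warp(ims, phi)[:, 0]
        i_r_gt = np.stack([ex.i_r_gt for ex in batch])
        phi_gt = np.stack([ex.phi_gt for ex in batch])
        loss = dvfnet_loss(i_r, i_r_gt, phi, phi_gt, weights)
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"DVF network training diverged at step {step}")
        model.model.zero_grad()
        loss.backward()
        opt.step()
        history.append({"step": step, "loss": loss.item()})
    return model, history


def fine_register_second(pairs: list, dvf_model: DVFNet,
                         bridge: Generator | None = None):
    """Replace the correlation search with DVF-network inference.

    For each (input, target) pair the fixed image is the bridge output of
    the input (or the input itself when no bridge is given); the predicted
    field warps the target into alignment.  Returns (refined pairs,
    report) where the report carries the per-pixel total variation of each
    applied field — the smoothness this second round exists to improve.
    """
    refined, report = [], []
    for k, (inp, tgt) in enumerate(pairs):
        inp = np.asarray(inp, dtype=np.float64)
        tgt = np.asarray(tgt, dtype=np.float64)
        fixed = bridge.infer(inp) if bridge is not None else inp
        phi = dvf_model.predict(tgt, fixed)
        registered = warp(tgt, phi)
        refined.append((inp, registered))
        npix = float(phi.dy.size)
        tv_pp = (total_variation(phi.dy) + total_variation(phi.dx)) / npix
        report.append({"pair": k, "tv_per_pixel": tv_pp,
                       "median_mag_px": float(np.median(phi.magnitude()))})
    return refined, report
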