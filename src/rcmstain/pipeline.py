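"""End-to-end inference and the full training workflow.

Inference follows the sliding-window geometry of the stainer: each
seven-slice window of a registered z-stack produces the virtually stained
image of its central plane, so an N-slice stack yields N-6 output slices.
Large mosaics are stained tile-wise with overlapping tiles and cosine
blending (the network is fully convolutional, so interior pixels agree
with whole-image inference).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .stacks import ImageStack
from .networks import (Generator, GeneratorConfig,
                       save_checkpoint, load_checkpoint)
from .training import (RegisteredPair, TrainConfig, train_vsaa, train_vshe,
                       TrainResult)
from .registration.pyramid import (PyramidConfig, register_stacks,
                                   register_timelapse_depth,
                                   select_reference_depth, estimate_dvf, warp)
from .registration.learned import (BridgeNetConfig, soft_train_bridge,
                                   fine_register_first, fine_register_second,
                                   train_dvf_network, DVFNet, DVFTrainExample)
from . import hne
from .phantoms import Timelapse


@dataclasses.dataclass
class StainRunConfig:
    window_depth: int = 7
    stride: int = 1
    tile_size: int = 896
    tile_overlap: int = 64
    auto_register: bool = False

    def validate(self):
        if self.window_depth % 2 == 0 or self.window_depth < 1:
            raise ValueError("window_depth must be odd")
        if not (0 <= self.tile_overlap < self.tile_size):
            raise ValueError("overlap must be smaller than tile_size")


def extract_windows(stack: ImageStack | np.ndarray, depth: int = 7
                    ) -> list[np.ndarray]:
    """All axially adjacent depth-windows of a stack.

    An N-slice stack yields exactly N - (depth - 1) windows; window k
    (0-based) holds slices k .. k+depth-1 and is centered on slice
    k + depth//2.
    """
    voxels = stack.voxels if isinstance(stack, ImageStack) else \
        np.asarray(stack, dtype=np.float64)
    n = voxels.shape[0]
    if depth % 2 == 0 or depth < 1:
        raise ValueError("window depth must be odd")
    if n < depth:
        raise ValueError(
            f"stack has {n} slices; at least {depth} are required for "
            f"{depth}-to-1 inference")
    return [voxels[k:k + depth] for k in range(n - depth + 1)]


def stain_stack(stack: ImageStack, vsaa: Generator, vshe: Generator | None,
                config: StainRunConfig | None = None,
                registered: bool = True):
    """Virtually stain a registered stack.

    Returns (acetic_stack, hne_stack): the N-6 acetic-acid staining
    slices, and — when a pseudo-H&E model is given — the matching RGB
    renderings, each aligned with the central input slice of its window.
    Misaligned stacks make the staining inference fail, so an unregistered
    stack triggers automatic slice registration (or a warning).
    """
    config = config or StainRunConfig()
    config.validate()
    if not registered:
        if config.auto_register:
            stack = register_stack_slices(stack)
        else:
            import warnings
            warnings.warn("stack not marked registered; inference on "
                          "misaligned stacks is unreliable", stacklevel=2)
    windows = extract_windows(stack, config.window_depth)
    half = config.window_depth // 2
    aa_slices, he_slices = [], []
    for k, win in enumerate(windows):
        aa = vsaa.infer(win)
        aa_slices.append(aa)
        if vshe is not None:
            central_input = stack.voxels[k + half]
            he_slices.append(hne.apply_vshe(vshe, aa, central_input))
    aa_stack = np.stack(aa_slices)
    he_stack = np.stack(he_slices) if he_slices else None
    return aa_stack, he_stack


def register_stack_slices(stack: ImageStack,
                          config: PyramidConfig | None = None) -> ImageStack:
    """Align every slice of a stack to its predecessor (drift removal)."""
    aligned, _ = register_timelapse_depth(list(stack.voxels), config)
    return ImageStack(np.stack(aligned), stack.axial_step, stack.pixel_pitch,
                      {**stack.metadata, "registered": True})


def _tile_weights(h: int, w: int, margins) -> np.ndarray:
    """Cosine ramp from 0 to 1 over each margin that borders another tile."""
    top, bottom, left, right = margins
    wy = np.ones(h)
    wx = np.ones(w)
    if top:
        ramp = 0.5 - 0.5 * np.cos(np.pi * (np.arange(top) + 0.5) / top)
        wy[:top] = ramp
    if bottom:
        ramp = 0.5 - 0.5 * np.cos(np.pi * (np.arange(bottom) + 0.5) / bottom)
        wy[-bottom:] = ramp[::-1]
    if left:
        ramp = 0.5 - 0.5 * np.cos(np.pi * (np.arange(left) + 0.5) / left)
        wx[:left] = ramp
    if right:
        ramp = 0.5 - 0.5 * np.cos(np.pi * (np.arange(right) + 0.5) / right)
        wx[-right:] = ramp[::-1]
    return wy[:, None] * wx[None, :]


def stain_mosaic(window: np.ndarray, vsaa: Generator,
                 vshe: Generator | None = None,
                 config: StainRunConfig | None = None):
    """Stain one large-mosaic depth-window (depth, H, W) tile-wise.

    Overlapping tiles are blended with cosine ramps; a mosaic no larger
    than one tile reduces to whole-image inference.  Returns
    (acetic_mosaic, hne_mosaic or None).
    """
    config = config or StainRunConfig()
    config.validate()
    window = np.asarray(window, dtype=np.float64)
    d, h, w = window.shape
    half = d // 2
    tile, overlap = config.tile_size, config.tile_overlap
    if min(tile, h, w) < 32:
        raise ValueError("tile and mosaic must be at least 32 px")
    if h <= tile and w <= tile:
        aa = vsaa.infer(window)
        he_img = hne.apply_vshe(vshe, aa, window[half]) \
            if vshe is not None else None
        return aa, he_img
    step = tile - overlap
    ys = sorted({min(y, h - tile) for y in range(0, h - tile + step, step)})
    xs = sorted({min(x, w - tile) for x in range(0, w - tile + step, step)})
    acc = np.zeros((h, w))
    wacc = np.zeros((h, w))
    for y in ys:
        for x in xs:
            sub = window[:, y:y + tile, x:x + tile]
            out = vsaa.infer(sub)
            margins = (overlap if y > 0 else 0,
                       overlap if y + tile < h else 0,
                       overlap if x > 0 else 0,
                       overlap if x + tile < w else 0)
            wt = _tile_weights(tile, tile, margins)
            acc[y:y + tile, x:x + tile] += out * wt
            wacc[y:y + tile, x:x + tile] += wt
    aa = acc / np.maximum(wacc, 1e-12)
    he_img = hne.apply_vshe(vshe, aa, window[half]) if vshe is not None \
        else None
    return aa, he_img


# -- full training workflow ---------------------------------------------------

@dataclasses.dataclass
class WorkflowConfig:
    """Budgets and sub-configurations for the end-to-end training run.

    Defaults are desk-scale: small networks and short budgets that
    exercise every stage.
    """

    pyramid: PyramidConfig = dataclasses.field(default_factory=PyramidConfig)
    # fine rounds correct small residuals against a bridge *rendering*:
    # restrict the search and skip the global translation stage, which is
    # unreliable between a blurry bridge output and a sharp target
    fine_pyramid: PyramidConfig = dataclasses.field(
        default_factory=lambda: PyramidConfig(n_levels=2, search_radius=2,
                                              n_iterations=1,
                                              global_init=False))
    bridge: BridgeNetConfig = dataclasses.field(
        default_factory=lambda: BridgeNetConfig(base_channels=8,
                                                n_downsamplings=2))
    bridge_budget: int = 120
    dvf_budget: int = 120
    dvf_subset_fraction: float = 0.1
    vsaa_train: TrainConfig = dataclasses.field(
        default_factory=lambda: TrainConfig(batch_size=3, patch_size=64,
                                            total_d_iterations=5))
    vsaa_generator_channels: int = 8
    vshe_budget: int = 120
    window_depth: int = 7
    seed: int = 0


def run_full_training_workflow(timelapse: Timelapse,
                               config: WorkflowConfig | None = None,
                               outdir: str | Path | None = None,
                               resume: bool = False) -> dict:
    """Run the complete registration-and-training pipeline on a time-lapse.

    Stages: initial registration (time-lapse chain at the most textured
    depth, then stack registration of the unstained/stained endpoints) ->
    soft-train bridge A -> first fine registration -> soft-train A' ->
    pyramid ground truth on a seeded ~10% subset -> train DVF network B ->
    second fine registration -> train the acetic-acid stainer on 7-slice
    windows -> render analytic pseudo-H&E targets -> train the H&E
    renderer.  Artifacts of every stage are returned (and written to
    `outdir` when given; with ``resume=True`` previously written model
    checkpoints are reused).
    """
    config = config or WorkflowConfig()
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def _stage_path(name):
        return out / name if out else None

    try:
        # (1) initial registration
        first, last = timelapse.stacks[0], timelapse.stacks[-1]
        depth_ref = select_reference_depth(first)
        seq = [s.voxels[depth_ref] for s in timelapse.stacks]
        _, chain = register_timelapse_depth(seq, config.pyramid)
        artifacts["timelapse_chain"] = chain
        # undo cumulative drift of the final (stained) stack, then register
        # the two endpoint stacks slice-wise
        final_dvf = chain[-1]
        corrected = np.stack([warp(last.voxels[z], final_dvf)
                              for z in range(last.n_slices)])
        last_corr = ImageStack(corrected, last.axial_step, last.pixel_pitch)
        # unstained-vs-stained registration: correlate edges, not raw
        # intensities (nuclei flip from dark to bright across staining)
        slice_pairs = register_stacks(first, last_corr, config.fine_pyramid,
                                      edge_based=True)
        coarse = [(p.fixed, p.registered) for p in slice_pairs]
        artifacts["coarse_pairs"] = coarse
    except Exception as err:
        raise RuntimeError(f"workflow stage 'initial_registration' failed: "
                           f"{err}") from err

    rng = np.random.default_rng(config.seed)

    def _bridge_stage(name, pairs, seed):
        path = _stage_path(f"{name}.npz")
        cfg = dataclasses.replace(config.bridge, seed=seed)
        if resume and path and path.exists():
            model = dataclasses_build_bridge(cfg)
            load_checkpoint(model, path)
            return model, []
        model, hist = soft_train_bridge(pairs, cfg,
                                        budget=config.bridge_budget,
                                        seed=seed)
        if path:
            save_checkpoint(model, path)
        return model, hist

    from .registration.learned import build_bridge as dataclasses_build_bridge

    try:
        bridge_a, hist_a = _bridge_stage("bridge_A", coarse, config.seed)
        artifacts["bridge_A_history"] = hist_a
        refined1, report1 = fine_register_first(coarse, bridge_a,
                                                config.fine_pyramid)
        artifacts["first_fine_report"] = report1
    except Exception as err:
        raise RuntimeError(f"workflow stage 'first_fine_registration' "
                           f"failed: {err}") from err

    try:
        bridge_a2, hist_a2 = _bridge_stage("bridge_Aprime", refined1,
                                           config.seed + 1)
        artifacts["bridge_Aprime_history"] = hist_a2
        # (5) pyramid ground truth on a seeded ~10% subset
        n_sub = max(1, int(round(config.dvf_subset_fraction * len(refined1))))
        subset = rng.choice(len(refined1), size=n_sub, replace=False)
        examples = []
        for i in subset:
            inp, tgt = refined1[i]
            i_f = bridge_a2.infer(inp)
            phi_gt = estimate_dvf(i_f, tgt, config.fine_pyramid)
            i_r_gt = warp(tgt, phi_gt)
            examples.append(DVFTrainExample(tgt, i_f, i_r_gt, phi_gt))
        dvf_path = _stage_path("dvfnet_B.npz")
        if resume and dvf_path and dvf_path.exists():
            dvf_model = DVFNet(seed=config.seed)
            load_checkpoint(dvf_model.model, dvf_path)
        else:
            dvf_model, _ = train_dvf_network(examples,
                                             budget=config.dvf_budget,
                                             seed=config.seed)
            if dvf_path:
                save_checkpoint(dvf_model.model, dvf_path)
        final_pairs2d, report2 = fine_register_second(refined1, dvf_model,
                                                      bridge_a2)
        artifacts["second_fine_report"] = report2
    except Exception as err:
        raise RuntimeError(f"workflow stage 'second_fine_registration' "
                           f"failed: {err}") from err

    try:
        # (8) assemble 7-slice training windows around each registered target
        depth = config.window_depth
        half = depth // 2
        input_vox = first.voxels
        n = input_vox.shape[0]
        reg_targets = [t for _, t in final_pairs2d]
        pairs = []
        for z in range(half, n - half):
            pairs.append(RegisteredPair(input_vox[z - half:z + half + 1],
                                        reg_targets[z]))
        vsaa_cfg = dataclasses.replace(config.vsaa_train, seed=config.seed)
        gen = Generator(GeneratorConfig(
            input_depth=depth, base_channels=config.vsaa_generator_channels,
            seed=config.seed))
        vsaa_path = _stage_path("vsaa.npz")
        if resume and vsaa_path and vsaa_path.exists():
            load_checkpoint(gen, vsaa_path)
            result = TrainResult(gen, None, [])
        else:
            result = train_vsaa(pairs, vsaa_cfg, generator=gen)
            if vsaa_path:
                save_checkpoint(result.generator, vsaa_path)
        artifacts["vsaa"] = result
    except Exception as err:
        raise RuntimeError(f"workflow stage 'train_vsaa' failed: {err}"
                           ) from err

    try:
        # (9)-(10) analytic H&E targets and the learned renderer
        mel_volume = hne.synthesize_melanin_labels(timelapse.pair)
        inputs, targets = [], []
        for z in range(half, n - half):
            i_input = input_vox[z]
            i_target = reg_targets[z]
            fg = hne.extract_foreground(np.clip(i_target, 0, 1),
                                        np.clip(i_input, 0, 1))
            analytic = hne.render_analytic_hne_with_melanin(
                fg, i_input, mel_volume[z])
            inputs.append((i_target, i_input))
            targets.append(np.moveaxis(analytic, -1, 0))   # (3, H, W)
        vshe_path = _stage_path("vshe.npz")
        if resume and vshe_path and vshe_path.exists():
            from .networks import build_vshe_network
            vshe_model = build_vshe_network(base_channels=12, n_levels=2,
                                            seed=config.seed)
            load_checkpoint(vshe_model, vshe_path)
            vshe_result = TrainResult(vshe_model, None, [])
        else:
            vshe_result = train_vshe(inputs, targets,
                                     TrainConfig(batch_size=3,
                                                 seed=config.seed),
                                     n_iterations=config.vshe_budget)
            if vshe_path:
                save_checkpoint(vshe_result.generator, vshe_path)
        artifacts["vshe"] = vshe_result
    except Exception as err:
        raise RuntimeError(f"workflow stage 'train_vshe' failed: {err}"
                           ) from err

    artifacts["registered_pairs"] = pairs
    if out:
        (out / "workflow_summary.json").write_text(json.dumps(
            {"n_pairs": len(pairs),
             "first_fine_median_px": float(np.median(
                 [r["median_correction_px"] for r in report1])),
             "second_fine_tv_per_pixel": float(np.median(
                 [r["tv_per_pixel"] for r in report2]))}, indent=1))
    return artifacts
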