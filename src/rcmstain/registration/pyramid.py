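"""Pyramid elastic registration by multi-scale local correlation.

The estimator builds an image pyramid (factor-2 downsampling), initializes
with a global phase-correlation translation, and at each level iterates:
warp the moving image by the current field, exhaustively score integer
offsets within a search window by windowed normalized cross-correlation,
refine the best offset to sub-pixel precision with a parabola fit, clamp
abnormal values to the search radius, and Gaussian-smooth the increment.
The result is a dense displacement vector field (DVF) in pull semantics:
output pixel (y, x) samples the moving image at (y + dy, x + dx).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

from ..stacks import DisplacementField, ImageStack


@dataclasses.dataclass
class PyramidConfig:
    """Multi-scale correlation settings.

    ``block_size`` is the side of the local correlation window in pixels
    (at every level), ``search_radius`` the exhaustive integer search range
    per level, ``smoothing_sigma`` the Gaussian regularization of the field
    (defaults to block_size / 2), ``n_iterations`` the warp/match/update
    sweeps per level.  ``global_init`` switches the phase-correlation
    translation initialization at the coarsest level.
    """

    n_levels: int = 4
    block_size: int = 16
    search_radius: int = 4
    smoothing_sigma: float | None = None
    n_iterations: int = 2
    global_init: bool = True

    def validate(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.block_size < 8:
            raise ValueError("block_size must be >= 8")
        if self.search_radius < 1 or self.n_iterations < 1:
            raise ValueError("search_radius and n_iterations must be >= 1")

    @property
    def sigma(self) -> float:
        return self.block_size / 2.0 if self.smoothing_sigma is None \
            else self.smoothing_sigma


def warp(image: np.ndarray, dvf: DisplacementField) -> np.ndarray:
    """Resample `image` through `dvf` (bilinear, edge-clamped).

    A zero field returns the input bit-exactly.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != dvf.shape:
        raise ValueError(f"image shape {image.shape} does not match "
                         f"field shape {dvf.shape}")
    if not (np.any(dvf.dy) or np.any(dvf.dx)):
        return image.copy()
    h, w = image.shape
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([gy + dvf.dy, gx + dvf.dx])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def _sample_field(field: np.ndarray, dy: np.ndarray,
                  dx: np.ndarray) -> np.ndarray:
    """Evaluate a scalar field at displaced positions (for composition)."""
    h, w = field.shape
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([gy + dy, gx + dx])
    return ndimage.map_coordinates(field, coords, order=1, mode="nearest")


def _local_ncc_displacement(fixed: np.ndarray, moving: np.ndarray,
                            block: int, radius: int) -> tuple:
    """Per-pixel best integer offset by windowed NCC, with parabola sub-pixel.

    Returns (dy, dx) increments mapping fixed coords into `moving`.
    """
    size = block
    eps = 1e-8
    mf = ndimage.uniform_filter(fixed, size)
    vf = ndimage.uniform_filter(fixed * fixed, size) - mf * mf
    sf = np.sqrt(np.maximum(vf, 0.0))
    n_off = 2 * radius + 1
    scores = np.full((n_off, n_off, *fixed.shape), -2.0)
    pad = radius
    mp = np.pad(moving, pad, mode="edge")
    h, w = fixed.shape
    for iu, u in enumerate(range(-radius, radius + 1)):
        for iv, v in enumerate(range(-radius, radius + 1)):
            # moving sampled at (y+u, x+v)
            ms = mp[pad + u:pad + u + h, pad + v:pad + v + w]
            mm = ndimage.uniform_filter(ms, size)
            vm = ndimage.uniform_filter(ms * ms, size) - mm * mm
            sm = np.sqrt(np.maximum(vm, 0.0))
            cov = ndimage.uniform_filter(fixed * ms, size) - mf * mm
            scores[iu, iv] = cov / (sf * sm + eps)
    flat = scores.reshape(n_off * n_off, h, w)
    best = np.argmax(flat, axis=0)
    bu, bv = np.unravel_index(best, (n_off, n_off))
    ii, jj = np.mgrid[0:h, 0:w]
    s0 = scores[bu, bv, ii, jj]

    def _subpixel(b, s_minus, s_plus):
        # 1D parabola through (b-1, b, b+1); vertex offset in [-0.5, 0.5]
        denom = s_minus - 2 * s0 + s_plus
        safe = np.where(np.abs(denom) > eps, denom, 1.0)
        off = np.where((b > 0) & (b < n_off - 1) & (np.abs(denom) > eps),
                       0.5 * (s_minus - s_plus) / safe, 0.0)
        return np.clip(off, -0.5, 0.5)

    sub_u = _subpixel(bu, scores[np.clip(bu - 1, 0, n_off - 1), bv, ii, jj],
                      scores[np.clip(bu + 1, 0, n_off - 1), bv, ii, jj])
    sub_v = _subpixel(bv, scores[bu, np.clip(bv - 1, 0, n_off - 1), ii, jj],
                      scores[bu, np.clip(bv + 1, 0, n_off - 1), ii, jj])
    dy = (bu - radius) + sub_u
    dx = (bv - radius) + sub_v
    # suppress updates where there is no local texture or no good match
    weak = (sf < 0.1 * sf.mean()) | (s0 < 0.1)
    dy = np.where(weak, 0.0, dy)
    dx = np.where(weak, 0.0, dx)
    return dy, dx


def estimate_dvf(fixed: np.ndarray, moving: np.ndarray,
                 config: PyramidConfig | None = None) -> DisplacementField:
    """Estimate the DVF warping `moving` onto `fixed`."""
    config = config or PyramidConfig()
    config.validate()
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must share a shape")
    if fixed.std() < 1e-9 or moving.std() < 1e-9:
        raise ValueError("no texture to correlate: constant image")
    h, w = fixed.shape

    # pyramid of images, coarse last
    pyr_f, pyr_m = [fixed], [moving]
    for _ in range(config.n_levels - 1):
        prev_f, prev_m = pyr_f[-1], pyr_m[-1]
        if min(prev_f.shape) // 2 < max(config.block_size, 8):
            break
        shape = (prev_f.shape[0] // 2, prev_f.shape[1] // 2)
        pyr_f.append(resize(prev_f, shape, anti_aliasing=True))
        pyr_m.append(resize(prev_m, shape, anti_aliasing=True))

    # initialize at the coarsest level
    dy = np.zeros(pyr_f[-1].shape)
    dx = np.zeros(pyr_f[-1].shape)
    if config.global_init:
        scale = 2 ** (len(pyr_f) - 1)
        shift, _, _ = phase_cross_correlation(fixed, moving,
                                              upsample_factor=10,
                                              normalization=None)
        # phase correlation reports the shift of moving w.r.t. fixed;
        # pull semantics needs the negation
        dy += -shift[0] / scale
        dx += -shift[1] / scale

    for level in range(len(pyr_f) - 1, -1, -1):
        f, m = pyr_f[level], pyr_m[level]
        if dy.shape != f.shape:
            dy = resize(dy, f.shape, order=3) * 2.0
            dx = resize(dx, f.shape, order=3) * 2.0
        for _ in range(config.n_iterations):
            warped = warp(m, DisplacementField(dy, dx))
            inc_y, inc_x = _local_ncc_displacement(
                f, warped, config.block_size, config.search_radius)
            inc_y = np.clip(inc_y, -config.search_radius, config.search_radius)
            inc_x = np.clip(inc_x, -config.search_radius, config.search_radius)
            inc_y = ndimage.gaussian_filter(inc_y, config.sigma)
            inc_x = ndimage.gaussian_filter(inc_x, config.sigma)
            dy = dy + inc_y
            dx = dx + inc_x
    return DisplacementField(dy, dx)


def register_timelapse_depth(sequence: list, config: PyramidConfig | None = None
                             ) -> tuple[list, list]:
    """Align a same-depth time-lapse sequence to its first frame.

    Consecutive frame pairs are registered and the fields chained, so that
    cumulative drift is corrected; returns (aligned frames, cumulative DVF
    per frame) for audit.
    """
    if len(sequence) < 2:
        raise ValueError("need at least two images to register a sequence")
    config = config or PyramidConfig()
    aligned = [np.asarray(sequence[0], dtype=np.float64)]
    h, w = aligned[0].shape
    cumulative = [DisplacementField.zero((h, w))]
    for t in range(1, len(sequence)):
        try:
            step = estimate_dvf(sequence[t - 1], sequence[t], config)
        except ValueError as err:
            raise ValueError(f"registration failed at timepoint {t}: {err}"
                             ) from err
        total = cumulative[-1].compose(step) if t > 1 else step
        cumulative.append(total)
        aligned.append(warp(np.asarray(sequence[t], dtype=np.float64), total))
    return aligned, cumulative


@dataclasses.dataclass
class RegisteredSlicePair:
    """One slice of a stack pair after elastic alignment."""

    index: int
    fixed: np.ndarray
    registered: np.ndarray
    dvf: DisplacementField


def register_stacks(stack_before: ImageStack, stack_after: ImageStack,
                    config: PyramidConfig | None = None,
                    edge_based: bool = False) -> list[RegisteredSlicePair]:
    """Slice-wise elastic alignment of `stack_after` onto `stack_before`.

    With ``edge_based`` the correlation runs on Gaussian gradient-magnitude
    images while the displacement is applied to the intensities — the
    standard robustification when the two stacks differ in contrast
    polarity (staining turns dark nuclei bright, anti-correlating the raw
    intensities, but their edges coincide).
    """
    if stack_before.n_slices != stack_after.n_slices:
        raise ValueError(
            f"stack depth mismatch: {stack_before.n_slices} vs "
            f"{stack_after.n_slices}")
    config = config or PyramidConfig()
    pairs = []
    for z in range(stack_before.n_slices):
        fixed = stack_before.voxels[z]
        moving = stack_after.voxels[z]
        if edge_based:
            dvf = estimate_dvf(
                ndimage.gaussian_gradient_magnitude(fixed, 1.0),
                ndimage.gaussian_gradient_magnitude(moving, 1.0), config)
        else:
            dvf = estimate_dvf(fixed, moving, config)
        pairs.append(RegisteredSlicePair(z, fixed, warp(moving, dvf), dvf))
    return pairs


def select_reference_depth(stack: ImageStack) -> int:
    """Depth with maximal texture variance (automation of the manual pick).

    Heuristic: the slice whose intensity variance is largest carries the
    most registrable texture.
    """
    variances = stack.voxels.var(axis=(1, 2))
    return int(np.argmax(variances))
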