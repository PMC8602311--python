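"""Pseudo-H&E colorization of acetic-acid-stained RCM images.

The analytic renderer models transillumination absorption with the
Beer-Lambert law.  The nuclear foreground is extracted by a weighted
subtraction of the unstained image from the stained one, then each RGB
channel c is attenuated exponentially:

    I_HE[c] = exp(-beta_hematoxylin[c] * I_foreground)
              * exp(-beta_eosin[c] * I_input)

which stains nuclei blue/purple (hematoxylin) on a pink cytoplasm/stroma
background (eosin) over a white (1,1,1) background where both components
vanish.  Melanin — bright in both the unstained and stained channels
because of its high refractive index — receives a third brown absorption
term.  A learned renderer (the VS_HE network) reproduces this map while
inpainting melanin from spatial context; the analytic renderings are its
training targets.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .networks import Generator
from .phantoms import PhantomPair


@dataclasses.dataclass
class BetaVectors:
    """Per-channel (RGB) absorption coefficients of the three chromophores."""

    hematoxylin: tuple = (0.84, 1.2, 0.36)
    eosin: tuple = (0.2, 2.0, 0.8)
    brown: tuple = (0.12, 0.24, 0.28)

    def validate(self):
        for name in ("hematoxylin", "eosin", "brown"):
            vec = np.asarray(getattr(self, name), dtype=np.float64)
            if vec.shape != (3,) or np.any(vec <= 0):
                raise ValueError(f"beta_{name} must be 3 positive components")

    def as_arrays(self):
        return (np.asarray(self.hematoxylin, dtype=np.float64),
                np.asarray(self.eosin, dtype=np.float64),
                np.asarray(self.brown, dtype=np.float64))


def _check01(name: str, img: np.ndarray):
    if img.min() < -1e-9 or img.max() > 1.0 + 1e-9:
        raise ValueError(
            f"{name} must be normalized to [0, 1]; got range "
            f"[{img.min():.3g}, {img.max():.3g}]")


def extract_foreground(i_target: np.ndarray, i_input: np.ndarray
                       ) -> np.ndarray:
    """Nuclear foreground: max(1.2 * stained - 0.8 * unstained, 0)."""
    i_target = np.asarray(i_target, dtype=np.float64)
    i_input = np.asarray(i_input, dtype=np.float64)
    if i_target.shape != i_input.shape:
        raise ValueError("stained and unstained images must share a shape")
    _check01("I_target", i_target)
    _check01("I_input", i_input)
    return np.maximum(1.2 * i_target - 0.8 * i_input, 0.0)


def render_analytic_hne(i_foreground: np.ndarray, i_input: np.ndarray,
                        betas: BetaVectors | None = None) -> np.ndarray:
    """Beer-Lambert rendering without the melanin term -> (H, W, 3)."""
    betas = betas or BetaVectors()
    betas.validate()
    i_foreground = np.asarray(i_foreground, dtype=np.float64)
    i_input = np.asarray(i_input, dtype=np.float64)
    if i_foreground.shape != i_input.shape:
        raise ValueError("foreground and input images must share a shape")
    bh, be, _ = betas.as_arrays()
    return (np.exp(-bh * i_foreground[..., None])
            * np.exp(-be * i_input[..., None]))


def estimate_melanin(i_input: np.ndarray, i_target: np.ndarray,
                     threshold: float = 0.2) -> np.ndarray:
    """Initial melanin estimate from joint brightness.

    Melanin reflects strongly in both channels, so pixels whose product
    I_target * I_input strictly exceeds the threshold keep their unstained
    intensity; all others are zeroed.  Ties at the threshold are excluded.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("melanin threshold must lie in (0, 1)")
    i_input = np.asarray(i_input, dtype=np.float64)
    i_target = np.asarray(i_target, dtype=np.float64)
    if i_input.shape != i_target.shape:
        raise ValueError("images must share a shape")
    _check01("I_input", i_input)
    _check01("I_target", i_target)
    return np.where(i_target * i_input > threshold, i_input, 0.0)


def render_analytic_hne_with_melanin(i_foreground: np.ndarray,
                                     i_input: np.ndarray,
                                     i_melanin_labeled: np.ndarray,
                                     betas: BetaVectors | None = None
                                     ) -> np.ndarray:
    """Beer-Lambert rendering with the brown melanin absorption term."""
    betas = betas or BetaVectors()
    betas.validate()
    i_melanin_labeled = np.asarray(i_melanin_labeled, dtype=np.float64)
    base = render_analytic_hne(i_foreground, i_input, betas)
    if i_melanin_labeled.shape != np.asarray(i_input).shape:
        raise ValueError("melanin image must match the input shape")
    if not np.any(i_melanin_labeled):
        return base              # exact reduction to the melanin-free form
    _, _, bb = betas.as_arrays()
    return base * np.exp(-bb * i_melanin_labeled[..., None])


def synthesize_melanin_labels(phantom: PhantomPair, z: int | None = None
                              ) -> np.ndarray:
    """Curated melanin labels from phantom ground truth.

    On real data the thresholded estimate is cleaned up manually; phantoms
    carry an exact melanin mask, so the labeled image is the unstained
    intensity restricted to that mask.  Returns the full volume, or one
    slice when `z` is given.
    """
    mask = phantom.melanin_mask
    labeled = np.where(mask, phantom.unstained.voxels, 0.0)
    return labeled if z is None else labeled[z]


def apply_vshe(model: Generator, i_stain: np.ndarray, i_input: np.ndarray
               ) -> np.ndarray:
    """Run the learned pseudo-H&E renderer -> (H, W, 3) in (0, 1).

    `i_stain` may be a network staining output or an actual acetic-acid
    stained image; both uses share the same model.
    """
    i_stain = np.asarray(i_stain, dtype=np.float64)
    i_input = np.asarray(i_input, dtype=np.float64)
    if i_stain.shape != i_input.shape or i_stain.ndim != 2:
        raise ValueError("expected two aligned 2D images")
    out = model.infer(np.stack([i_stain, i_input]))   # (3, H, W)
    return np.moveaxis(out, 0, -1)


def to_uint8(rgb: np.ndarray) -> np.ndarray:
    """8-bit export with round-half-even after scaling by 255."""
    scaled = np.clip(np.asarray(rgb, dtype=np.float64), 0.0, 1.0) * 255.0
    return np.asarray(np.rint(scaled), dtype=np.uint8)


def write_rgb(path: str | Path, rgb: np.ndarray):
    """Write a pseudo-H&E image: PNG (8-bit) or TIFF (float32) by suffix."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, to_uint8(rgb))
    else:
        tifffile.imwrite(path, np.asarray(rgb, dtype=np.float32))
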