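"""Core data carriers for RCM volumes and registration fields.

An :class:`ImageStack` is a Z x H x W grayscale volume in [0, 1] with the
acquisition geometry (axial step between optical sections, lateral pixel
pitch) attached, because every micrometre <-> pixel conversion in the
pipeline goes through it.  A :class:`DisplacementField` is the per-pixel
(dy, dx) warp produced by registration, in pixels, with pull semantics:
the value at output pixel (y, x) points at source location (y+dy, x+dx)
in the moving image.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_AXIAL_STEP_UM = 1.52
DEFAULT_PIXEL_PITCH_UM = 0.5


@dataclasses.dataclass
class ImageStack:
    """Grayscale RCM z-stack, values in [0, 1]."""

    voxels: np.ndarray                      # (Z, H, W) float
    axial_step: float = DEFAULT_AXIAL_STEP_UM   # µm between slices
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM  # µm per pixel
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.atleast_3d(np.asarray(self.voxels, dtype=np.float64))
        if self.voxels.ndim != 3:
            raise ValueError("ImageStack expects a (Z, H, W) volume")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("ImageStack contains non-finite values")
        if self.axial_step <= 0 or self.pixel_pitch <= 0:
            raise ValueError("axial_step and pixel_pitch must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def slice(self, z: int) -> np.ndarray:
        return self.voxels[z]

    def copy(self) -> "ImageStack":
        return ImageStack(self.voxels.copy(), self.axial_step,
                          self.pixel_pitch, dict(self.metadata))

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_pitch

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_pitch

    # -- I/O ---------------------------------------------------------------
    def write_tiff(self, path: str | Path):
        path = Path(path)
        # grayscale pages; a 3-slice stack must not be mistaken for RGB
        tifffile.imwrite(path, self.voxels.astype(np.float32),
                         photometric="minisblack")
        sidecar = {"axial_step_um": self.axial_step,
                   "pixel_pitch_um": self.pixel_pitch,
                   "metadata": self.metadata}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        voxels = np.asarray(tifffile.imread(path), dtype=np.float64)
        kwargs = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            kwargs = {"axial_step": meta.get("axial_step_um",
                                             DEFAULT_AXIAL_STEP_UM),
                      "pixel_pitch": meta.get("pixel_pitch_um",
                                              DEFAULT_PIXEL_PITCH_UM),
                      "metadata": meta.get("metadata", {})}
        if voxels.max() > 1.0 + 1e-9:
            voxels = normalize01(voxels)
            kwargs.setdefault("metadata", {})["normalization"] = \
                "percentile-minmax(0.1,99.9)"
        return cls(voxels, **kwargs)


def normalize01(array: np.ndarray, lo_pct: float = 0.1,
                hi_pct: float = 99.9) -> np.ndarray:
    """Min-max normalize to [0, 1] with percentile clipping.

    Robust percentile clipping (0.1 / 99.9 by default) keeps isolated hot
    pixels from compressing the dynamic range of the whole stack.
    """
    a = np.asarray(array, dtype=np.float64)
    lo, hi = np.percentile(a, [lo_pct, hi_pct])
    if hi <= lo:
        raise ValueError("cannot normalize a constant array")
    return np.clip((a - lo) / (hi - lo), 0.0, 1.0)


@dataclasses.dataclass
class DisplacementField:
    """Per-pixel 2-vector warp (dy, dx) in pixels, pull semantics."""

    dy: np.ndarray
    dx: np.ndarray

    def __post_init__(self):
        self.dy = np.asarray(self.dy, dtype=np.float64)
        self.dx = np.asarray(self.dx, dtype=np.float64)
        if self.dy.shape != self.dx.shape or self.dy.ndim != 2:
            raise ValueError("dy and dx must be matching 2D arrays")
        if not (np.all(np.isfinite(self.dy)) and np.all(np.isfinite(self.dx))):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.dy.shape

    @classmethod
    def zero(cls, shape: tuple) -> "DisplacementField":
        return cls(np.zeros(shape), np.zeros(shape))

    @classmethod
    def constant(cls, shape: tuple, dy: float, dx: float) -> "DisplacementField":
        return cls(np.full(shape, float(dy)), np.full(shape, float(dx)))

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)

    def compose(self, other: "DisplacementField") -> "DisplacementField":
        """Field equivalent to warping by `self` after `other`.

        (warp by result) == (warp by other) applied to (warp by self), i.e.
        result(y,x) = self(y,x) + other evaluated at (y,x)+self(y,x).
        """
        from .registration.pyramid import _sample_field  # local import
        oy = _sample_field(other.dy, self.dy, self.dx)
        ox = _sample_field(other.dx, self.dy, self.dx)
        return DisplacementField(self.dy + oy, self.dx + ox)

    def write_tiff(self, path: str | Path):
        tifffile.imwrite(Path(path),
                         np.stack([self.dy, self.dx]).astype(np.float32),
                         photometric="minisblack")

    @classmethod
    def read_tiff(cls, path: str | Path) -> "DisplacementField":
        arr = np.asarray(tifffile.imread(Path(path)), dtype=np.float64)
        return cls(arr[0], arr[1])
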