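"""Synthetic RCM-like phantoms with known ground truth.

The phantoms emulate the contrast relations of acetic-acid staining
experiments on skin: a speckle-textured tissue background that is shared
between the "unstained" and "stained" channels, dark round nuclei that
become bright once stained, and melanin-rich cells that are bright in both
channels (melanin's high refractive index gives strong endogenous
reflectance without any stain).  Every planted structure — nucleus labels,
melanin masks, applied deformations and drifts — is returned alongside the
images so registration, staining and segmentation can be scored against
exact ground truth.

The phantoms are statistical stand-ins, not optical simulations: there is
no PSF, no depth-dependent SNR falloff, and the speckle is low-pass
filtered Gaussian noise rather than coherent speckle.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .stacks import ImageStack, DisplacementField

# rendering constants: background level/contrast and staining brightness.
# Acetic acid gives strong nuclear contrast, so stained nuclei sit well
# above the speckle background.
_BG_LEVEL = 0.32
_BG_AMPLITUDE = 0.06
_NUCLEUS_DARK = 0.15      # unstained nuclei multiply the background down
_STAIN_CONTRAST = 0.6     # brightness added to nuclei by "staining"
_MELANIN_LEVEL = 0.85     # bright in both channels


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of a synthetic RCM phantom pair.

    Defaults follow the acquisition geometry of ex vivo RCM stacks
    (40 slices at 1.52 µm axial increments) and nucleus sizes sit inside
    the 10-25 px diameter window used downstream by the segmenter.
    """

    height: int = 256
    width: int = 256
    n_slices: int = 40
    axial_step: float = 1.52          # µm
    pixel_pitch: float = 0.5          # µm / px
    n_nuclei: int = 40
    nucleus_radius_range: tuple = (5.0, 12.0)   # px
    melanin_fraction: float = 0.0
    speckle_grain: float = 1.0        # px (~coherent speckle at 0.5 µm/px)
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self):
        if min(self.height, self.width, self.n_slices) <= 0:
            raise ValueError("all phantom dimensions must be positive")
        if not (0.0 <= self.melanin_fraction <= 1.0):
            raise ValueError("melanin_fraction must lie in [0, 1]")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be nonnegative")
        r0, r1 = self.nucleus_radius_range
        if not (0 < r0 <= r1):
            raise ValueError("nucleus_radius_range must be positive, min <= max")
        if self.axial_step <= 0 or self.pixel_pitch <= 0:
            raise ValueError("axial_step and pixel_pitch must be positive")
        if self.noise_sigma < 0 or self.speckle_grain <= 0:
            raise ValueError("noise_sigma >= 0 and speckle_grain > 0 required")


@dataclasses.dataclass
class PhantomPair:
    """Unstained/stained phantom stacks plus ground truth volumes."""

    unstained: ImageStack
    stained: ImageStack
    nucleus_labels: np.ndarray      # uint16 (Z, H, W), 0 = background
    melanin_mask: np.ndarray        # bool (Z, H, W)
    applied_dvf: DisplacementField | None = None
    spec: PhantomSpec | None = None

    def n_objects(self) -> int:
        return int(len(np.unique(self.nucleus_labels)) - 1)

    def write(self, outdir: str | Path):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.unstained.write_tiff(outdir / "unstained.tif")
        self.stained.write_tiff(outdir / "stained.tif")
        tifffile.imwrite(outdir / "nucleus_labels.tif",
                         self.nucleus_labels.astype(np.uint16))
        tifffile.imwrite(outdir / "melanin_mask.tif",
                         self.melanin_mask.astype(np.uint8))
        summary = {"spec": dataclasses.asdict(self.spec) if self.spec else None,
                   "n_nuclei": self.n_objects(),
                   "melanin_voxels": int(self.melanin_mask.sum())}
        (outdir / "ground_truth.json").write_text(json.dumps(summary, indent=1))


def _place_nuclei(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse parameters.

    Returns (centers, semi_axes, angles, z_centers).  Raises if the
    requested count cannot be placed without overlap.
    """
    r0, r1 = spec.nucleus_radius_range
    margin = r1 + 2
    centers, axes, angles, zc = [], [], [], []
    attempts = 0
    max_attempts = 200 * max(spec.n_nuclei, 1)
    while len(centers) < spec.n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei of "
                f"radius {r0}-{r1} px in a {spec.height}x{spec.width} field; "
                "reduce n_nuclei or the nucleus radius range")
        cy = rng.uniform(margin, spec.height - margin)
        cx = rng.uniform(margin, spec.width - margin)
        a = rng.uniform(r0, r1)
        ecc = rng.uniform(0.0, 0.9)          # eccentricity <= 0.9
        b = a * np.sqrt(1.0 - ecc ** 2)
        ok = True
        for (oy, ox), (oa, _ob) in zip(centers, axes):
            if np.hypot(cy - oy, cx - ox) < a + oa + 2.0:
                ok = False
                break
        if ok:
            centers.append((cy, cx))
            axes.append((a, b))
            angles.append(rng.uniform(0, np.pi))
            zc.append(rng.uniform(0, spec.n_slices - 1))
    return centers, axes, angles, zc


def _speckle(shape, grain: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass filtered Gaussian noise, standardized; correlated in z."""
    raw = rng.normal(size=shape)
    sm = ndimage.gaussian_filter(raw, sigma=(1.0, grain, grain))
    sm = (sm - sm.mean()) / (sm.std() + 1e-12)
    return sm


def _ellipse_mask(h, w, center, semi_axes, angle) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center
    a, b = semi_axes
    ca, sa = np.cos(angle), np.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_pair(spec: PhantomSpec, shared_noise: bool = False
                  ) -> PhantomPair:
    """Generate a matched unstained/stained phantom pair.

    Deterministic for a fixed seed.  Nuclei share their lateral geometry
    across slices (a cell spans several optical sections) with a smooth
    per-slice intensity modulation; the two channels share the clean
    background but carry independent sensor-noise realizations unless
    ``shared_noise`` is set (used by the time-lapse simulator, whose
    frames must differ only where the stain signal grows).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    z, h, w = spec.n_slices, spec.height, spec.width

    background = _BG_LEVEL + _BG_AMPLITUDE * _speckle((z, h, w),
                                                      spec.speckle_grain, rng)
    background = np.clip(background, 0.02, 0.98)

    centers, axes, angles, zcs = _place_nuclei(spec, rng)
    labels = np.zeros((z, h, w), dtype=np.uint16)
    nucleus_field = np.zeros((z, h, w))          # smooth [0,1] nuclear support
    for i, (c, ax, ang, zc) in enumerate(zip(centers, axes, angles, zcs),
                                         start=1):
        mask2d = _ellipse_mask(h, w, c, ax, ang)
        # per-slice modulation: cells fade smoothly away from their z center
        zz = np.arange(z)
        zprofile = np.clip(1.0 - 0.5 * ((zz - zc) / max(z, 2.0)) ** 2,
                           0.7, 1.0)
        labels[:, mask2d] = i
        soft = ndimage.gaussian_filter(mask2d.astype(float), sigma=1.0)
        nucleus_field += zprofile[:, None, None] * soft[None]
    nucleus_field = np.clip(nucleus_field, 0.0, 1.0)

    n_mel = int(round(spec.melanin_fraction * spec.n_nuclei))
    mel_ids = rng.choice(np.arange(1, spec.n_nuclei + 1), size=n_mel,
                         replace=False) if n_mel else np.array([], dtype=int)
    melanin_mask = np.isin(labels, mel_ids)

    unstained = background * (1.0 - (1.0 - _NUCLEUS_DARK) * nucleus_field)
    stained = unstained + _STAIN_CONTRAST * nucleus_field
    if spec.noise_sigma > 0:
        noise_u = rng.normal(0, spec.noise_sigma, size=(z, h, w))
        noise_s = noise_u if shared_noise else \
            rng.normal(0, spec.noise_sigma, size=(z, h, w))
        unstained = unstained + noise_u
        stained = stained + noise_s
    # melanin-rich cells: bright in BOTH channels
    unstained = np.where(melanin_mask, np.maximum(unstained, _MELANIN_LEVEL),
                         unstained)
    stained = np.where(melanin_mask, np.maximum(stained, _MELANIN_LEVEL),
                       stained)
    unstained = np.clip(unstained, 0.0, 1.0)
    stained = np.clip(stained, 0.0, 1.0)
    # staining adds signal: enforce the ordering at nucleus pixels
    nucleus_mask = labels > 0
    stained = np.where(nucleus_mask, np.maximum(stained, unstained), stained)

    mk = lambda v: ImageStack(v, spec.axial_step, spec.pixel_pitch,
                              {"phantom_seed": spec.seed})
    return PhantomPair(mk(unstained), mk(stained), labels, melanin_mask,
                       None, spec)


def _smooth_random_field(shape, magnitude: float, seed: int,
                         grain: float = 24.0):
    """Smooth random 2D vector field with max |component| == magnitude."""
    rng = np.random.default_rng(seed)
    comps = []
    for _ in range(2):
        f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=grain)
        peak = np.abs(f).max() + 1e-12
        comps.append(f / peak * magnitude)
    return DisplacementField(comps[0], comps[1])


def apply_known_deformation(stack: ImageStack, kind: str, magnitude: float,
                            seed: int = 0):
    """Warp a stack by a known lateral deformation; return (warped, dvf).

    ``kind`` is "translation" (constant field along x) or "smooth_elastic"
    (band-limited random field with max component equal to ``magnitude``).
    The same 2D field is applied to every slice, emulating lateral drift of
    the whole stack.  The returned field is exactly the field applied, so
    registration recovery can be scored against it.
    """
    h, w = stack.shape[1:]
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    if magnitude >= min(h, w) / 4:
        raise ValueError(
            f"deformation magnitude {magnitude} px exceeds min(H,W)/4 "
            f"= {min(h, w) / 4:.1f} px")
    if kind == "translation":
        dvf = DisplacementField.constant((h, w), 0.0, magnitude)
    elif kind == "smooth_elastic":
        dvf = _smooth_random_field((h, w), magnitude, seed)
    else:
        raise ValueError(f"unknown deformation kind: {kind!r}")
    if magnitude == 0:
        return stack.copy(), DisplacementField.zero((h, w))
    from .registration.pyramid import warp
    warped = np.stack([warp(stack.voxels[z], dvf)
                       for z in range(stack.n_slices)])
    out = ImageStack(warped, stack.axial_step, stack.pixel_pitch,
                     dict(stack.metadata))
    return out, dvf


@dataclasses.dataclass
class Timelapse:
    """Phantom time-lapse of a staining run with recorded ground truth."""

    stacks: list               # list[ImageStack], t = 0 ... T-1
    drifts: list               # per-timepoint cumulative DisplacementField
    pair: PhantomPair          # endpoint ground truth (pre-drift)
    stain_level: np.ndarray    # monotone staining fraction per timepoint


def generate_timelapse_staining(spec: PhantomSpec, n_timepoints: int,
                                drift_per_frame: float = 0.0) -> Timelapse:
    """Simulate gradual acetic-acid staining over consecutive stacks.

    The first stack is fully unstained and the last fully stained; the
    nuclear signal ramps monotonically in between (smoothstep).  A constant
    per-timepoint lateral drift can be added, with the cumulative field
    recorded for each timepoint.  The sensor-noise realization is shared
    across timepoints so that, at zero drift, frames differ only where the
    stain signal grows.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    spec.validate()
    pair = generate_pair(spec, shared_noise=True)
    t = np.linspace(0.0, 1.0, n_timepoints)
    level = t * t * (3.0 - 2.0 * t)          # monotone smoothstep
    u = pair.unstained.voxels
    s = pair.stained.voxels
    h, w = spec.height, spec.width
    stacks, drifts = [], []
    from .registration.pyramid import warp
    for k in range(n_timepoints):
        vox = u + level[k] * (s - u)
        shift = k * drift_per_frame
        dvf = DisplacementField.constant((h, w), 0.0, shift)
        if shift:
            vox = np.stack([warp(vox[z], dvf) for z in range(vox.shape[0])])
        stacks.append(ImageStack(vox, spec.axial_step, spec.pixel_pitch,
                                 {"timepoint": k, "stain_level": float(level[k])}))
        drifts.append(dvf)
    return Timelapse(stacks, drifts, pair, level)
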