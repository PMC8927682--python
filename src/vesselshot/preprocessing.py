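"""Fundus image preprocessing and overlapping patch extraction.

The chain applied to every annotated image, in fixed order: gamma
correction (brightness), green-channel separation (vessels have the best
contrast in green), CLAHE (local contrast), field-of-view masking (discard
everything outside the circular retina region), and finally extraction of
overlapping square patches that later serve as few-shot class members.

At the study scale patches are 224x224 with a 64-pixel stride (160-pixel
overlap); the desk-scale test configuration uses 64x64 patches with a
48-pixel stride.  Patch origins are 0-based top-left corners and windows
are half-open ``[r, r+t) x [c, c+t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage import exposure, transform

from .exceptions import ConsistencyError, ParameterError, ShapeError, SizeError

__all__ = [
    "FundusImage", "BinaryMask", "PatchGrid", "PreprocessConfig",
    "gamma_correct", "green_channel", "clahe", "apply_field_mask",
    "extract_patches", "reassemble", "preprocess_image", "resize_mask",
    "read_image", "read_mask",
]


@dataclass
class FundusImage:
    """An RGB fundus photograph with values in [0, 1]."""

    pixels: np.ndarray  # (H, W, 3) float
    id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ShapeError(f"expected (H, W, 3) image, got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ParameterError("image values must lie in [0, 1]")


@dataclass
class BinaryMask:
    """A strictly binary mask: vessel annotation or field of view."""

    pixels: np.ndarray  # (H, W) in {0, 1}
    role: str = "vessel_annotation"  # or "field_of_view"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ShapeError(f"expected (H, W) mask, got {self.pixels.shape}")
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ParameterError(f"mask values must be 0/1, found {vals[:5]}")
        self.pixels = self.pixels.astype(np.uint8)


@dataclass
class PatchGrid:
    """Overlapping patch layout over an image extent.

    Origins step by ``stride``; when the extent minus the template is not a
    stride multiple, one extra border-flush origin is appended per axis so
    every pixel is covered.
    """

    template: int = 224
    stride: int = 64
    origins: list = field(default_factory=list)  # [(row, col), ...]

    @classmethod
    def for_extent(cls, extent: tuple[int, int], template: int = 224,
                   stride: int = 64) -> "PatchGrid":
        h, w = extent
        if h < template or w < template:
            raise SizeError(
                f"extent {h}x{w} smaller than patch template {template}")
        if stride <= 0:
            raise ParameterError("stride must be positive")

        def axis_offsets(n: int) -> list[int]:
            offs = list(range(0, n - template + 1, stride))
            if offs[-1] != n - template:
                offs.append(n - template)
            return offs

        rows = axis_offsets(h)
        cols = axis_offsets(w)
        return cls(template=template, stride=stride,
                   origins=[(r, c) for r in rows for c in cols])

    @property
    def overlap(self) -> int:
        return self.template - self.stride


def _plane(x) -> np.ndarray:
    return x.pixels if isinstance(x, (FundusImage, BinaryMask)) else np.asarray(x)


def gamma_correct(image, gamma: float):
    """Per-pixel power-law brightness correction ``out = in ** gamma``."""
    if gamma <= 0:
        raise ParameterError(f"gamma must be positive, got {gamma}")
    pixels = _plane(image)
    out = np.clip(np.power(pixels, gamma), 0.0, 1.0)
    if isinstance(image, FundusImage):
        return FundusImage(out, image.id)
    return out


def green_channel(image) -> np.ndarray:
    """Return the green plane of an RGB image unchanged."""
    pixels = _plane(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ShapeError(f"expected 3-channel image, got {pixels.shape}")
    return pixels[:, :, 1]


def clahe(plane: np.ndarray, clip_limit: float = 2.0,
          tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of a [0,1] plane.

    ``clip_limit`` follows the histogram-count convention common in imaging
    toolkits (typical values 1-4); internally it is divided by the histogram
    bin count (256) to obtain the normalized limit skimage expects.
    """
    if clip_limit <= 0:
        raise ParameterError(f"clip_limit must be positive, got {clip_limit}")
    plane = np.asarray(plane, dtype=np.float64)
    if np.ptp(plane) == 0:
        return plane.copy()  # nothing to equalize
    kernel = (max(1, plane.shape[0] // tile_grid[0]),
              max(1, plane.shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(plane, kernel_size=kernel,
                                      clip_limit=clip_limit / 256.0)
    return np.clip(out, 0.0, 1.0)


def apply_field_mask(plane: np.ndarray, fov) -> np.ndarray:
    """Zero every pixel outside the field of view."""
    plane = np.asarray(plane)
    fov_px = _plane(fov)
    if plane.shape != fov_px.shape:
        raise ShapeError(
            f"plane {plane.shape} and field mask {fov_px.shape} differ")
    return plane * fov_px


def extract_patches(plane: np.ndarray, mask, grid: PatchGrid):
    """Crop (patch, patch_mask) pairs at every grid origin."""
    plane = np.asarray(plane)
    mask_px = _plane(mask)
    t = grid.template
    if plane.shape[0] < t or plane.shape[1] < t:
        raise SizeError(f"plane {plane.shape} smaller than template {t}")
    if mask_px.shape != plane.shape:
        raise ShapeError(
            f"plane {plane.shape} and mask {mask_px.shape} differ")
    pairs = []
    for r, c in grid.origins:
        pairs.append((plane[r:r + t, c:c + t].copy(),
                      mask_px[r:r + t, c:c + t].copy()))
    return pairs


def reassemble(patches, grid: PatchGrid, extent: tuple[int, int]) -> np.ndarray:
    """Stitch per-patch probability maps back to image extent.

    Pixels covered by several overlapping patches receive the arithmetic
    mean of all covering values.
    """
    if len(patches) != len(grid.origins):
        raise ConsistencyError(
            f"{len(patches)} patches for {len(grid.origins)} origins")
    t = grid.template
    acc = np.zeros(extent, dtype=np.float64)
    cover = np.zeros(extent, dtype=np.float64)
    for patch, (r, c) in zip(patches, grid.origins):
        patch = np.asarray(patch)
        if patch.shape != (t, t):
            raise ShapeError(f"patch shape {patch.shape} != template {t}")
        acc[r:r + t, c:c + t] += patch
        cover[r:r + t, c:c + t] += 1.0
    out = np.zeros(extent, dtype=np.float64)
    np.divide(acc, cover, out=out, where=cover > 0)
    return out


@dataclass
class PreprocessConfig:
    gamma: float = 1.2
    clahe_clip: float = 2.0
    clahe_grid: tuple[int, int] = (8, 8)
    use_clahe: bool = True


def preprocess_image(image, fov, config: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain: gamma -> green channel -> CLAHE -> field mask."""
    cfg = config or PreprocessConfig()
    corrected = gamma_correct(image, cfg.gamma)
    plane = green_channel(corrected)
    if cfg.use_clahe:
        plane = clahe(plane, cfg.clahe_clip, cfg.clahe_grid)
    return apply_field_mask(plane, fov)


def resize_mask(mask, shape: tuple[int, int]) -> np.ndarray:
    """Resize a binary mask by linear interpolation, then threshold at 0.5."""
    mask_px = _plane(mask).astype(np.float64)
    if mask_px.shape == tuple(shape):
        return (mask_px > 0.5).astype(np.float64)
    resized = transform.resize(mask_px, shape, order=1, mode="edge",
                               anti_aliasing=False, preserve_range=True)
    return (resized > 0.5).astype(np.float64)


# -- file I/O -------------------------------------------------------------

def read_image(path: str | Path, image_id: str | None = None) -> FundusImage:
    """Read a PNG/TIFF/JPEG photograph, normalized to float RGB in [0,1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        arr = arr / 255.0
    elif arr.dtype == np.uint16:
        arr = arr / 65535.0
    arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return FundusImage(arr, image_id or Path(path).stem)


def read_mask(path: str | Path, role: str = "vessel_annotation") -> BinaryMask:
    """Read a single-channel 0/255 or 0/1 mask, auto-normalized to {0,1}."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return BinaryMask((arr > arr.max() / 2 if arr.max() > 0
                       else arr.astype(bool)).astype(np.uint8), role)
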