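"""Image loading and the scene container.

Conventions used throughout the package:

* pixels are stored as an ``H x W x 3`` uint8 array, channels ordered R, G, B;
* coordinates are 0-based, row-major, origin at the top-left corner, with the
  row index increasing downward;
* resizing uses area-averaging (box) interpolation, which preserves mean
  intensity and avoids the perimeter bias of nearest-neighbour sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError


class SceneLoadError(ValueError):
    """Raised when an image file cannot be read or decoded."""


@dataclass
class Scene:
    """An RGB photograph (or synthetic render) ready for analysis.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        Intensities in [0, 255], channels ordered R, G, B.
    source_id : str
        Identifier of the originating file (file stem) or generator.
    resize_factor : float
        Down-scaling factor in (0, 1] that was applied at load time.
    """

    pixels: np.ndarray
    source_id: str = "scene"
    resize_factor: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"scene pixels must be H x W x 3, got {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("scene must be at least 2 x 2 pixels")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if not (0.0 < self.resize_factor <= 1.0):
            raise ValueError("resize_factor must be in (0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def gray(self) -> np.ndarray:
        """Unweighted channel mean, float64 in [0, 255]."""
        return self.pixels.mean(axis=2)


def load_scene(path: str | Path, resize_factor: float = 1.0) -> Scene:
    """Load a photograph from PNG/JPEG/TIFF into a :class:`Scene`.

    Grayscale images are replicated across the three channels; an alpha
    channel, if present, is dropped.  When ``resize_factor < 1`` the image is
    down-scaled with anti-aliased box (area-average) interpolation to
    ``floor(original * resize_factor)`` in each dimension.

    Raises
    ------
    SceneLoadError
        If the file is missing or cannot be decoded as a raster image.
    ValueError
        If ``resize_factor`` is outside (0, 1].
    """
    if not (0.0 < resize_factor <= 1.0):
        raise ValueError(f"resize_factor must be in (0, 1], got {resize_factor}")
    path = Path(path)
    try:
        with Image.open(path) as img:
            img = img.convert("RGB")
            if resize_factor < 1.0:
                w = int(img.width * resize_factor)
                h = int(img.height * resize_factor)
                if w < 2 or h < 2:
                    raise ValueError(
                        f"resize_factor {resize_factor} would shrink {path} below 2 px"
                    )
                img = img.resize((w, h), resample=Image.BOX)
            pixels = np.asarray(img, dtype=np.uint8)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise SceneLoadError(f"cannot read image file {path}: {exc}") from exc
    return Scene(pixels=pixels, source_id=path.stem, resize_factor=resize_factor)


def save_scene(scene: Scene, path: str | Path) -> None:
    """Write a scene as an image file (format chosen from the extension).

    PNG and TIFF are lossless: a load/save/load round trip is byte-identical
    on the pixel array.  JPEG is accepted but lossy.
    """
    Image.fromarray(scene.pixels, mode="RGB").save(Path(path))
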