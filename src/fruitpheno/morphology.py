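"""Mask cleanup and object extraction.

Segmentation masks of glossy fruit typically contain specular holes (bright
reflections classified as background) and photographs often show radial
illumination fall-off toward the borders.  This module fills enclosed holes,
flattens smooth shading fields before segmentation, and extracts connected
components above a minimum area.

Connectivity follows the standard dual convention: foreground components are
8-connected, background holes 4-connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .core_io import Scene
from .segmentation import SegmentationMask

logger = logging.getLogger(__name__)

ROLE_REFERENCE = "reference"
ROLE_SPECIMEN = "specimen"
ROLE_DISCARDED = "discarded"


@dataclass
class DetectedObject:
    """One 8-connected foreground component.

    ``pixels`` holds the (row, col) coordinates of the support as an (N, 2)
    integer array.  ``role`` starts as ``"specimen"`` and is reassigned by
    reference classification; components below the area cutoff are
    ``"discarded"``.
    """

    label_id: int
    pixel_count: int
    pixels: np.ndarray
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) half-open
    role: str = ROLE_SPECIMEN
    touches_border: bool = False
    warnings: list[str] = field(default_factory=list)

    def local_mask(self) -> np.ndarray:
        """Boolean crop of the component over its bounding box."""
        r0, c0, r1, c1 = self.bbox
        m = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        m[self.pixels[:, 0] - r0, self.pixels[:, 1] - c0] = True
        return m


def fill_holes(mask: SegmentationMask) -> SegmentationMask:
    """Fill enclosed background holes.

    Every 4-connected background region with no path to the image border
    becomes foreground; all other pixels are unchanged.  Idempotent, and
    never decreases the foreground pixel count.
    """
    filled = ndimage.binary_fill_holes(mask.bits, structure=ndimage.generate_binary_structure(2, 1))
    return SegmentationMask(bits=filled, provenance=mask.provenance)


def stabilize_illumination(scene: Scene, sigma_fraction: float = 0.25) -> Scene:
    """Divide out a smooth multiplicative shading field.

    The field is estimated by heavily blurring the gray image at scale
    ``sigma_fraction * min(H, W)`` (Gaussian, computed on a down-sampled
    copy for speed), normalised to unit mean, and divided out of every
    channel.  Intensities are then rescaled so the image median is
    preserved, and clipped to [0, 255].  A uniform image passes through
    within +-1 intensity unit.
    """
    h, w = scene.shape
    gray = scene.gray()
    sigma = sigma_fraction * min(h, w)

    # estimate the field on a decimated copy; a median filter wider than any
    # specimen first, so dark (or bright) objects do not drag the field, then
    # a Gaussian to smooth the remaining steps
    step = max(1, min(h, w) // 64)
    small = gray[::step, ::step]
    med_size = max(3, int(round(sigma / step)) | 1)
    field_small = ndimage.median_filter(small, size=med_size, mode="nearest")
    field_small = ndimage.gaussian_filter(field_small, sigma=max(1.0, sigma / (4 * step)), mode="nearest")
    zoom = (h / field_small.shape[0], w / field_small.shape[1])
    fld = ndimage.zoom(field_small, zoom, order=1, mode="nearest", grid_mode=True)
    fld = np.maximum(fld, 1e-6)
    fld /= fld.mean()

    corrected = scene.pixels.astype(np.float64) / fld[:, :, None]
    old_median = np.median(scene.pixels)
    new_median = np.median(corrected)
    if new_median > 1e-9:
        corrected *= old_median / new_median
    corrected = np.clip(np.rint(corrected), 0, 255).astype(np.uint8)
    return Scene(
        pixels=corrected,
        source_id=scene.source_id,
        resize_factor=scene.resize_factor,
    )


def label_objects(mask: SegmentationMask, min_area: int = 1) -> list[DetectedObject]:
    """Extract 8-connected components, discarding those below ``min_area``.

    Components touching the image border are flagged (``touches_border``)
    with a warning message — they are measured but the record is suspect
    because the specimen may be truncated.  Surviving objects are ordered in
    "reading order": top-to-bottom in row bands one median object height
    tall, left-to-right within a band.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    labels = measure.label(mask.bits, connectivity=2)
    h, w = mask.bits.shape
    objects: list[DetectedObject] = []
    for prop in measure.regionprops(labels):
        coords = prop.coords
        r0, c0, r1, c1 = prop.bbox
        obj = DetectedObject(
            label_id=int(prop.label),
            pixel_count=int(prop.num_pixels),
            pixels=coords,
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            bbox=(int(r0), int(c0), int(r1), int(c1)),
        )
        if prop.num_pixels < min_area:
            obj.role = ROLE_DISCARDED
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            obj.touches_border = True
            obj.warnings.append("W-BORDER: component touches the image border; specimen may be truncated")
        objects.append(obj)

    kept = [o for o in objects if o.role != ROLE_DISCARDED]
    if not kept:
        logger.warning("no component survived min_area=%d", min_area)
        return objects

    heights = sorted(o.bbox[2] - o.bbox[0] for o in kept)
    band_h = max(1.0, float(heights[len(heights) // 2]))
    kept.sort(key=lambda o: (int(o.centroid[0] // band_h), o.centroid[1]))
    discarded = [o for o in objects if o.role == ROLE_DISCARDED]
    return kept + discarded
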