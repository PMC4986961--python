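"""Reference-marker detection and pixel-to-physical-unit conversion.

Scenes include circular markers of known physical diameter (one near each
side or corner of the mat).  Markers are told apart from specimens by a
score combining circularity (they are near-perfect disks) and proximity to
the image border (they sit at the edges of the mat, away from the produce).
The scale is the known diameter divided by the mean equivalent-disk diameter
of the detected markers; the dispersion of those diameters is a quality
check for camera tilt or mis-detection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .core_io import Scene
from .morphology import ROLE_DISCARDED, ROLE_REFERENCE, ROLE_SPECIMEN, DetectedObject

logger = logging.getLogger(__name__)

#: a reference candidate must be at least this circular (4*pi*A / P^2)
MIN_REFERENCE_CIRCULARITY = 0.85

#: reference-diameter coefficient of variation above this triggers a warning
DISPERSION_WARNING = 0.05


class CalibrationError(ValueError):
    """Raised when references cannot be identified or a scale computed."""


@dataclass
class CalibrationScale:
    """Pixel-to-cm conversion derived from the reference markers."""

    cm_per_px: float
    n_references_used: int
    reference_diameters_px: list[float]
    dispersion: float
    warnings: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cm_per_px <= 0:
            raise ValueError("cm_per_px must be positive")
        if self.n_references_used < 1:
            raise ValueError("at least one reference required")
        if self.warnings is None:
            self.warnings = []


def equivalent_disk_diameter(obj: DetectedObject) -> float:
    """Diameter of the disk with the object's pixel area: ``2*sqrt(A/pi)``."""
    return 2.0 * math.sqrt(obj.pixel_count / math.pi)


def classify_references(
    objects: list[DetectedObject],
    scene: Scene,
    num_references: int,
) -> list[DetectedObject]:
    """Assign ``reference``/``specimen`` roles in place and return the list.

    Candidates must exceed circularity 0.85; among candidates, the
    ``num_references`` best scores win, where the score multiplies
    circularity by closeness of the centroid to the nearest image edge.
    """
    if num_references < 1:
        raise ValueError("num_references must be >= 1 (physical units require markers)")
    live = [o for o in objects if o.role != ROLE_DISCARDED]
    if len(live) <= num_references:
        raise CalibrationError(
            f"need more than {num_references} detected objects to separate "
            f"references from specimens, found {len(live)}"
        )

    from .descriptors import circularity  # local import to avoid a cycle

    h, w = scene.shape
    half = min(h, w) / 2.0
    scored: list[tuple[float, float, DetectedObject]] = []
    for obj in live:
        circ = circularity(obj)
        r, c = obj.centroid
        edge_dist = min(r, c, h - 1 - r, w - 1 - c)
        border_score = max(0.0, 1.0 - edge_dist / half)
        scored.append((circ * border_score, circ, obj))

    candidates = [t for t in scored if t[1] > MIN_REFERENCE_CIRCULARITY]
    if len(candidates) < num_references:
        detail = ", ".join(
            f"object {t[2].label_id}: circularity={t[1]:.3f} score={t[0]:.3f}"
            for t in sorted(scored, key=lambda t: -t[0])[:10]
        )
        raise CalibrationError(
            f"only {len(candidates)} objects exceed circularity "
            f"{MIN_REFERENCE_CIRCULARITY} but {num_references} references "
            f"expected; candidates: {detail}"
        )
    candidates.sort(key=lambda t: -t[0])
    winners = {id(t[2]) for t in candidates[:num_references]}
    for obj in live:
        obj.role = ROLE_REFERENCE if id(obj) in winners else ROLE_SPECIMEN
    return objects


def compute_scale(
    references: list[DetectedObject],
    known_size_cm: float,
) -> CalibrationScale:
    """Scale from reference markers of known physical *diameter* (cm).

    ``cm_per_px`` is the known diameter over the mean equivalent-disk
    diameter of the references.  A dispersion (CV of the per-reference
    diameters) above 5% suggests a tilted camera or a mis-detected marker
    and is recorded as a warning.
    """
    refs = [o for o in references if o.role == ROLE_REFERENCE]
    if not refs:
        raise CalibrationError("no reference objects supplied")
    if known_size_cm <= 0:
        raise ValueError("known_size_cm must be positive")
    diameters = [equivalent_disk_diameter(o) for o in refs]
    mean_d = sum(diameters) / len(diameters)
    if len(diameters) > 1:
        var = sum((d - mean_d) ** 2 for d in diameters) / len(diameters)
        dispersion = math.sqrt(var) / mean_d
    else:
        dispersion = 0.0
    scale = CalibrationScale(
        cm_per_px=known_size_cm / mean_d,
        n_references_used=len(refs),
        reference_diameters_px=diameters,
        dispersion=dispersion,
    )
    if dispersion > DISPERSION_WARNING:
        msg = (
            f"W-CALIB-DISPERSION: reference diameters vary by CV={dispersion:.3f} "
            "(> 0.05); check for camera tilt or mis-detected references"
        )
        scale.warnings.append(msg)
        logger.warning(msg)
    return scale
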