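"""Synthetic photograph generator with exact ground truth.

Real validation photographs are not redistributable, so every stage of the
pipeline is exercised on generated scenes that imitate the photographic
protocol: non-touching specimens (minimum 3 px gap, enforced by rejection
sampling) on a contrasting mat with circular reference markers near the
corners.  Specimens are rotated superellipses — exponent 2 gives ordinary
ellipses with closed-form axes, eccentricity and (Ramanujan) perimeter;
other exponents create blocky or pinched shapes for solidity tests.

The ground-truth mask is the exact rasterization used to paint the scene
(never anti-aliased), so segmentation accuracy can be scored pixel by
pixel.  Optional perturbations emulate robustness experiments: exposure
scaling (shutter-speed variation), vignettes (border light fall-off), and a
camera-height rescaling of the whole geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import Scene
from .segmentation import SegmentationMask


class GenerationError(RuntimeError):
    """Raised when a scene specification cannot be realised on its canvas."""


@dataclass(frozen=True)
class SpecimenSpec:
    """One superellipse specimen: ((|x|/a)^n + (|y|/b)^n) <= 1, rotated."""

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a, b) px, a >= b
    rotation_deg: float = 0.0
    base_color: tuple[int, int, int] = (120, 22, 32)  # dark cranberry red
    gradient_amplitude: float = 0.0  # radial darkening, in [0, 1)
    hole_fraction: float = 0.0  # specular holes, fraction of area in [0, 0.3]
    exponent: float = 2.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("semi_axes must satisfy a >= b > 0")
        if not (0.0 <= self.gradient_amplitude < 1.0):
            raise ValueError("gradient_amplitude must be in [0, 1)")
        if not (0.0 <= self.hole_fraction <= 0.3):
            raise ValueError("hole_fraction must be in [0, 0.3]")


@dataclass(frozen=True)
class ReferenceLayout:
    """Circular markers of known physical size, one per corner by default."""

    count: int = 4
    diameter_px: float = 100.0
    color: tuple[int, int, int] = (12, 12, 12)
    margin_px: float = 90.0  # corner inset of the marker centres
    size_cm: float = 2.54  # declared physical diameter


@dataclass(frozen=True)
class SceneSpec:
    canvas: tuple[int, int] = (1200, 1600)
    background_color: tuple[int, int, int] = (252, 252, 252)
    vignette_amplitude: float = 0.0
    noise_sd: float = 0.0
    references: ReferenceLayout = field(default_factory=ReferenceLayout)
    specimens: tuple[SpecimenSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.vignette_amplitude < 1.0):
            raise ValueError("vignette_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SpecimenTruth:
    """Exact geometry/colour of one painted specimen."""

    center: tuple[float, float]
    length_px: float  # 2a
    width_px: float  # 2b
    rotation_deg: float
    area_px: int  # rasterized count, holes NOT subtracted
    eccentricity: float  # analytic, exponent-2 only (nan otherwise)
    perimeter_px: float  # Ramanujan, exponent-2 only (nan otherwise)
    mean_color: tuple[float, float, float]  # painted mean (pre-noise, ex-holes)
    exponent: float = 2.0


@dataclass
class GroundTruth:
    specimens: list[SpecimenTruth]
    cm_per_px: float  # implied by the reference diameter and declared size
    reference_centers: list[tuple[float, float]]
    reference_diameter_px: float


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def _raster_and_rho(spec: SpecimenSpec, canvas: tuple[int, int]):
    """Boolean raster of the specimen plus the normalised radius per pixel."""
    h, w = canvas
    a, b = spec.semi_axes
    cr, cc = spec.center
    reach = a + 2
    r0, r1 = max(0, int(cr - reach)), min(h, int(cr + reach) + 1)
    c0, c1 = max(0, int(cc - reach)), min(w, int(cc + reach) + 1)
    rows = np.arange(r0, r1, dtype=np.float64) - cr
    cols = np.arange(c0, c1, dtype=np.float64) - cc
    dy, dx = np.meshgrid(rows, cols, indexing="ij")
    th = math.radians(spec.rotation_deg)
    # rotate scene coords into the specimen frame; length axis along x'
    xp = dx * math.cos(th) + dy * math.sin(th)
    yp = -dx * math.sin(th) + dy * math.cos(th)
    n = spec.exponent
    rho = (np.abs(xp / a) ** n + np.abs(yp / b) ** n) ** (1.0 / n)
    inside = rho <= 1.0
    return (r0, c0), inside, rho


def _specimen_holes(spec: SpecimenSpec, rng: np.random.Generator):
    """Specular hole disks (centre, radius) in the specimen frame, ex-border."""
    if spec.hole_fraction <= 0:
        return []
    a, b = spec.semi_axes
    target = spec.hole_fraction * math.pi * a * b
    holes = []
    covered = 0.0
    for _ in range(64):
        if covered >= target:
            break
        radius = rng.uniform(0.12, 0.22) * b
        # keep the disk well inside so fill_holes can recover it
        rho_max = 0.65
        ang = rng.uniform(0, 2 * math.pi)
        rad = math.sqrt(rng.uniform(0, 1)) * rho_max
        center = (rad * math.cos(ang) * a, rad * math.sin(ang) * b)
        holes.append((center, radius))
        covered += math.pi * radius**2
    return holes


def generate_scene(spec: SceneSpec) -> tuple[Scene, SegmentationMask, GroundTruth]:
    """Render a scene spec into (Scene, exact foreground mask, GroundTruth).

    Deterministic given ``spec.seed``.  The returned mask is exactly the
    painted foreground (specimens minus their specular holes, plus the
    reference markers); no anti-aliasing is applied on the mask path.
    """
    h, w = spec.canvas
    rng = np.random.default_rng(spec.seed)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:, :] = spec.background_color

    fg = np.zeros((h, w), dtype=bool)
    occupied = np.zeros((h, w), dtype=bool)

    # reference markers at the corners (then along the sides if count > 4)
    ref = spec.references
    rad = ref.diameter_px / 2.0
    m = ref.margin_px
    corner_centers = [(m, m), (m, w - 1 - m), (h - 1 - m, m), (h - 1 - m, w - 1 - m)]
    side_centers = [(m, (w - 1) / 2), (h - 1 - m, (w - 1) / 2), ((h - 1) / 2, m), ((h - 1) / 2, w - 1 - m)]
    centers = (corner_centers + side_centers)[: ref.count]
    if ref.count > len(centers):
        raise GenerationError("at most 8 reference markers supported")
    yy, xx = np.mgrid[0:h, 0:w]
    for cr, cc in centers:
        disk = (yy - cr) ** 2 + (xx - cc) ** 2 <= rad**2
        img[disk] = ref.color
        fg |= disk
        occupied |= disk

    # 3 px protocol gap around everything already painted
    from scipy import ndimage

    gap = ndimage.binary_dilation(occupied, iterations=3)
    gap[:3, :] = gap[-3:, :] = True
    gap[:, :3] = gap[:, -3:] = True

    truths: list[SpecimenTruth] = []
    for sp in spec.specimens:
        (r0, c0), inside, rho = _raster_and_rho(sp, spec.canvas)
        rr, cc_ = np.nonzero(inside)
        if rr.size == 0:
            raise GenerationError(f"specimen at {sp.center} rasterizes to nothing")
        sub_gap = gap[r0 : r0 + inside.shape[0], c0 : c0 + inside.shape[1]]
        if np.any(inside & sub_gap):
            raise GenerationError(
                f"specimen at {sp.center} touches another object or the border "
                "(the protocol requires a >= 3 px gap)"
            )
        # paint with a radial gradient: multiplier 1 - g * rho^2
        mult = 1.0 - sp.gradient_amplitude * np.clip(rho, 0, 1) ** 2
        base = np.array(sp.base_color, dtype=np.float64)
        sub_img = img[r0 : r0 + inside.shape[0], c0 : c0 + inside.shape[1]]
        sub_img[inside] = base[None, :] * mult[inside, None]

        painted = inside.copy()
        for (hx, hy), hrad in _specimen_holes(sp, rng):
            th = math.radians(sp.rotation_deg)
            hr = sp.center[0] + hx * math.sin(th) + hy * math.cos(th)
            hc = sp.center[1] + hx * math.cos(th) - hy * math.sin(th)
            hole = (yy[r0 : r0 + inside.shape[0], c0 : c0 + inside.shape[1]] - hr) ** 2 + (
                xx[r0 : r0 + inside.shape[0], c0 : c0 + inside.shape[1]] - hc
            ) ** 2 <= hrad**2
            hole &= inside
            sub_img[hole] = spec.background_color
            painted &= ~hole

        mean_color = tuple(
            float(v) for v in (base[None, :] * mult[painted, None]).mean(axis=0)
        )
        sub_fg = fg[r0 : r0 + inside.shape[0], c0 : c0 + inside.shape[1]]
        sub_fg |= painted
        sub_occ = occupied[r0 : r0 + inside.shape[0], c0 : c0 + inside.shape[1]]
        sub_occ |= inside
        grow = ndimage.binary_dilation(
            occupied[max(0, r0 - 3) : r0 + inside.shape[0] + 3, max(0, c0 - 3) : c0 + inside.shape[1] + 3],
            iterations=3,
        )
        gap[max(0, r0 - 3) : r0 + inside.shape[0] + 3, max(0, c0 - 3) : c0 + inside.shape[1] + 3] |= grow

        a, b = sp.semi_axes
        is_ellipse = abs(sp.exponent - 2.0) < 1e-12
        truths.append(
            SpecimenTruth(
                center=sp.center,
                length_px=2.0 * a,
                width_px=2.0 * b,
                rotation_deg=sp.rotation_deg,
                area_px=int(inside.sum()),
                eccentricity=math.sqrt(1.0 - (b / a) ** 2) if is_ellipse else float("nan"),
                perimeter_px=ellipse_perimeter(a, b) if is_ellipse else float("nan"),
                mean_color=mean_color,
                exponent=sp.exponent,
            )
        )

    if spec.vignette_amplitude > 0:
        img *= _vignette_field(h, w, spec.vignette_amplitude)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    scene = Scene(pixels=pixels, source_id=f"synthetic-{spec.seed}", resize_factor=1.0)
    mask = SegmentationMask(bits=fg, provenance="threshold")
    truth = GroundTruth(
        specimens=truths,
        cm_per_px=ref.size_cm / ref.diameter_px,
        reference_centers=[(float(r), float(c)) for r, c in centers],
        reference_diameter_px=ref.diameter_px,
    )
    return scene, mask, truth


def _vignette_field(h: int, w: int, amplitude: float) -> np.ndarray:
    """Radial multiplicative fall-off: 1 at centre, 1 - amplitude at corners."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    r /= r.max()
    return (1.0 - amplitude * r**2)[:, :, None]


def random_scene_spec(
    seed: int,
    n_specimens: int = 25,
    canvas: tuple[int, int] = (1200, 1600),
    semi_axis_major: tuple[float, float] = (42.0, 60.0),
    aspect: tuple[float, float] = (0.62, 0.95),
    gradient_amplitude: float = 0.15,
    hole_fraction: float = 0.0,
    noise_sd: float = 0.0,
    vignette_amplitude: float = 0.0,
    exponent: float = 2.0,
    references: ReferenceLayout | None = None,
    max_attempts: int = 1000,
) -> SceneSpec:
    """A batch-of-fruits layout: ``n_specimens`` non-touching ellipses.

    Sizes and aspects emulate cranberry-like produce photographed at a
    height where a fruit spans roughly 80-120 px.  Placement is rejection
    sampling; an explicit error is raised if the canvas cannot hold the
    requested batch after ``max_attempts`` draws per specimen.
    """
    rng = np.random.default_rng(seed)
    refs = references or ReferenceLayout()
    h, w = canvas
    placed: list[SpecimenSpec] = []
    # the field protocol keeps produce in the central zone, markers at the
    # mat borders; enforce that so border proximity separates the two
    clearance = refs.margin_px + refs.diameter_px / 2.0 + 30

    for _ in range(n_specimens):
        for attempt in range(max_attempts):
            a = rng.uniform(*semi_axis_major)
            b = a * rng.uniform(*aspect)
            reach = a + 4
            cr = rng.uniform(clearance + reach, h - 1 - clearance - reach)
            cc = rng.uniform(clearance + reach, w - 1 - clearance - reach)
            ok = True
            for other in placed:
                d = math.hypot(cr - other.center[0], cc - other.center[1])
                if d < a + other.semi_axes[0] + 8:
                    ok = False
                    break
            if ok:
                hue_jitter = rng.uniform(0.75, 1.1)
                color = tuple(
                    int(np.clip(round(c * hue_jitter), 0, 255)) for c in (132, 24, 34)
                )
                placed.append(
                    SpecimenSpec(
                        center=(cr, cc),
                        semi_axes=(a, b),
                        rotation_deg=float(rng.uniform(0, 180)),
                        base_color=color,  # type: ignore[arg-type]
                        gradient_amplitude=gradient_amplitude,
                        hole_fraction=hole_fraction,
                        exponent=exponent,
                    )
                )
                break
        else:
            raise GenerationError(
                f"could not place specimen {len(placed) + 1}/{n_specimens} after "
                f"{max_attempts} attempts; canvas too small for the batch"
            )
    return SceneSpec(
        canvas=canvas,
        vignette_amplitude=vignette_amplitude,
        noise_sd=noise_sd,
        references=refs,
        specimens=tuple(placed),
        seed=seed,
    )


def perturb_lighting(
    scene: Scene, exposure_factor: float, vignette_amplitude: float = 0.0
) -> Scene:
    """Exposure scaling plus optional vignette, clipped to [0, 255].

    ``exposure_factor`` must lie in [0.1, 4]; 1.0 with no vignette is the
    identity.  Emulates shutter-speed variation between photography
    sessions.
    """
    if not (0.1 <= exposure_factor <= 4.0):
        raise ValueError("exposure_factor must be in [0.1, 4]")
    img = scene.pixels.astype(np.float64) * exposure_factor
    if vignette_amplitude > 0:
        img *= _vignette_field(*scene.shape, vignette_amplitude)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Scene(
        pixels=pixels,
        source_id=f"{scene.source_id}-exp{exposure_factor:g}",
        resize_factor=scene.resize_factor,
    )


def simulate_camera_height(spec: SceneSpec, relative_height: float) -> SceneSpec:
    """Rescale every pixel dimension by ``1 / relative_height``.

    Raising the camera shrinks the projection of references and specimens
    alike (centres scale about the canvas centre); physical-unit outputs
    should be invariant because the markers shrink too.  Fails if any
    specimen would fall under 10 px across.
    """
    if relative_height <= 0:
        raise ValueError("relative_height must be positive")
    k = 1.0 / relative_height
    h, w = spec.canvas
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    new_specs = []
    for sp in spec.specimens:
        a, b = sp.semi_axes[0] * k, sp.semi_axes[1] * k
        if 2 * b < 10:
            raise GenerationError(
                f"specimen at {sp.center} would span {2 * b:.1f} px "
                "(< 10 px) at this camera height"
            )
        new_specs.append(
            replace(
                sp,
                center=(cy + (sp.center[0] - cy) * k, cx + (sp.center[1] - cx) * k),
                semi_axes=(a, b),
            )
        )
    refs = replace(
        spec.references,
        diameter_px=spec.references.diameter_px * k,
        margin_px=max(4.0, cy - (cy - spec.references.margin_px) * k)
        if relative_height > 1
        else spec.references.margin_px * k,
    )
    return replace(spec, specimens=tuple(new_specs), references=refs)


def rescale_spec(spec: SceneSpec, factor: float) -> SceneSpec:
    """Render the same physical scene at ``factor`` times the resolution.

    Scales the canvas and every pixel dimension together (unlike
    :func:`simulate_camera_height`, which keeps the canvas fixed).
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    h, w = spec.canvas
    new_specs = tuple(
        replace(
            sp,
            center=(sp.center[0] * factor, sp.center[1] * factor),
            semi_axes=(sp.semi_axes[0] * factor, sp.semi_axes[1] * factor),
        )
        for sp in spec.specimens
    )
    refs = replace(
        spec.references,
        diameter_px=spec.references.diameter_px * factor,
        margin_px=spec.references.margin_px * factor,
    )
    return replace(
        spec,
        canvas=(int(round(h * factor)), int(round(w * factor))),
        specimens=new_specs,
        references=refs,
    )
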