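"""End-to-end pipeline: images in, phenotype tables and figures out.

Each image is processed independently (results do not depend on batch
order): load and optionally resize, stabilise illumination, segment
(threshold or neural), fill holes, extract components, identify reference
markers, calibrate, and measure.  Per-image tables are pooled into one CSV;
annotated figures overlay the perimeter (green), length (magenta) and width
(blue) of every object.  Input images are never modified.

With identical inputs, configuration and seed the output CSV is
byte-identical across reruns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, descriptors, morphology, segmentation
from .core_io import Scene, load_scene
from .descriptors import SPECIMEN_COLUMNS, PhenotypeRecord

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


@dataclass
class RunConfig:
    """Arguments of one batch run (mirrors the CLI flags)."""

    images_dir: str | Path = "."
    resize_factor: float = 1.0
    min_area: int = 100
    method: str = "threshold"  # or "neural"
    channels: tuple[str, ...] = ("B",)
    cutoffs: tuple[int, ...] = (50,)
    polarity: str = "object_darker"
    classifier_path: str | Path | None = None
    num_references: int = 4
    reference_size_cm: float = 2.54
    stabilize: bool = True
    gray_mode: str = "mean"
    emit_csv: bool = True
    emit_figures: bool = False
    output_csv: str | Path = "phenotypes.csv"
    figures_dir: str | Path = "figures"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("threshold", "neural"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "neural" and self.classifier_path is None:
            raise ValueError("method=neural requires classifier_path")
        if self.num_references < 1:
            raise ValueError("num_references must be >= 1")


@dataclass
class SceneResult:
    """Outcome of one image: records, QC, warnings, or a failure message."""

    source_id: str
    specimens: list[PhenotypeRecord] = field(default_factory=list)
    references: list[PhenotypeRecord] = field(default_factory=list)
    scale: calibration.CalibrationScale | None = None
    n_objects: int = 0
    warnings: list[str] = field(default_factory=list)
    error: str | None = None


def process_scene(
    scene: Scene,
    config: RunConfig,
    classifier: segmentation.PixelClassifier | None = None,
) -> SceneResult:
    """Run the full measurement chain on one already-loaded scene."""
    result = SceneResult(source_id=scene.source_id)
    work = morphology.stabilize_illumination(scene) if config.stabilize else scene
    if config.method == "threshold":
        spec = segmentation.ThresholdSpec(
            channels=config.channels, cutoffs=config.cutoffs, polarity=config.polarity
        )
        mask = segmentation.segment_threshold(work, spec)
    else:
        clf = classifier or segmentation.PixelClassifier.load(config.classifier_path)
        mask = segmentation.segment_with_classifier(work, clf)
    mask = morphology.fill_holes(mask)
    objects = morphology.label_objects(mask, min_area=config.min_area)
    live = [o for o in objects if o.role != morphology.ROLE_DISCARDED]
    result.n_objects = len(live)
    for obj in live:
        result.warnings.extend(obj.warnings)
    calibration.classify_references(objects, work, config.num_references)
    refs = [o for o in live if o.role == morphology.ROLE_REFERENCE]
    scale = calibration.compute_scale(refs, config.reference_size_cm)
    result.scale = scale
    result.warnings.extend(scale.warnings)
    # colour always from the original (pre-stabilisation) pixels
    result.specimens, result.references = descriptors.assemble_records(
        objects, scene, scale, gray_mode=config.gray_mode
    )
    return result


def run_pipeline(config: RunConfig) -> tuple[pd.DataFrame, list[SceneResult]]:
    """Process every readable image under ``config.images_dir``.

    A failure on one image is logged and recorded; the batch continues.
    Returns the pooled specimen table (sorted by source_id, then
    object_index) and the per-scene results.
    """
    images_dir = Path(config.images_dir)
    paths = sorted(
        p for p in images_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not paths:
        raise FileNotFoundError(f"no readable images in {images_dir}")

    classifier = None
    if config.method == "neural":
        classifier = segmentation.PixelClassifier.load(config.classifier_path)

    results: list[SceneResult] = []
    for path in paths:
        try:
            scene = load_scene(path, resize_factor=config.resize_factor)
            res = process_scene(scene, config, classifier=classifier)
        except Exception as exc:  # per-image isolation: log, continue
            logger.error("image %s failed: %s", path.name, exc)
            res = SceneResult(source_id=path.stem, error=str(exc))
        else:
            logger.info(
                "%s: %d objects, %d specimens, cm_per_px=%.5f",
                path.name,
                res.n_objects,
                len(res.specimens),
                res.scale.cm_per_px if res.scale else float("nan"),
            )
        results.append(res)

    pooled = pool_records(results)
    if config.emit_csv:
        write_csv(pooled, config.output_csv)
    if config.emit_figures:
        figdir = Path(config.figures_dir)
        figdir.mkdir(parents=True, exist_ok=True)
        for path, res in zip(paths, results):
            if res.error is None:
                scene = load_scene(path, resize_factor=config.resize_factor)
                render_annotations(
                    scene,
                    res.specimens,
                    res.references,
                    figdir / f"{res.source_id}_annotated.png",
                )
    return pooled, results


def pool_records(results: list[SceneResult]) -> pd.DataFrame:
    """Pooled specimen table, deterministically ordered."""
    recs: list[PhenotypeRecord] = []
    for res in results:
        recs.extend(res.specimens)
    frame = descriptors.records_to_frame(recs)
    if len(frame):
        frame = frame.sort_values(["source_id", "object_index"], kind="mergesort")
        frame = frame.reset_index(drop=True)
    return frame


def write_csv(records: pd.DataFrame | list[PhenotypeRecord], path: str | Path) -> None:
    """Write the specimen table as RFC-4180 CSV, floats at 6 significant digits."""
    if not isinstance(records, pd.DataFrame):
        records = descriptors.records_to_frame(records)
    records.to_csv(Path(path), index=False, float_format="%.6g", lineterminator="\r\n")


def render_annotations(
    scene: Scene,
    specimens: list[PhenotypeRecord],
    references: list[PhenotypeRecord],
    path: str | Path,
) -> None:
    """Annotated overlay: perimeter green, length magenta, width blue.

    Specimen indices are printed at the centroids; reference markers are
    outlined with a dashed yellow circle instead of measurement lines.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage import measure as skmeasure

    h, w = scene.shape
    fig, ax = plt.subplots(figsize=(w / 120, h / 120), dpi=120)
    ax.imshow(scene.pixels)
    ax.set_axis_off()

    # outlines via an intensity iso-contour in a crop around each centroid
    gray = scene.gray()
    for rec in specimens:
        r0 = max(0, int(rec.centroid_row - rec.length_px))
        c0 = max(0, int(rec.centroid_col - rec.length_px))
        r1 = min(h, int(rec.centroid_row + rec.length_px) + 1)
        c1 = min(w, int(rec.centroid_col + rec.length_px) + 1)
        crop = gray[r0:r1, c0:c1]
        level = 0.5 * (crop.min() + crop.max())
        for contour in skmeasure.find_contours(crop, level):
            ax.plot(contour[:, 1] + c0, contour[:, 0] + r0, color="lime", lw=1.0)
        if rec.length_segment:
            (ar, ac), (br, bc) = rec.length_segment
            ax.plot([ac, bc], [ar, br], color="magenta", lw=1.2)
        if rec.width_segment:
            (ar, ac), (br, bc) = rec.width_segment
            ax.plot([ac, bc], [ar, br], color="blue", lw=1.2)
        ax.text(
            rec.centroid_col,
            rec.centroid_row,
            str(rec.object_index),
            color="white",
            ha="center",
            va="center",
            fontsize=8,
        )
    for rec in references:
        radius = rec.length_px / 2.0
        circle = plt.Circle(
            (rec.centroid_col, rec.centroid_row),
            radius + 3,
            fill=False,
            color="yellow",
            ls="--",
            lw=1.2,
        )
        ax.add_patch(circle)
    fig.savefig(Path(path), bbox_inches="tight", pad_inches=0)
    plt.close(fig)
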