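"""Foreground/background segmentation.

Two strategies are offered, matching the two photographic situations in the
field protocol:

* **threshold** — for scenes with strong object/background contrast, a cutoff
  in one or more RGB channels (dark objects on a white mat, or the reverse);
* **neural** — a small pixel classifier (3 inputs -> 10 sigmoid hidden units
  -> softmax) trained on user-supplied colour swatches, for fruits whose
  colour varies too much for a single threshold.

The classifier splits its training pixels 70/15/15 into train/validation/test
partitions, minimises cross-entropy with a full-batch quasi-Newton optimiser,
and early-stops on the validation loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from .core_io import Scene, SceneLoadError, load_scene

CLASSIFIER_FORMAT_VERSION = 1

#: pixels per class are capped; larger swatches are subsampled
MAX_PIXELS_PER_CLASS = 1_000_000

_HIDDEN_UNITS = 10
_SPLIT_FRACTIONS = (0.70, 0.15, 0.15)


class TrainingError(ValueError):
    """Raised when the swatch set cannot define a classification problem."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-channel cutoff rule.

    With polarity ``"object_darker"`` a pixel is foreground iff its intensity
    is strictly below the cutoff in *every* selected channel; with
    ``"object_lighter"`` strictly above.
    """

    channels: tuple[str, ...]
    cutoffs: tuple[int, ...]
    polarity: str = "object_darker"

    def __post_init__(self) -> None:
        chans = tuple(self.channels)
        if not chans or any(c not in "RGB" for c in chans):
            raise ValueError("channels must be a non-empty subset of {R, G, B}")
        if len(set(chans)) != len(chans):
            raise ValueError("channels must be unique")
        cuts = tuple(int(c) for c in self.cutoffs)
        if len(cuts) != len(chans):
            raise ValueError("one cutoff per selected channel required")
        if any(not 0 <= c <= 255 for c in cuts):
            raise ValueError("cutoffs must lie in [0, 255]")
        if self.polarity not in ("object_darker", "object_lighter"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        object.__setattr__(self, "channels", chans)
        object.__setattr__(self, "cutoffs", cuts)


@dataclass
class SegmentationMask:
    """Boolean foreground raster aligned with a :class:`~fruitpheno.core_io.Scene`."""

    bits: np.ndarray
    provenance: str = "threshold"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape


_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


def segment_threshold(scene: Scene, spec: ThresholdSpec) -> SegmentationMask:
    """Threshold the scene per :class:`ThresholdSpec`.

    Multiple channels are combined with AND: a pixel must satisfy the cutoff
    in every selected channel to be foreground.
    """
    mask = np.ones(scene.shape, dtype=bool)
    for chan, cut in zip(spec.channels, spec.cutoffs):
        values = scene.pixels[:, :, _CHANNEL_INDEX[chan]]
        if spec.polarity == "object_darker":
            mask &= values < cut
        else:
            mask &= values > cut
    return SegmentationMask(bits=mask, provenance="threshold")


def ingest_training_swatches(
    paths: Sequence[str | Path],
    labels: Sequence[str],
    max_pixels_per_class: int = MAX_PIXELS_PER_CLASS,
    seed: int = 0,
) -> "np.ndarray":
    """Pool swatch images into a labelled pixel table.

    Each pixel of each swatch becomes one (R, G, B, label) row; swatches
    sharing a label are pooled.  Exactly one label must be ``"background"``.
    Classes contributing more than ``max_pixels_per_class`` pixels are
    subsampled (seeded) — moderate-resolution swatches suffice for pixel
    classification.

    Returns a structured record array with fields ``r, g, b`` (uint8) and
    ``label`` (str).
    """
    if len(paths) != len(labels):
        raise ValueError("paths and labels must have equal length")
    if len(paths) < 2:
        raise TrainingError("at least two swatches (background + object) required")
    unique = sorted(set(labels))
    if len(unique) < 2:
        raise TrainingError("at least two distinct classes required")
    if "background" not in set(labels):
        raise TrainingError('one class must be labelled "background"')

    rgb_by_label: dict[str, list[np.ndarray]] = {}
    for path, label in zip(paths, labels):
        scene = load_scene(path)
        px = scene.pixels.reshape(-1, 3)
        if px.shape[0] == 0:
            raise SceneLoadError(f"swatch {path} contains no pixels")
        rgb_by_label.setdefault(label, []).append(px)

    rng = np.random.default_rng(seed)
    rows_rgb: list[np.ndarray] = []
    rows_label: list[np.ndarray] = []
    for label in sorted(rgb_by_label):
        px = np.concatenate(rgb_by_label[label], axis=0)
        if px.shape[0] > max_pixels_per_class:
            keep = rng.choice(px.shape[0], size=max_pixels_per_class, replace=False)
            px = px[np.sort(keep)]
        rows_rgb.append(px)
        rows_label.append(np.full(px.shape[0], label, dtype=object))
    rgb = np.concatenate(rows_rgb, axis=0)
    lab = np.concatenate(rows_label, axis=0)
    table = np.empty(
        rgb.shape[0],
        dtype=[("r", np.uint8), ("g", np.uint8), ("b", np.uint8), ("label", object)],
    )
    table["r"], table["g"], table["b"] = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    table["label"] = lab
    return table


def pixel_table_from_arrays(rgb: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Build a pixel table directly from an (N, 3) uint8 array and labels."""
    rgb = np.asarray(rgb, dtype=np.uint8)
    table = np.empty(
        rgb.shape[0],
        dtype=[("r", np.uint8), ("g", np.uint8), ("b", np.uint8), ("label", object)],
    )
    table["r"], table["g"], table["b"] = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    table["label"] = np.asarray(list(labels), dtype=object)
    return table


@dataclass
class PixelClassifier:
    """A trained 3-input, 10-hidden-unit, softmax pixel classifier.

    ``class_labels`` is ordered with ``"background"`` first; ``predict_proba``
    columns follow that order.  Inputs are R, G, B scaled to [0, 1].
    """

    class_labels: list[str]
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    training_report: dict = field(default_factory=dict)

    def predict_proba(self, rgb: np.ndarray) -> np.ndarray:
        """Class probabilities for an (N, 3) array of [0, 255] intensities."""
        x = np.asarray(rgb, dtype=np.float64) / 255.0
        hidden = 1.0 / (1.0 + np.exp(-(x @ self.coefs[0] + self.intercepts[0])))
        logits = hidden @ self.coefs[1] + self.intercepts[1]
        if logits.shape[1] == 1:  # sklearn binary case: single logistic output
            p1 = 1.0 / (1.0 + np.exp(-logits[:, 0]))
            probs = np.column_stack([1.0 - p1, p1])
        else:
            logits -= logits.max(axis=1, keepdims=True)
            np.exp(logits, out=logits)
            probs = logits / logits.sum(axis=1, keepdims=True)
        return probs

    def save(self, path: str | Path) -> None:
        """Serialize to a single portable, version-tagged JSON file."""
        payload = {
            "format": "fruitpheno-pixel-classifier",
            "version": CLASSIFIER_FORMAT_VERSION,
            "class_labels": self.class_labels,
            "coefs": [c.tolist() for c in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "training_report": self.training_report,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "fruitpheno-pixel-classifier":
            raise ValueError(f"{path} is not a fruitpheno classifier file")
        if payload.get("version") != CLASSIFIER_FORMAT_VERSION:
            raise ValueError(f"unsupported classifier format version in {path}")
        return cls(
            class_labels=list(payload["class_labels"]),
            coefs=[np.asarray(c, dtype=np.float64) for c in payload["coefs"]],
            intercepts=[np.asarray(b, dtype=np.float64) for b in payload["intercepts"]],
            training_report=payload.get("training_report", {}),
        )


def _split_sizes(n: int) -> tuple[int, int, int]:
    """Exact 70/15/15 partition sizes; remainder pixels go to training."""
    n_val = int(round(n * _SPLIT_FRACTIONS[1]))
    n_test = int(round(n * _SPLIT_FRACTIONS[2]))
    return n - n_val - n_test, n_val, n_test


def train_pixel_classifier(
    pixel_table: np.ndarray,
    seed: int = 0,
    max_checks: int = 60,
    epochs_per_check: int = 25,
    patience: int = 6,
) -> PixelClassifier:
    """Train the pixel classifier on a labelled pixel table.

    Pixels are shuffled with the seed and split 70/15/15 into
    train/validation/test.  Optimisation is full-batch L-BFGS on the
    cross-entropy, run in chunks of ``epochs_per_check`` iterations; after
    each chunk the validation loss is checked and training stops when it has
    not improved for ``patience`` consecutive checks.  With a fixed seed the
    procedure is bit-reproducible.

    The returned ``training_report`` records the pixel count, split
    fractions and sizes, per-partition cross-entropy and test accuracy, plus
    a convergence note.
    """
    labels_all = np.asarray(pixel_table["label"], dtype=object)
    classes, counts = np.unique(labels_all.astype(str), return_counts=True)
    if len(classes) < 2:
        raise TrainingError("training requires at least 2 classes")
    if "background" not in classes:
        raise TrainingError('one class must be labelled "background"')
    if counts.min() < 100:
        raise TrainingError("each class needs at least 100 pixels")

    # background first, remaining classes alphabetical
    ordered = ["background"] + [c for c in sorted(classes) if c != "background"]
    label_index = {c: i for i, c in enumerate(ordered)}
    y = np.array([label_index[str(l)] for l in labels_all])
    x = (
        np.column_stack([pixel_table["r"], pixel_table["g"], pixel_table["b"]])
        .astype(np.float64)
        / 255.0
    )

    n = x.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train, n_val, n_test = _split_sizes(n)
    idx_train = perm[:n_train]
    idx_val = perm[n_train : n_train + n_val]
    idx_test = perm[n_train + n_val :]

    clf = MLPClassifier(
        hidden_layer_sizes=(_HIDDEN_UNITS,),
        activation="logistic",
        solver="lbfgs",
        alpha=1e-6,
        max_iter=epochs_per_check,
        warm_start=True,
        random_state=int(seed) % (2**31),
    )
    all_classes = np.arange(len(ordered))
    best_val = np.inf
    best_weights: tuple[list[np.ndarray], list[np.ndarray]] | None = None
    stale = 0
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _check in range(max_checks):
            clf.fit(x[idx_train], y[idx_train])
            val_loss = log_loss(
                y[idx_val], clf.predict_proba(x[idx_val]), labels=all_classes
            )
            if val_loss < best_val - 1e-7:
                best_val = val_loss
                best_weights = (
                    [c.copy() for c in clf.coefs_],
                    [b.copy() for b in clf.intercepts_],
                )
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    converged = True
                    break

    if best_weights is None:  # pragma: no cover - defensive
        best_weights = (clf.coefs_, clf.intercepts_)
    model = PixelClassifier(
        class_labels=ordered, coefs=best_weights[0], intercepts=best_weights[1]
    )
    losses = {}
    for part, idx in (("train", idx_train), ("validation", idx_val), ("test", idx_test)):
        losses[part] = float(
            log_loss(y[idx], model.predict_proba(x[idx] * 255.0), labels=all_classes)
        )
    test_pred = model.predict_proba(x[idx_test] * 255.0).argmax(axis=1)
    model.training_report = {
        "n_pixels_total": int(n),
        "split_fractions": list(_SPLIT_FRACTIONS),
        "split_sizes": [int(n_train), int(n_val), int(n_test)],
        "final_cross_entropy": losses,
        "test_accuracy": float(np.mean(test_pred == y[idx_test])),
        "converged": converged,
        "note": "" if converged else "early-stopping patience not reached before max checks",
        "seed": int(seed),
    }
    return model


def segment_with_classifier(scene: Scene, clf: PixelClassifier) -> SegmentationMask:
    """Classify every pixel; foreground is the union of non-background classes.

    Ties in the class probabilities break toward background (the background
    class occupies column 0 and ``argmax`` keeps the first maximum).
    """
    h, w = scene.shape
    probs = clf.predict_proba(scene.pixels.reshape(-1, 3))
    fg = probs.argmax(axis=1) != 0
    return SegmentationMask(bits=fg.reshape(h, w), provenance="neural")
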