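import numpy as np
import pytest

from fruitpheno import (
    RunConfig,
    generate_scene,
    random_scene_spec,
    train_pixel_classifier,
)
from fruitpheno.pipeline import process_scene
from fruitpheno.segmentation import pixel_table_from_arrays


@pytest.fixture(scope="session")
def batch_scene():
    """A noiseless 25-fruit batch with 4 corner markers (seed 1)."""
    spec = random_scene_spec(seed=1, n_specimens=25)
    scene, mask, truth = generate_scene(spec)
    return spec, scene, mask, truth


@pytest.fixture(scope="session")
def batch_result(batch_scene):
    """The full measurement chain run on the default batch."""
    _, scene, _, _ = batch_scene
    return process_scene(scene, RunConfig(min_area=300))


@pytest.fixture(scope="session")
def separable_pixel_table():
    """10,000 perfectly separable pixels: near-white mat vs dark-red fruit."""
    rng = np.random.default_rng(42)
    white = np.clip(rng.normal(250, 2, (5000, 3)), 0, 255).astype(np.uint8)
    red = np.clip(
        rng.normal([150, 28, 38], 4, (5000, 3)), 0, 255
    ).astype(np.uint8)
    rgb = np.vstack([white, red])
    labels = ["background"] * 5000 + ["fruit"] * 5000
    return pixel_table_from_arrays(rgb, labels)


@pytest.fixture(scope="session")
def white_red_classifier(separable_pixel_table):
    return train_pixel_classifier(separable_pixel_table, seed=1)


def match_truth(record, truth):
    """The ground-truth specimen nearest to a measured record's centroid."""
    return min(
        truth.specimens,
        key=lambda t: (t.center[0] - record.centroid_row) ** 2
        + (t.center[1] - record.centroid_col) ** 2,
    )
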