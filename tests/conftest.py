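import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from seedscore import (
    FeatureMatrix,
    SeedImage,
    extract_feature_table,
    iter_images,
    make_label_table,
    presets,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_tile(h=20, w=20, background=200, block=None, value=40, seed_id="s0", t=1):
    """Uniform tile with an optional darker rectangular block."""
    px = np.full((h, w, 3), background, dtype=np.uint8)
    if block is not None:
        r0, r1, c0, c1 = block
        px[r0:r1, c0:c1] = value
    return SeedImage(pixels=px, seed_id=seed_id, time_index=t)


@pytest.fixture(scope="session")
def small_image_dataset():
    """A small easy-preset synthetic dataset with extracted features.

    30 seeds x 3 time points on a reduced tile keeps rendering cheap while
    exercising the full segmentation + feature path.
    """
    config = presets(n_seeds=30, n_timepoints=3, rng_seed=7)["easy"]
    images, truths = [], []
    for image, truth in iter_images(config):
        images.append(image)
        truths.append(truth)
    features = extract_feature_table(images)
    truth_df = pd.DataFrame(truths)
    labels = make_label_table(
        truth_df.rename(columns={"germinated": "label"})[
            ["seed_id", "time_index", "label"]
        ]
    )
    return {
        "config": config,
        "images": images,
        "features": features,
        "labels": labels,
        "ground_truth": truth_df,
    }


@pytest.fixture
def gaussian_clusters():
    """Two separable Gaussian clusters as a stand-in feature matrix."""
    rng = np.random.default_rng(42)
    n_per = 60
    x0 = rng.normal(0.0, 0.6, size=(n_per, 4))
    x1 = rng.normal(3.0, 0.6, size=(n_per, 4))
    values = np.vstack([x0, x1])
    labels = np.r_[np.zeros(n_per, int), np.ones(n_per, int)]
    keys = [(f"s{i:03d}", 1) for i in range(2 * n_per)]
    matrix = FeatureMatrix(
        values=values,
        feature_names=[f"f{j}" for j in range(4)],
        image_keys=keys,
        stage="normalized",
    )
    return matrix, labels
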