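import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from affectdecode.synthetic import FeatureSimConfig, RaterSimConfig, simulate_ratings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_table(rows):
    """Build a ratings table from (respondent, image, rating) triples."""
    return pd.DataFrame(
        {
            "respondent_id": [r[0] for r in rows],
            "image_id": [r[1] for r in rows],
            "rating": [float(r[2]) for r in rows],
            "affect": "beauty",
            "image_category": "all",
            "dataset_id": "toy",
        }
    )


@pytest.fixture(scope="session")
def toy_table():
    """3 respondents x 4 images with hand-computable mean-minus-one values."""
    rows = []
    ratings = {"A": [1, 3, 5, 7], "B": [2, 2, 6, 6], "C": [1, 4, 4, 7]}
    for resp, vals in ratings.items():
        for j, v in enumerate(vals):
            rows.append((resp, f"img{j}", v))
    return make_table(rows)


@pytest.fixture(scope="session")
def small_sim():
    """A modest rater pool + truth reused across tests (fast)."""
    cfg = RaterSimConfig(n_images=120, n_raters=16, seed=11)
    return simulate_ratings(cfg)


@pytest.fixture(scope="session")
def small_feature_cfg():
    return FeatureSimConfig(n_layers=4, dims_per_layer=(48, 48, 48, 48), seed=5)
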