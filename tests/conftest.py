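import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ctradiomics.synthetic import CohortSimConfig, generate_cohort


def random_labeled_volume(rng, shape=(4, 4, 2), n_levels=4, mask_p=1.0):
    """A random discretised volume with labels 1..n_levels and a random mask."""
    labels = rng.integers(1, n_levels + 1, size=shape)
    if mask_p >= 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = rng.random(shape) < mask_p
        if not mask.any():
            mask.flat[0] = True
    labels = np.where(mask, labels, 0)
    return labels, mask


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default study-scale settings."""
    cohort, features, blood, truth = generate_cohort(CohortSimConfig(seed=42))
    merged = cohort.merge(features, on=["patient", "visit"])
    return {
        "cohort": cohort,
        "features": features,
        "blood": blood,
        "truth": truth,
        "merged": merged,
        "feature_cols": [c for c in features.columns if c.startswith("f")],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
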