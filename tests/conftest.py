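import numpy as np
import pandas as pd
import pytest

from tissueclock.containers import BetaMatrix
from tissueclock.io import filter_missing, impute_missing
from tissueclock.simulate import SimConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """3-tissue panel with planted common and specific markers."""
    cfg = SimConfig(
        n_tissues=3,
        n_samples_per_tissue=120,
        n_probes=800,
        n_common_markers=12,
        n_specific_markers_per_tissue=8,
        seed=3,
    )
    return cfg, generate_panel(cfg)


@pytest.fixture(scope="session")
def harmonized_tissue(small_panel):
    """First tissue of the small panel, imputed and missing-filtered."""
    cfg, (mats, tables, annotation, truth) = small_panel
    mat = impute_missing(filter_missing(mats[0]))
    return mat, tables[0], annotation, truth


@pytest.fixture()
def tiny_matrix():
    values = pd.DataFrame(
        [[0.1, 0.2, 0.3], [0.5, np.nan, 0.7], [0.9, 0.8, 0.7]],
        index=["cgA", "cgB", "cgC"],
        columns=["s1", "s2", "s3"],
    )
    return BetaMatrix(values, platform="toy")


@pytest.fixture()
def tiny_samples():
    return pd.DataFrame(
        {"sample_id": ["s1", "s2", "s3"], "age": [25.0, 50.0, 75.0], "tissue": "toy"}
    )
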