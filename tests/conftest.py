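import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from enterotyper import simulate
from enterotyper.diversity import DistanceMatrix
from enterotyper.tables import FeatureTable, TaxonomyMap, to_relative


@pytest.fixture
def tiny_counts() -> FeatureTable:
    df = pd.DataFrame(
        {"s1": [2, 2, 0], "s2": [1, 3, 4], "s3": [5, 0, 5]},
        index=["f1", "f2", "f3"],
    )
    return FeatureTable(df, kind="counts")


@pytest.fixture
def tiny_taxonomy() -> TaxonomyMap:
    lin = pd.DataFrame(
        {
            "family": ["FamA", "FamA", "FamB"],
            "genus": ["G1", "G1", None],
        },
        index=["f1", "f2", "f3"],
    )
    return TaxonomyMap(lin)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests."""
    cfg = simulate.default_config(seed=42)
    return simulate.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_default(default_cohort):
    from enterotyper import EnterotypeModel

    table, tax, meta, truth = default_cohort
    res = EnterotypeModel(table, taxonomy=tax, metadata=meta).fit()
    return res, truth


def euclidean_dm(points: np.ndarray, ids=None) -> DistanceMatrix:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1:
        pts = pts.T
    ids = ids or [f"s{i}" for i in range(pts.shape[0])]
    return DistanceMatrix(ids, squareform(pdist(pts)), "euclidean")


@pytest.fixture
def euclid():
    return euclidean_dm


@pytest.fixture
def relative_from():
    def _make(arr, sample_ids=None, feature_ids=None) -> FeatureTable:
        arr = np.asarray(arr, dtype=float)
        sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
        feature_ids = feature_ids or [f"f{i}" for i in range(arr.shape[0])]
        df = pd.DataFrame(arr, index=feature_ids, columns=sample_ids)
        return to_relative(FeatureTable(df, kind="counts")) if not np.allclose(
            arr.sum(axis=0), 1.0
        ) else FeatureTable(df, kind="relative")

    return _make
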