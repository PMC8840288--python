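import numpy as np
import pytest

from stressreport.features import extract_cohort_features
from stressreport.model import StressModel, Tree, _fit_forest
from stressreport.synthetic import default_subject_params, simulate_subject


@pytest.fixture(scope="session")
def flat_subject_recording():
    """One noise-free-parameter subject (population centres exactly) over a
    baseline + stress schedule; shared by recovery-style tests."""
    params = default_subject_params(seed=0, jitter_scale=0.0)
    return params, simulate_subject(
        params, [("baseline", 300.0), ("stress", 300.0)], seed=42
    )


@pytest.fixture(scope="session")
def flat_feature_matrix(flat_subject_recording):
    _, rec = flat_subject_recording
    return extract_cohort_features([rec])


def make_stump(feature: int, threshold: float, left: float, right: float, m: int) -> Tree:
    """Single-split tree: value `left` when x[feature] <= threshold."""
    return Tree(
        children_left=np.array([1, -1, -1]),
        children_right=np.array([2, -1, -1]),
        feature=np.array([feature, -2, -2]),
        threshold=np.array([threshold, -2.0, -2.0]),
        value=np.array([0.0, left, right]),
    )


def make_model(trees, m: int) -> StressModel:
    return StressModel(
        trees=list(trees),
        feature_names=[f"f{i}" for i in range(m)],
        p_avg=0.5,
        params={},
        seed=0,
    )


def random_forest_model(rng: np.random.Generator, m: int, n_trees: int, seed: int) -> StressModel:
    """Small fitted ensemble on random separable data (helper for Shapley
    oracle suites)."""
    n = 120
    X = rng.normal(size=(n, m))
    y = (X[:, 0] + 0.5 * X[:, min(1, m - 1)] + 0.3 * rng.normal(size=n) > 0).astype(int)
    trees = _fit_forest(X, y, {"n_estimators": n_trees, "max_depth": 4}, seed=seed)
    return make_model(trees, m)
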