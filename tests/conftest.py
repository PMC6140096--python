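import numpy as np
import pytest

from itemrel import CumulativeTables, ItemScoreMatrix, LatentClassModel

# Marginal cumulative probabilities of the four-item, three-category
# artificial example (columns: items 1..4; rows: x = 0, 1, 2).
EXAMPLE_MARGINALS = np.array(
    [
        [1.00, 1.00, 1.00, 1.00],
        [0.97, 0.94, 0.93, 0.86],
        [0.53, 0.32, 0.85, 0.72],
    ]
).T  # -> shape (J, m+1)

# Cross-item joint cumulative probabilities of the same example, keyed
# ((item, x), (item, y)) with 0-based items.
EXAMPLE_JOINTS = {
    ((1, 2), (0, 2)): 0.20,
    ((1, 2), (3, 2)): 0.27,
    ((1, 2), (2, 2)): 0.29,
    ((1, 2), (3, 1)): 0.30,
    ((1, 2), (2, 1)): 0.31,
    ((1, 2), (0, 1)): 0.32,
    ((0, 2), (3, 2)): 0.41,
    ((0, 2), (2, 2)): 0.47,
    ((0, 2), (3, 1)): 0.48,
    ((0, 2), (2, 1)): 0.50,
    ((0, 2), (1, 1)): 0.51,
    ((3, 2), (2, 2)): 0.64,
    ((3, 2), (2, 1)): 0.68,
    ((3, 2), (1, 1)): 0.68,
    ((3, 2), (0, 1)): 0.70,
    ((2, 2), (3, 1)): 0.76,
    ((2, 2), (1, 1)): 0.81,
    ((2, 2), (0, 1)): 0.84,
    ((3, 1), (2, 1)): 0.81,
    ((3, 1), (1, 1)): 0.81,
    ((3, 1), (0, 1)): 0.84,
    ((2, 1), (1, 1)): 0.88,
    ((2, 1), (0, 1)): 0.91,
    ((1, 1), (0, 1)): 0.91,
}


def example_tables() -> CumulativeTables:
    """CumulativeTables of the published artificial four-item example."""
    j, m = 4, 2
    joint = np.full((j, j, m, m), np.nan)
    for ((a, x), (b, y)), v in EXAMPLE_JOINTS.items():
        joint[a, b, x - 1, y - 1] = v
        joint[b, a, y - 1, x - 1] = v
    return CumulativeTables(EXAMPLE_MARGINALS, joint, np.full(j, np.nan))


@pytest.fixture
def artificial_example():
    return example_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_data(rng):
    """A 40 x 5 polytomous (m=2) score matrix with correlated items."""
    theta = rng.normal(size=40)
    probs = 1 / (1 + np.exp(-(theta[:, None] - np.linspace(-1, 1, 5))))
    scores = (rng.random((40, 5)) < probs).astype(int) + (
        rng.random((40, 5)) < probs * 0.6
    ).astype(int)
    return ItemScoreMatrix.from_array(scores, m=2)


# Latent class models of the two worked examples: both imply the same
# marginal P(Xi = 1) = .68 but different same-item joint probabilities.
@pytest.fixture
def two_class_model():
    return LatentClassModel.dichotomous([0.4, 0.6], [0.5, 0.8])


@pytest.fixture
def three_class_model():
    return LatentClassModel.dichotomous([0.4, 0.3, 0.3], [0.5, 0.6, 1.0])


def exact_cov_data(cov: np.ndarray, n: int, seed=0) -> np.ndarray:
    """Continuous data whose sample covariance (ddof=1) equals ``cov`` exactly.

    Draw normal data, empirically whiten, then color by the Cholesky factor.
    """
    cov = np.asarray(cov, dtype=float)
    j = cov.shape[0]
    rng_ = np.random.default_rng(seed)
    raw = rng_.normal(size=(n, j))
    raw = raw - raw.mean(axis=0)
    sample = np.cov(raw, rowvar=False, ddof=1)
    white = raw @ np.linalg.inv(np.linalg.cholesky(sample)).T
    return white @ np.linalg.cholesky(cov).T
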