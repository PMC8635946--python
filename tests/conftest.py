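import numpy as np
import pytest

from dtifuse import DTIDataset, RunConfig
from dtifuse.synthetic import benchmark_spec, generate


def gaussian_similarity(rng: np.random.Generator, n: int, dim: int = 4) -> np.ndarray:
    """Random valid similarity matrix: Gaussian kernel of latent points
    (symmetric, unit diagonal, entries in (0, 1], PSD)."""
    X = rng.standard_normal((n, dim))
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    S = np.exp(-d2 / max(np.median(d2), 1e-9))
    np.fill_diagonal(S, 1.0)
    return S


def random_dataset(seed: int, n: int = 8, m: int = 5,
                   density: float = 0.3) -> DTIDataset:
    rng = np.random.default_rng(seed)
    Y = (rng.random((n, m)) < density).astype(int)
    if Y.sum() == 0:
        Y[0, 0] = 1
    return DTIDataset(
        [f"D{i}" for i in range(n)], [f"T{j}" for j in range(m)],
        Y, gaussian_similarity(rng, n), gaussian_similarity(rng, m),
    )


@pytest.fixture
def tiny_dataset() -> DTIDataset:
    """3 drugs x 2 targets with hand-set similarities and one new drug."""
    S_d = np.array([[1.0, 0.8, 0.2],
                    [0.8, 1.0, 0.3],
                    [0.2, 0.3, 1.0]])
    S_t = np.array([[1.0, 0.4],
                    [0.4, 1.0]])
    Y = np.array([[1, 0],
                  [0, 1],
                  [0, 0]])
    return DTIDataset(["D1", "D2", "D3"], ["T1", "T2"], Y, S_d, S_t)


@pytest.fixture
def default_config() -> RunConfig:
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def benchmark_one():
    """Standard planted benchmark at seed 1 (shared across tests)."""
    return generate(benchmark_spec(1))
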