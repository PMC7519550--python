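import numpy as np
import pandas as pd
import pytest

from qstab.data import OBS_COLUMNS, CqDataset


def make_long_frame(matrix: dict, culture: str = "A1") -> pd.DataFrame:
    """Long frame from gene -> Cq list, samples laid out as lysates of one passage."""
    rows = []
    for gene, cqs in matrix.items():
        for i, cq in enumerate(cqs):
            rows.append((gene, culture, 1, i + 1, 1, float(cq)))
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def make_dataset(matrix: dict, culture: str = "A1") -> CqDataset:
    return CqDataset(make_long_frame(matrix, culture), sample_unit="lysate_mean")


def random_matrix(rng: np.random.Generator, n_genes: int, n_samples: int) -> dict:
    """Random Cq matrix dict with realistic baselines and spread."""
    baselines = rng.uniform(8.0, 30.0, size=n_genes)
    return {
        f"G{i:02d}": list(baselines[i] + rng.normal(0.0, 0.4, size=n_samples))
        for i in range(n_genes)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_dataset():
    """3 genes x 4 samples, fixed values."""
    rng = np.random.default_rng(7)
    return make_dataset(random_matrix(rng, 3, 4))


@pytest.fixture
def medium_dataset():
    """5 genes x 10 samples, fixed values."""
    rng = np.random.default_rng(11)
    return make_dataset(random_matrix(rng, 5, 10))
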