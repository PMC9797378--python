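from pathlib import Path

import numpy as np
import pytest

from dfu.core import OrdinalScale

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def opgt_csv() -> Path:
    """Synthetic stand-in for the gold-judgment histogram table.

    Fifteen K=5 histograms with a perceived-polarization score that is,
    by construction, a monotone function of DFU.
    """
    return DATA_DIR / "synthetic_opgt.csv"


@pytest.fixture
def sentiment_scale() -> OrdinalScale:
    return OrdinalScale(("negative", "neutral", "positive"))


def random_histogram(rng: np.random.Generator, k: int) -> list[float]:
    """A random point on the K-simplex (Dirichlet(1))."""
    f = rng.dirichlet(np.ones(k))
    return f.tolist()
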