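from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from serous.io import ExpressionMatrix, read_meme_minimal

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def known_motifs():
    """Synthetic stand-ins for curated TF database motifs (10 PWMs)."""
    return read_meme_minimal(DATA_DIR / "known_motifs_synthetic.meme")


@pytest.fixture
def small_matrix():
    """3 genes x 5 samples, two groups, no missing values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 10.0, 12.0],
         [5.0, 4.0, 6.0, 5.5, 4.5],
         [0.1, 0.2, 0.1, 8.0, 9.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4", "s5"])
    groups = {"s1": "X", "s2": "X", "s3": "X", "s4": "Y", "s5": "Y"}
    return ExpressionMatrix(values, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
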