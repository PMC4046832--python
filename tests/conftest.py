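import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chromcause import MarkMatrix


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 100, size=(30, 3)).astype(float)
    return MarkMatrix(
        gene_ids=[f"g{i}" for i in range(30)],
        mark_names=["H3K4Me3", "H3K27Ac", "H2AZ"],
        counts=counts,
        nucpos=rng.integers(1, 50, size=30).astype(float),
    )


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name: str, text: str) -> Path:
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
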