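import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from coordinome import BlockSpec, SyntheticSpec, generate_expression


@pytest.fixture(scope="session")
def two_state_spec():
    """Two conditions with a block planted in each: the deconstruction /
    reconstruction pattern at small scale."""
    genes = [f"g{i:04d}" for i in range(120)]
    return SyntheticSpec(
        n_genes=120,
        conditions=("stateA", "stateB"),
        n_replicates=3,
        blocks=(
            BlockSpec("blockA", tuple(genes[:15]), {"stateA": 0.99}),
            BlockSpec("blockB", tuple(genes[15:30]), {"stateB": 0.99}),
        ),
        regulated_fraction=0.3,
        effect_size_log2=1.0,
        noise_sd=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def two_state_data(two_state_spec):
    return generate_expression(two_state_spec)


@pytest.fixture()
def tiny_matrix():
    """Hand-built matrix: 2 conditions x 3 replicates, 4 genes with known
    mean ratios (2x, 1x, 0.5x, and a zero-mean denominator case)."""
    data = {
        "A_1": [2.0, 3.0, 1.0, 0.0],
        "A_2": [2.0, 3.0, 1.0, 0.0],
        "A_3": [2.0, 3.0, 1.0, 0.0],
        "B_1": [1.0, 3.0, 2.0, 1.0],
        "B_2": [1.0, 3.0, 2.0, 1.0],
        "B_3": [1.0, 3.0, 2.0, 1.0],
    }
    return pd.DataFrame(data, index=pd.Index(["up2", "flat", "down2", "zeroA"], name="gene"))
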