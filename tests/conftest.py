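import numpy as np
import pandas as pd
import pytest

from stag2loop.contacts import BinTable, ContactMatrix, make_bin_table
from stag2loop.study import generate_study


@pytest.fixture(scope="session")
def noiseless_study():
    """The planted study in its exact (noise-free) configuration."""
    return generate_study(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_contact_matrix(
    rng: np.random.Generator,
    n_bins: int = 60,
    bait_frac: float = 0.3,
    density: float = 0.2,
    n_chrom: int = 1,
) -> ContactMatrix:
    """A random sparse raw matrix on a random bait layout (test helper)."""
    per = n_bins // n_chrom
    bt = make_bin_table({f"chr{i+1}": per * 1000 for i in range(n_chrom)}, 1000)
    flags = rng.random(bt.n_bins) < bait_frac
    if not flags.any():
        flags[0] = True
    bins = bt.bins.assign(is_bait=flags)
    bt = BinTable(bins=bins, bin_size=1000)
    pairs = [(i, j) for i in range(bt.n_bins) for j in range(i, bt.n_bins)]
    keep = rng.random(len(pairs)) < density
    chosen = [p for p, k in zip(pairs, keep) if k]
    counts = rng.integers(1, 50, size=len(chosen))
    px = pd.DataFrame(
        {
            "bin1_id": [p[0] for p in chosen],
            "bin2_id": [p[1] for p in chosen],
            "count": counts,
        }
    )
    return ContactMatrix(bt, px)
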