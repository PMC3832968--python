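import numpy as np
import pandas as pd
import pytest

from maxfj.data import GenotypeCounts


def random_dataset(rng, n_min=6, n_max=60, ensure_cells=True):
    """Random two-stage subject table with all six cells occupied."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        stage = rng.integers(1, 3, size=n)
        geno = rng.integers(0, 3, size=n)
        if ensure_cells:
            # guarantee one subject in every stage x genotype cell
            cells = [(s, g) for s in (1, 2) for g in (0, 1, 2)]
            if n < 6:
                continue
            for i, (s, g) in enumerate(cells):
                stage[i], geno[i] = s, g
        df = pd.DataFrame(
            {
                "stage": stage,
                "genotype": geno,
                "phenotype": rng.standard_normal(n),
            }
        )
        counts = np.bincount((stage - 1) * 3 + geno, minlength=6)
        n1 = int((stage == 1).sum())
        if not ensure_cells or (np.all(counts > 0) and n1 > 3 and n - n1 > 3):
            return df


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def random_counts_factory(rng):
    def make(lo=5, hi=2000):
        vals = rng.integers(lo, hi + 1, size=6)
        return GenotypeCounts(*vals.astype(float))

    return make
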