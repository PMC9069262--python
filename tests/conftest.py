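import numpy as np
import pytest

import chronoscan as cs


@pytest.fixture(scope="session")
def end_to_end_dir(tmp_path_factory):
    """One on-disk synthetic dataset shared by I/O and CLI tests."""
    outdir = tmp_path_factory.mktemp("dataset")
    truth = cs.gen_end_to_end(outdir, seed=123)
    return outdir, truth


def random_genotype_matrix(rng, n=30, m=10, missing_rate=0.05):
    codes = rng.integers(0, 3, (n, m)).astype(np.int8)
    mask = rng.random((n, m)) < missing_rate
    codes[mask] = cs.MISSING
    return cs.GenotypeMatrix(
        [f"s{i}" for i in range(n)],
        [f"l{j}" for j in range(m)],
        codes,
        ["A"] * m,
    )
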