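import numpy as np
import pandas as pd
import pytest

from epidriver.io import MethylomeMatrix
from epidriver.simulate import SyntheticConfig, generate_bundle


def make_methylome(pos, meth, total, sample_names=None, conditions=None, chrom="chr1"):
    """Build a MethylomeMatrix from plain arrays (single chromosome)."""
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    if meth.shape[0] != len(pos):
        meth, total = meth.T, total.T
    n_samples = meth.shape[1]
    if sample_names is None:
        sample_names = [f"S{i + 1}" for i in range(n_samples)]
    if conditions is None:
        half = n_samples // 2
        conditions = ["tumor"] * half + ["normal"] * (n_samples - half)
    pair_ids = []
    counter = {}
    for c in conditions:
        counter[c] = counter.get(c, 0) + 1
        pair_ids.append(f"P{counter[c]}")
    meta = pd.DataFrame(
        {"condition": conditions, "pair_id": pair_ids},
        index=pd.Index(sample_names, name="sample"),
    )
    sites = pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64)})
    return MethylomeMatrix(sites, meth.astype(int), total.astype(int), list(sample_names), meta)


@pytest.fixture(scope="session")
def small_bundle():
    """A desk-size bundle: 200 genes, 10 pairs, 10 drivers."""
    cfg = SyntheticConfig(n_genes=200, n_pairs=10, n_drivers=10, n_homeobox=25, seed=1)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The reference benchmark: 2000 genes, 30 pairs, 40 drivers, seed 1."""
    return generate_bundle(SyntheticConfig(seed=1))
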