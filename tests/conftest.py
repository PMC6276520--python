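import numpy as np
import pandas as pd
import pytest

from isingdmr import MethylationDataset


def make_dataset(n_sites=12, n_pairs=6, seed=0, scale="M", chrom="chr1",
                 values=None):
    """Small random paired dataset on a regular 100-bp grid."""
    rng = np.random.default_rng(seed)
    manifest = pd.DataFrame({
        "site_id": [f"cg{i:04d}" for i in range(n_sites)],
        "chrom": chrom,
        "pos": 1000 + 100 * np.arange(n_sites),
    })
    samples = pd.DataFrame({
        "sample_id": [f"T{i}" for i in range(n_pairs)]
                     + [f"N{i}" for i in range(n_pairs)],
        "condition": ["tumor"] * n_pairs + ["normal"] * n_pairs,
        "pair_id": [f"P{i}" for i in range(n_pairs)] * 2,
    })
    if values is None:
        if scale == "beta":
            values = rng.uniform(0.05, 0.95, size=(n_sites, 2 * n_pairs))
        else:
            values = rng.normal(size=(n_sites, 2 * n_pairs))
    return MethylationDataset(manifest=manifest, samples=samples,
                              values=values, scale=scale)


@pytest.fixture
def tiny_dataset():
    """3 sites x 4 samples (2 pairs), beta scale."""
    return make_dataset(n_sites=3, n_pairs=2, seed=1, scale="beta")


@pytest.fixture
def random_dataset():
    """50 sites x 10 pairs, M scale, for brute-force comparisons."""
    return make_dataset(n_sites=50, n_pairs=10, seed=7)


@pytest.fixture
def dataset_files(tmp_path, tiny_dataset):
    """The tiny dataset written out as the three delimited files."""
    from isingdmr import write_dataset

    paths = write_dataset(tiny_dataset, tmp_path)
    return paths, tiny_dataset
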