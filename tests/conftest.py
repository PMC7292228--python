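import numpy as np
import pandas as pd
import pytest

from plscreen import CountMatrix, build_manifest, partition_pools


@pytest.fixture(scope="session")
def paper_manifest():
    """The published library design: 730 genes, 584 with 6 hairpins."""
    return build_manifest(730, 584)


@pytest.fixture(scope="session")
def small_manifest():
    """12 genes (6 six-hairpin, 6 five-hairpin), one pool."""
    return partition_pools(build_manifest(12, 6), target_size=100, seed=0)


@pytest.fixture(scope="session")
def study_manifest():
    """The synthetic study design used for calibration/recovery runs:
    200 genes (half with 6 hairpins), pooled at target size 100."""
    return partition_pools(build_manifest(200, 100), target_size=100, seed=3)


def make_count_matrix(counts: dict, classes: dict, pool_id: int = 1,
                      normalized: bool = False) -> CountMatrix:
    """Build a CountMatrix from {sample: vector} and {sample: class}."""
    df = pd.DataFrame(counts)
    df.index = [f"hp{i+1}" for i in range(len(df))]
    df.index.name = "hairpin_id"
    samples = pd.DataFrame(
        {"class_": pd.Series(classes), "pool_id": pool_id, "scored": True})
    samples.index.name = "sample_id"
    return CountMatrix(df, samples, normalized=normalized)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
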