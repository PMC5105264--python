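import numpy as np
import pytest

from concordia import MISSING, PlatformDataset, SimulationConfig, SnpRecord
from concordia.synthetic_data import simulate_dual_platform


def make_dataset(calls, platform="test", quality=None,
                 quality_orientation="higher_is_better", snps=None):
    """Build a small PlatformDataset from a 2-D list/array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if snps is None:
        snps = [SnpRecord(snp_id=f"snp{j+1}", chrom="1", pos=j + 1,
                          allele_a="A", allele_b="G") for j in range(m)]
    ds = PlatformDataset(
        platform_name=platform,
        sample_ids=[f"s{i+1}" for i in range(n)],
        snps=snps,
        calls=calls,
        quality=None if quality is None else np.asarray(quality, dtype=float),
        quality_orientation=quality_orientation,
    )
    ds.validate()
    return ds


def random_dataset(rng, n=6, m=10, missing_rate=0.1, with_quality=False,
                   platform="rand"):
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    miss = rng.random((n, m)) < missing_rate
    calls[miss] = MISSING
    quality = None
    if with_quality:
        quality = rng.random((n, m))
        quality[miss] = np.nan
    return make_dataset(calls, platform=platform, quality=quality)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim_pair():
    """A modest coupled-quality dual-platform simulation reused across tests."""
    cfg = SimulationConfig(
        n_samples=60, n_snps=3000, error_rate_left=0.005,
        error_rate_right=0.02, missing_rate_left=0.01,
        missing_rate_right=0.03, seed=7,
    )
    return simulate_dual_platform(cfg)
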