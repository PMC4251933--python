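import numpy as np
import pytest

from sexsnpscan.pool_io import PoolSiteCounts


def make_site(
    chrom="LG1",
    pos=100,
    ref="A",
    male=(0, 0, 0, 0, 0, 0),
    female=(0, 0, 0, 0, 0, 0),
):
    """Counts are in sync order A:T:C:G:N:del."""
    return PoolSiteCounts(chrom, pos, ref, tuple(male), tuple(female))


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_929)


@pytest.fixture
def random_sites(rng):
    """1000 random biallelic sites with coverages in [2, 60]."""
    sites = []
    for i in range(1000):
        cov_m = int(rng.integers(2, 61))
        cov_f = int(rng.integers(2, 61))
        a_m = int(rng.integers(0, cov_m + 1))
        a_f = int(rng.integers(0, cov_f + 1))
        sites.append(
            make_site(
                pos=i + 1,
                male=(a_m, cov_m - a_m, 0, 0, 0, 0),
                female=(a_f, cov_f - a_f, 0, 0, 0, 0),
            )
        )
    return sites
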