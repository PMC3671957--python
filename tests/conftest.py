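import numpy as np
import pytest

from tfmir.energy import toy_params
from tfmir.promoter_binding import BindingCluster, GenomicInterval, PromoterRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy():
    """Every canonical stack -1, init 0, loops forbidden."""
    return toy_params()


@pytest.fixture
def toy_loops():
    """Toy stacks plus affine loop penalties (open 2, extend 1, cap 3)."""
    return toy_params(
        bulge_open=2.0, bulge_extend=1.0, internal_open=2.0, internal_extend=1.0, max_loop=3
    )


def random_promoters(rng, n, chroms=("chr1", "chr2"), span=100_000):
    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 2000))
        out.append(
            PromoterRecord(
                f"p{i}",
                GenomicInterval(str(rng.choice(chroms)), start, start + length),
                (f"miR-x{i}",),
            )
        )
    return out


def random_clusters(rng, m, chroms=("chr1", "chr2"), span=100_000):
    out = []
    for _ in range(m):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 800))
        out.append(
            BindingCluster(
                GenomicInterval(str(rng.choice(chroms)), start, start + length),
                int(rng.integers(0, 1001)),
            )
        )
    return out
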