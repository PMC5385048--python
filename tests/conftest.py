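import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

from synthnorm import build_bin_grid, classify_bins
from synthnorm.coverage import CoverageProfile
from synthnorm.intervals import GenomicInterval


@pytest.fixture
def toy_grid():
    """chr1 of 250 kb at 100-kb bins: two usable bins plus a partial one."""
    return build_bin_grid({"chr1": 250_000}, 100_000)


@pytest.fixture
def two_chrom_grid():
    return build_bin_grid({"chr1": 500_000, "chr2": 300_000}, 100_000)


@pytest.fixture
def classified_grid(toy_grid):
    return classify_bins(toy_grid, [GenomicInterval("chr1", 150_000, 151_000)])


def make_profile(grid, counts, sample_id="s", role="normal", library_size=None):
    counts = np.asarray(counts, dtype=float)
    return CoverageProfile(
        sample_id=sample_id,
        role=role,
        counts=counts,
        library_size=float(counts.sum() if library_size is None else library_size),
        grid=grid,
    )


@pytest.fixture
def profile_factory():
    return make_profile
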