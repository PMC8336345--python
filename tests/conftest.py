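import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cnvrassoc import CnvLocus, build_snp_map, simulate_cohort


@pytest.fixture(scope="session")
def small_map():
    """1 chromosome, 1200 markers, ~3 kb spacing."""
    return build_snp_map(1, 1200, 3000, 1e6, seed=7)


@pytest.fixture(scope="session")
def deletion_locus(small_map):
    """A 50-probe heterozygous deletion locus."""
    return CnvLocus(
        1, int(small_map.pos[400]), int(small_map.pos[449]), 1, 1.0, 1.0
    )


@pytest.fixture(scope="session")
def duplication_locus(small_map):
    """A 100-probe single-copy duplication locus."""
    return CnvLocus(
        1, int(small_map.pos[700]), int(small_map.pos[799]), 3, 1.0, 1.0
    )
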