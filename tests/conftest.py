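import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from varscreen import (
    CohortGenotypeTable,
    VariantKey,
    demo_config,
    write_fixture_bundle,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_keys(n: int, chrom: str = "chr1", start: int = 1_000, step: int = 100):
    """n distinct SNV keys on one chromosome."""
    return [VariantKey(chrom, start + i * step, "A", "G") for i in range(n)]


def table_from_dosages(dosages, chrom: str = "chr1") -> CohortGenotypeTable:
    """Cohort table from a dosage matrix (-1 = missing), keys autogenerated."""
    dosages = np.asarray(dosages, dtype=np.int16)
    return CohortGenotypeTable.from_dosages(make_keys(dosages.shape[0], chrom), dosages)


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """The default synthetic fixture bundle, written once per session."""
    out = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(demo_config(seed=7), out)
    return paths
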