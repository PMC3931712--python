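import pytest
from hypothesis import HealthCheck, settings

from epimotif.io import RunConfig
from epimotif.synthetic import SyntheticDatasetSpec, generate
from epimotif.workflow import run_pipeline

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def default_ds():
    """Synthetic dataset at the default desk-scale study conditions."""
    return generate(SyntheticDatasetSpec(seed=0))


@pytest.fixture(scope="session")
def small_ds():
    """A fast, smaller dataset for structural (non-statistical) checks."""
    spec = SyntheticDatasetSpec(
        n_chromosomes=2,
        chrom_length=300_000,
        n_sites=60,
        gap_runs=((150_000, 5_000),),
        seed=0,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline result at the default study conditions (no files)."""
    return run_pipeline(RunConfig(seed=0), write=False)
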