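import numpy as np
import pytest
from hypothesis import settings

from clonearch import CohortConfig, PlantedFeature, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-sample synthetic cohort shared by the integration tests."""
    cfg = CohortConfig(
        n_samples=60,
        seed=7,
        n_candidates_per_sample=20,
        class_mix={"Low": 1.0},  # tight burden range: planted shift detectable
        planted_features=(PlantedFeature("sig_planted", "subclonal", 3.0),),
        feature_prevalence=0.35,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    """The small cohort written to disk in every interchange format."""
    outdir = tmp_path_factory.mktemp("cohort")
    small_cohort.write(outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
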